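"""Transcript/repeat annotation I/O and unique quantification regions.

Overlapping transcripts of a repeat-embedded locus cannot be told apart
by whole-transcript counting.  The strategy implemented here sidesteps
expectation-maximisation deconvolution entirely: each transcript is
quantified over the exonic bases that belong to it *alone* (its unique
region), while the composite gene is quantified over the repeat-annotated
provirus body verbatim.

GTF input/output uses the conventional 1-based inclusive coordinates and
``transcript_id`` / ``gene_id`` attributes; everything internal is
0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import (
    GenomicInterval,
    Interval,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)


class GTFParseError(ValueError):
    """Malformed GTF input; carries the offending line number."""


@dataclass
class TranscriptModel:
    """A named transcript: ordered, disjoint exons on one chromosome/strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")

    @property
    def exonic_union(self) -> list[Interval]:
        return list(self.exons)

    @property
    def spliced_length(self) -> int:
        return total_length(self.exons)


@dataclass(frozen=True)
class RepeatFeature:
    """A RepeatMasker-style repeat part (e.g. LTR5Hs, HERVK-int)."""

    name: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("repeat feature name must be non-empty")


@dataclass
class QuantRegionSet:
    """Named meta-features (disjoint interval unions) used for counting."""

    chrom: str
    features: dict[str, list[Interval]]

    def __post_init__(self) -> None:
        for fid, ivs in self.features.items():
            merged = merge_intervals(ivs)
            if total_length(merged) <= 0:
                raise ValueError(f"feature {fid!r} has zero effective length")
            self.features[fid] = merged

    @property
    def effective_length(self) -> dict[str, int]:
        return {fid: total_length(ivs) for fid, ivs in self.features.items()}

    def feature_ids(self) -> list[str]:
        return list(self.features)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(
    path: str | Path,
    feature_kinds: Iterable[str] = ("exon",),
) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Parameters
    ----------
    path:
        GTF file (1-based inclusive coordinates).
    feature_kinds:
        GTF feature-column values to treat as exon-like; other lines are
        skipped.

    Returns
    -------
    Transcripts in order of first appearance, exons converted to 0-based
    half-open, sorted and merged if book-ended.
    """
    kinds = set(feature_kinds)
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, kind, start, end, _score, strand, _frame, attrs = fields
            if kind not in kinds:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise GTFParseError(f"line {lineno}: invalid coordinates {start}-{end}")
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                raise GTFParseError(f"line {lineno}: exon without transcript_id attribute")
            gid = attr.get("gene_id", "")
            rec = per_tx.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []}
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise GTFParseError(
                    f"line {lineno}: transcript {tid} spans multiple chromosomes/strands"
                )
            rec["exons"].append((start_i - 1, end_i))  # 1-based inclusive -> half-open
    return [
        TranscriptModel(tid, rec["gene_id"], rec["chrom"], rec["strand"], rec["exons"])
        for tid, rec in per_tx.items()
    ]


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "erviso",
) -> None:
    """Write transcript models as GTF exon lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for s, e in tx.exons:
                attrs = f'transcript_id "{tx.transcript_id}"; gene_id "{tx.gene_id}";'
                fh.write(
                    "\t".join(
                        [tx.chrom, source, "exon", str(s + 1), str(e), ".", tx.strand, ".", attrs]
                    )
                    + "\n"
                )


def write_regions_gtf(regions: QuantRegionSet, path: str | Path, source: str = "erviso") -> None:
    """Write a quantification region set as a GTF (one transcript per feature)."""
    models = [
        TranscriptModel(fid, fid, regions.chrom, ".", list(ivs))
        for fid, ivs in regions.features.items()
    ]
    write_gtf(models, path, source=source)


def read_regions_gtf(path: str | Path) -> QuantRegionSet:
    transcripts = parse_gtf(path)
    chroms = {t.chrom for t in transcripts}
    if len(chroms) != 1:
        raise ValueError(f"region GTF must be single-chromosome, got {sorted(chroms)}")
    return QuantRegionSet(chroms.pop(), {t.transcript_id: t.exons for t in transcripts})


def read_repeat_features(path: str | Path) -> list[RepeatFeature]:
    """Read repeat parts from BED (chrom start end name [score strand]) or a
    3-column TSV (name, chrom:start-end, strand)."""
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 4 and fields[1].isdigit():
                chrom, start, end, name = fields[:4]
                strand = fields[5] if len(fields) >= 6 else "."
                feats.append(
                    RepeatFeature(name, GenomicInterval(chrom, int(start), int(end), strand))
                )
            elif len(fields) >= 2 and ":" in fields[1]:
                name, loc = fields[:2]
                strand = fields[2] if len(fields) >= 3 else "."
                chrom, rng = loc.rsplit(":", 1)
                start, end = rng.split("-")
                feats.append(
                    RepeatFeature(name, GenomicInterval(chrom, int(start), int(end), strand))
                )
            else:
                raise ValueError(f"line {lineno}: unrecognised repeat feature format")
    return feats


def derive_unique_regions(
    target: TranscriptModel,
    others: Sequence[TranscriptModel],
    same_strand_only: bool = False,
) -> list[Interval]:
    """Exonic bases of ``target`` covered by no transcript in ``others``.

    Strand is ignored by default (the locus features are co-located);
    ``same_strand_only`` restricts the subtraction to same-strand models.
    An empty result is allowed.
    """
    for other in others:
        if other.chrom != target.chrom:
            raise ValueError(
                f"mixed chromosomes: {target.transcript_id} on {target.chrom}, "
                f"{other.transcript_id} on {other.chrom}"
            )
    shadow: list[Interval] = []
    for other in others:
        if other.transcript_id == target.transcript_id:
            continue
        if same_strand_only and other.strand != target.strand:
            continue
        shadow.extend(other.exons)
    if not shadow:
        return list(target.exons)
    return subtract_intervals(target.exons, shadow)


def shared_exonic_bases(target: TranscriptModel, others: Sequence[TranscriptModel]) -> list[Interval]:
    shadow = [iv for o in others if o.transcript_id != target.transcript_id for iv in o.exons]
    if not shadow:
        return []
    return intersect_intervals(target.exons, shadow)


def build_quantification_regions(
    transcripts: Sequence[TranscriptModel],
    repeat_body: RepeatFeature,
    region_spec: Mapping[str, Mapping],
) -> QuantRegionSet:
    """Assemble the counting meta-features from per-feature rules.

    ``region_spec`` maps a feature id to one of:

    - ``{"unique_to": <transcript_id>, "versus": [ids...]}`` — exonic bases of
      the named transcript not covered by the ``versus`` set (default: all
      other supplied transcripts);
    - ``{"repeat_body": true}`` — the repeat interval verbatim;
    - ``{"intervals": [[start, end], ...]}`` — an explicit interval list.

    A unique-rule feature resolving to an empty union raises, naming the
    feature.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    chroms = {t.chrom for t in transcripts} | {repeat_body.interval.chrom}
    if len(chroms) != 1:
        raise ValueError(f"all models and the repeat body must share one chromosome, got {sorted(chroms)}")
    chrom = chroms.pop()

    features: dict[str, list[Interval]] = {}
    for fid, rule in region_spec.items():
        if "unique_to" in rule:
            tid = rule["unique_to"]
            if tid not in by_id:
                raise KeyError(f"feature {fid!r}: unknown transcript {tid!r}")
            versus_ids = rule.get("versus")
            if versus_ids is None:
                others = [t for t in transcripts if t.transcript_id != tid]
            else:
                others = [by_id[v] for v in versus_ids]
            region = derive_unique_regions(by_id[tid], others)
            if not region:
                raise ValueError(
                    f"feature {fid!r}: transcript {tid!r} is fully shadowed; unique region is empty"
                )
            features[fid] = region
        elif rule.get("repeat_body"):
            features[fid] = [repeat_body.interval.span]
        elif "intervals" in rule:
            features[fid] = merge_intervals([tuple(iv) for iv in rule["intervals"]])
        else:
            raise ValueError(f"feature {fid!r}: unrecognised rule {dict(rule)!r}")
    return QuantRegionSet(chrom, features)
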