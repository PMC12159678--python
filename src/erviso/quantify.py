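"""Read counting over quantification regions, TPM/CPM, junction scoring.

Counting follows the featureCounts conventions the locus analysis relies
on: unique alignments only by default, ambiguous (multi-feature) reads
discarded unless explicitly re-admitted, overlap decided block-wise
against each feature's interval union.

Promoter activity of the canonical 5' LTR is scored from *junction
reads*: alignments with at least one block overlapping the LTR and at
least one block (possibly the same, for contiguous read-through)
overlapping the internal coding region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import QuantRegionSet
from .intervals import GenomicInterval, Interval, intersect_intervals, merge_intervals, overlap_length
from .reads import AlignedRead

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountingPolicy:
    """Read-to-feature assignment policy.

    unique_only:
        Drop alignments that are not the single best hit (NH > 1).
    min_mapq:
        Minimum mapping quality; 30 mirrors a strict unique-coverage
        setting, 0 together with ``unique_only=False`` re-admits
        multimappers.
    allow_multioverlap:
        Count a read once per overlapped feature instead of discarding
        reads hitting two or more features.
    min_overlap_bases:
        A block must overlap a feature's union by at least this many
        bases for the read to hit the feature.
    """

    unique_only: bool = True
    min_mapq: int = 30
    allow_multioverlap: bool = False
    min_overlap_bases: int = 1


@dataclass
class CountTable:
    counts: pd.DataFrame  # features x samples, int
    library_size: dict[str, int]
    skipped_unknown_chrom: dict[str, int] = field(default_factory=dict)


def read_passes(read: AlignedRead, policy: CountingPolicy) -> bool:
    if policy.unique_only and not read.is_unique:
        return False
    return read.mapq >= policy.min_mapq


def assign_read(read: AlignedRead, regions: QuantRegionSet, policy: CountingPolicy) -> list[str]:
    """Feature ids the read is counted for (empty if filtered/ambiguous)."""
    if read.chrom != regions.chrom:
        return []
    hits = [
        fid
        for fid, union in regions.features.items()
        if any(
            overlap_length(block, union) >= policy.min_overlap_bases
            for block in read.blocks
        )
    ]
    if len(hits) > 1 and not policy.allow_multioverlap:
        return []
    return hits


def count_reads(
    alignments: Mapping[str, Iterable[AlignedRead]],
    regions: QuantRegionSet,
    policy: CountingPolicy | None = None,
) -> CountTable:
    """Count reads per (sample, feature).

    Parameters
    ----------
    alignments:
        Mapping sample_id -> iterable of alignments.
    regions:
        Quantification meta-features.
    policy:
        Assignment policy; defaults to :class:`CountingPolicy`.

    Reads on chromosomes absent from the annotation are skipped and
    tallied, not an error.  ``library_size`` records, per sample, the
    number of alignments passing the uniqueness/quality filters on the
    annotated chromosome.
    """
    policy = policy or CountingPolicy()
    fids = regions.feature_ids()
    samples = list(alignments)
    counts = pd.DataFrame(0, index=fids, columns=samples, dtype=int)
    library_size: dict[str, int] = {}
    skipped: dict[str, int] = {}
    for sample, reads in alignments.items():
        lib = 0
        skip = 0
        for read in reads:
            if not read_passes(read, policy):
                continue
            if read.chrom != regions.chrom:
                skip += 1
                continue
            lib += 1
            for fid in assign_read(read, regions, policy):
                counts.at[fid, sample] += 1
        library_size[sample] = lib
        skipped[sample] = skip
        if skip:
            logger.info("sample %s: %d reads on unannotated chromosomes skipped", sample, skip)
    return CountTable(counts=counts, library_size=library_size, skipped_unknown_chrom=skipped)


def tpm_normalize(
    counts: CountTable | pd.DataFrame,
    effective_lengths: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """Transcripts-per-million normalisation.

    rate_f = count_f / (length_f / 1000); TPM_f = rate_f / sum(rates) * 1e6
    per sample, over the full supplied feature annotation.  A sample with
    zero total rate yields an all-zero column with a warning.
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    lengths = pd.Series(dict(effective_lengths)).reindex(df.index).astype(float)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise KeyError(f"no effective length for features: {missing}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive effective length for features: {bad}")
    rates = df.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero total rate get all-zero TPM: {list(totals.index[zero])}",
            stacklevel=2,
        )
        totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def cpm(count: int, total_mapped: int) -> float:
    """Counts per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count / total_mapped * 1e6


@dataclass
class JunctionResult:
    sample_id: str
    junction_count: int
    cpm: float
    active: bool | None = None


Regionish = GenomicInterval | Interval | Sequence


def _as_union(region: Regionish) -> list[Interval]:
    if isinstance(region, GenomicInterval):
        return [region.span]
    region = list(region)
    if region and isinstance(region[0], (int, np.integer)):
        return [tuple(region)]  # a single (start, end)
    out: list[Interval] = []
    for item in region:
        if isinstance(item, GenomicInterval):
            out.append(item.span)
        else:
            out.append((int(item[0]), int(item[1])))
    return merge_intervals(out)


def find_junction_reads(
    alignments: Iterable[AlignedRead],
    region_a: Regionish,
    region_b: Regionish,
    policy: CountingPolicy | None = None,
) -> tuple[int, list[str]]:
    """Count reads spanning both regions.

    A read qualifies if at least one block overlaps ``region_a`` AND at
    least one block (possibly the same one, for contiguous read-through)
    overlaps ``region_b``.  Either side may be a single interval or an
    interval union (e.g. the exon union of the annotated transcripts).
    Regions must be disjoint.
    """
    policy = policy or CountingPolicy()
    a = _as_union(region_a)
    b = _as_union(region_b)
    if intersect_intervals(a, b):
        raise ValueError("region_a and region_b must be disjoint")
    count = 0
    ids: list[str] = []
    for read in alignments:
        if not read_passes(read, policy):
            continue
        hit_a = any(overlap_length(bl, a) > 0 for bl in read.blocks)
        hit_b = any(overlap_length(bl, b) > 0 for bl in read.blocks)
        if hit_a and hit_b:
            count += 1
            ids.append(read.read_id)
    return count, ids


def classify_ltr_activity(
    results: Sequence[JunctionResult],
    threshold: int = 1,
) -> tuple[list[tuple[str, bool]], dict]:
    """Flag samples with promoter-active canonical LTRs.

    A sample is active when its junction-read count reaches ``threshold``
    (default 1: presence/absence).  The summary reports the number of
    active samples and the mean CPM over all samples and over active
    samples.
    """
    if not results:
        raise ValueError("no junction results supplied")
    flags = []
    for r in results:
        r.active = r.junction_count >= threshold
        flags.append((r.sample_id, r.active))
    cpms = np.array([r.cpm for r in results], dtype=float)
    active_cpms = cpms[[r.active for r in results]]
    summary = {
        "n_samples": len(results),
        "n_active": int(sum(f for _, f in flags)),
        "mean_cpm": float(cpms.mean()),
        "mean_cpm_active": float(active_cpms.mean()) if active_cpms.size else 0.0,
    }
    return flags, summary
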