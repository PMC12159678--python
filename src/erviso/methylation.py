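"""CpG methylation summaries over a promoter region.

Consumes per-site modification calls (bedMethyl-style TSV, as exported
from nanopore modified basecalling) and classifies a region as
methylated when at least half of its adequately covered CpG sites are
majority-modified — the signature of a silenced LTR promoter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval


@dataclass(frozen=True)
class CpGSiteCall:
    chrom: str
    pos: int  # 0-based
    strand: str
    coverage: int
    mod_fraction: float

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.mod_fraction <= 1.0:
            raise ValueError("mod_fraction must be in [0, 1]")


@dataclass
class MethylationSummary:
    n_sites: int
    n_covered: int
    n_methylated: int
    weighted_mean: float  # coverage-weighted mean mod_fraction; nan if uncovered
    region_state: str  # methylated | unmethylated | indeterminate


def read_bedmethyl(path: str | Path) -> list[CpGSiteCall]:
    """Read a bedMethyl-style TSV: chrom, start, end, name, coverage,
    strand, mod_fraction (fraction in [0, 1])."""
    calls: list[CpGSiteCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"line {lineno}: expected >= 7 columns")
            chrom, start, _end, _name, coverage, strand, frac = fields[:7]
            calls.append(
                CpGSiteCall(chrom, int(start), strand, int(coverage), float(frac))
            )
    return calls


def write_bedmethyl(calls: Iterable[CpGSiteCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.pos + 1}\tCpG\t{c.coverage}\t{c.strand}\t{c.mod_fraction:.6g}\n"
            )


def collapse_cpg_strands(calls: Sequence[CpGSiteCall]) -> list[CpGSiteCall]:
    """Coverage-weighted merge of +/- calls of the same CpG dinucleotide.

    The minus-strand call of a CpG sits one base 3' of the plus-strand C;
    merged calls are reported at the plus-strand position.
    """
    by_site: dict[tuple[str, int], list[CpGSiteCall]] = {}
    for c in calls:
        pos = c.pos if c.strand != "-" else c.pos - 1
        by_site.setdefault((c.chrom, pos), []).append(c)
    merged = []
    for (chrom, pos), group in sorted(by_site.items()):
        cov = sum(c.coverage for c in group)
        frac = (
            sum(c.coverage * c.mod_fraction for c in group) / cov if cov > 0 else 0.0
        )
        merged.append(CpGSiteCall(chrom, pos, ".", cov, frac))
    return merged


def summarize_region_methylation(
    calls: Sequence[CpGSiteCall],
    region: GenomicInterval,
    min_cov: int = 5,
    site_threshold: float = 0.5,
    region_threshold: float = 0.5,
    collapse_strands: bool = False,
) -> MethylationSummary:
    """Summarise CpG methylation inside a region.

    A site is *covered* at coverage >= ``min_cov`` and *methylated* when
    additionally its modified fraction reaches ``site_threshold``.  The
    region is called methylated when the methylated share of covered
    sites reaches ``region_threshold``, unmethylated below it, and
    indeterminate with no covered site.
    """
    if collapse_strands:
        calls = collapse_cpg_strands(calls)
    inside = [
        c for c in calls if c.chrom == region.chrom and region.start <= c.pos < region.end
    ]
    covered = [c for c in inside if c.coverage >= min_cov]
    methylated = [c for c in covered if c.mod_fraction >= site_threshold]
    if covered:
        cov = np.array([c.coverage for c in covered], dtype=float)
        frac = np.array([c.mod_fraction for c in covered], dtype=float)
        wmean = float((cov * frac).sum() / cov.sum())
        state = "methylated" if len(methylated) / len(covered) >= region_threshold else "unmethylated"
    else:
        wmean = float("nan")
        state = "indeterminate"
    return MethylationSummary(
        n_sites=len(inside),
        n_covered=len(covered),
        n_methylated=len(methylated),
        weighted_mean=wmean,
        region_state=state,
    )
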