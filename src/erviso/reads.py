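"""Aligned-read containers and input (SAM via pysam, plain-text block tables).

A read is represented by its ordered aligned genomic blocks; gaps between
blocks are splices.  Uniqueness comes from the NH tag when present, else
from a mapping-quality proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .intervals import Interval, merge_intervals


@dataclass
class AlignedRead:
    read_id: str
    chrom: str
    blocks: list[Interval]
    is_unique: bool = True
    mapq: int = 60

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id} has no aligned blocks")
        # abutting blocks (e.g. across deletions) collapse; retained gaps are splices
        self.blocks = merge_intervals(self.blocks)


def read_sam(
    path: str | Path,
    unique_mapq: int = 30,
) -> Iterator[AlignedRead]:
    """Yield primary alignments from a SAM/BAM file.

    Uniqueness is taken from the ``NH`` tag (NH == 1) when present,
    otherwise ``mapq >= unique_mapq`` is used as a proxy.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            blocks = [(s, e) for s, e in aln.get_blocks() if s < e]
            if not blocks:
                continue
            if aln.has_tag("NH"):
                unique = aln.get_tag("NH") == 1
            else:
                unique = aln.mapping_quality >= unique_mapq
            yield AlignedRead(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                blocks=blocks,
                is_unique=unique,
                mapq=aln.mapping_quality,
            )


def read_block_table(path: str | Path) -> Iterator[AlignedRead]:
    """Read the plain-text block table: read_id, chrom, blocks, nh, mapq.

    Blocks are encoded ``start-end;start-end`` in 0-based half-open
    coordinates.  Lines starting with '#' are skipped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"line {lineno}: expected 5 fields, got {len(fields)}")
            read_id, chrom, blocks_s, nh, mapq = fields
            blocks = []
            for part in blocks_s.split(";"):
                s, e = part.split("-")
                blocks.append((int(s), int(e)))
            yield AlignedRead(read_id, chrom, blocks, is_unique=int(nh) == 1, mapq=int(mapq))


def write_block_table(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tblocks\tnh\tmapq\n")
        for r in reads:
            blocks_s = ";".join(f"{s}-{e}" for s, e in r.blocks)
            nh = 1 if r.is_unique else 2
            fh.write(f"{r.read_id}\t{r.chrom}\t{blocks_s}\t{nh}\t{r.mapq}\n")
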