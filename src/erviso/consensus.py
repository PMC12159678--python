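"""Consensus-divergence scan of an LTR against active reference elements.

Given a multiple sequence alignment of reference LTR elements known to
be promoter-active plus one query LTR, report every column where the
query departs from a strong reference consensus — candidate inactivating
substitutions (e.g. a T>C change in the core promoter motif).

Alignment computation is out of scope; an aligned FASTA is consumed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}


@dataclass(frozen=True)
class ConsensusDiff:
    column: int  # 0-based alignment column
    query_base: str
    consensus_base: str
    consensus_frequency: float  # modal count / non-gap reference count

    def __post_init__(self) -> None:
        if not 0.0 < self.consensus_frequency <= 1.0:
            raise ValueError("consensus frequency must be in (0, 1]")
        if self.query_base == self.consensus_base:
            raise ValueError("query base equals consensus base")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def filter_references_by_length(
    sequences: Mapping[str, str],
    min_len: int = 900,
) -> tuple[dict[str, str], list[str]]:
    """Keep sequences whose ungapped length *exceeds* ``min_len`` (strict >).

    Returns the retained subset and the discarded names; an empty result
    is an error.
    """
    kept: dict[str, str] = {}
    discarded: list[str] = []
    for name, seq in sequences.items():
        ungapped = sum(1 for ch in seq if ch not in GAP_CHARS)
        if ungapped > min_len:
            kept[name] = seq
        else:
            discarded.append(name)
    if not kept:
        raise ValueError(f"no sequences longer than {min_len} bp remain")
    return kept, discarded


def consensus_divergence(
    msa: Mapping[str, str],
    query_id: str,
    min_consensus_freq: float = 0.8,
) -> list[ConsensusDiff]:
    """Columns where the query departs from the reference consensus.

    Per column, the consensus is the modal non-gap base among the
    references (ties broken alphabetically, deterministic) with
    frequency = modal count / non-gap reference count.  A diff is
    emitted where the query base is a non-gap base different from the
    consensus and the consensus frequency reaches ``min_consensus_freq``.
    Query-gap columns and all-gap reference columns are skipped (the
    latter tallied to the module logger).
    """
    if query_id not in msa:
        raise KeyError(f"query {query_id!r} not in alignment")
    refs = {name: seq for name, seq in msa.items() if name != query_id}
    if len(refs) < 2:
        raise ValueError("need at least 2 reference rows")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    (length,) = lengths

    query = msa[query_id].upper()
    ref_rows = [s.upper() for s in refs.values()]
    diffs: list[ConsensusDiff] = []
    all_gap_columns = 0
    for col in range(length):
        qbase = query[col]
        if qbase in GAP_CHARS:
            continue
        bases = Counter(
            row[col] for row in ref_rows if row[col] not in GAP_CHARS
        )
        if not bases:
            all_gap_columns += 1
            continue
        n_nongap = sum(bases.values())
        top = max(bases.values())
        consensus = min(b for b, c in bases.items() if c == top)
        freq = top / n_nongap
        if qbase != consensus and freq >= min_consensus_freq:
            diffs.append(ConsensusDiff(col, qbase, consensus, freq))
    if all_gap_columns:
        logger.info("skipped %d all-gap reference columns", all_gap_columns)
    return diffs
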