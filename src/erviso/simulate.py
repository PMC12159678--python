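"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

- a toy provirus locus with three overlapping transcript forms — a long
  form with a distal unique exon, a short form with a 111 bp unique
  region, and a mostly silent canonical LTR-initiated form — embedded in
  a RepeatMasker-style repeat body (5' LTR / internal / 3' LTR);
- a three-group cohort (two tumor groups, one normal) where the long
  transcript is tumor-enriched, the short transcript is flat, and the
  composite gene is a linear mixture of the two plus noise;
- spliced single-end reads drawn uniformly along each transcript with an
  optional multimapper fraction (splice junctions are exact: the read
  counting and junction logic are under test, not aligners);
- beta-binomial-style per-CpG methylation (Poisson coverage, binomial
  modified calls);
- a cell-type-structured count matrix where the long form is restricted
  to designated cell types;
- reference-LTR alignments with planted query substitutions.

Every generator is fully deterministic under its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    QuantRegionSet,
    RepeatFeature,
    TranscriptModel,
    build_quantification_regions,
)
from .decomposition import ContributionRegression, zscore
from .intervals import GenomicInterval, Interval
from .methylation import CpGSiteCall
from .quantify import CountingPolicy, JunctionResult, assign_read, cpm, read_passes
from .reads import AlignedRead
from .single_cell import CellTable

LONG = "ERVK-7.long"
SHORT = "ERVK-7.short"
GENE = "ERVK-7"
CANONICAL = "ERVK-7.canonical"


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Latent log-normal TPM parameters for one cohort group."""

    n: int
    long_meanlog: float
    long_sdlog: float
    short_meanlog: float
    short_sdlog: float
    amp_prevalence: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("each group needs n >= 3")
        if self.long_sdlog < 0 or self.short_sdlog < 0:
            raise ValueError("scales must be >= 0")
        if not 0.0 <= self.amp_prevalence <= 1.0:
            raise ValueError("amp_prevalence must be in [0, 1]")


@dataclass
class CohortSpec:
    """Cohort generator settings.

    The composite gene is built as ``gene = location + scale * (a_star *
    z(long) + b_star * z(short) + noise)`` with z-scores taken over the
    pooled cohort and Gaussian noise of sd ``noise_sd`` on the z-scale.
    ``gene_scale`` is the factor mapping the standardised mixture back to
    TPM units; it is part of the ground truth and makes the mixing
    weights exactly invertible from the original-scale fit.
    """

    groups: dict[str, GroupSpec]
    a_star: float = 0.7
    b_star: float = 0.3
    noise_sd: float = 0.1
    gene_location: float = 50.0
    gene_scale: float = 10.0
    amp_effect: float = 0.5
    tnf_effect: float = 0.3
    ifn_effect: float = 0.3
    seed: int = 0


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Preset mimicking the study cohorts at desk scale.

    Two tumor groups where the long transcript is strongly enriched
    (slightly more so in the squamous group) and one normal group where
    the short transcript dominates; ~10% of tumor genomes carry the
    locus amplification.
    """
    groups = {
        "LUAD": GroupSpec(150, 2.6, 0.6, 2.2, 0.5, amp_prevalence=0.10),
        "LUSC": GroupSpec(150, 2.9, 0.6, 2.0, 0.5, amp_prevalence=0.10),
        "NORMAL": GroupSpec(100, 0.8, 0.6, 2.6, 0.5, amp_prevalence=0.0),
    }
    return CohortSpec(groups=groups, seed=seed, **overrides)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a per-sample table plus the ground-truth record.

    Returns
    -------
    samples:
        DataFrame indexed by sample_id with columns group, tpm_long,
        tpm_short, tpm_gene, copy_number, tnf_score, ifn_score.
    truth:
        Mixing weights, noise/scale parameters and the per-sample
        dominant transcript.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for gname, g in spec.groups.items():
        tnf = rng.standard_normal(g.n)
        ifn = rng.standard_normal(g.n)
        amp = rng.random(g.n) < g.amp_prevalence
        copy_number = np.where(
            amp,
            rng.uniform(3.0, 6.0, g.n),
            np.clip(rng.normal(2.0, 0.15, g.n), 0.5, 2.9),
        )
        log_tl = (
            g.long_meanlog
            + g.long_sdlog * rng.standard_normal(g.n)
            + spec.tnf_effect * tnf
            + spec.amp_effect * amp
        )
        log_ts = (
            g.short_meanlog
            + g.short_sdlog * rng.standard_normal(g.n)
            + spec.ifn_effect * ifn
            + spec.amp_effect * amp
        )
        for i in range(g.n):
            rows.append(
                {
                    "sample_id": f"{gname}_{i:04d}",
                    "group": gname,
                    "tpm_long": float(np.exp(log_tl[i])),
                    "tpm_short": float(np.exp(log_ts[i])),
                    "copy_number": float(copy_number[i]),
                    "tnf_score": float(tnf[i]),
                    "ifn_score": float(ifn[i]),
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")

    try:
        zl = zscore(df["tpm_long"].to_numpy(), "tpm_long")
        zs = zscore(df["tpm_short"].to_numpy(), "tpm_short")
    except ValueError as exc:
        raise ValueError(f"degenerate cohort spec (zero variance): {exc}") from exc
    noise = spec.noise_sd * rng.standard_normal(len(df))
    mixture = spec.a_star * zl + spec.b_star * zs + noise
    gene = spec.gene_location + spec.gene_scale * mixture
    if (gene < 0).any():
        warnings.warn("negative composite TPMs clipped to 0", stacklevel=2)
        gene = np.clip(gene, 0.0, None)
    df["tpm_gene"] = gene

    truth = {
        "a_star": spec.a_star,
        "b_star": spec.b_star,
        "noise_sd": spec.noise_sd,
        "gene_location": spec.gene_location,
        "gene_scale": spec.gene_scale,
        "dominant": pd.Series(
            np.where(
                spec.a_star * df["tpm_long"].to_numpy()
                >= spec.b_star * df["tpm_short"].to_numpy(),
                "long",
                "short",
            ),
            index=df.index,
        ),
    }
    return df, truth


def estimated_mixing_weights(
    fit: ContributionRegression,
    samples: pd.DataFrame,
    spec: CohortSpec,
) -> tuple[float, float]:
    """Invert the fitted original-scale coefficients to mixing weights.

    The generator maps the standardised mixture to TPM units with factor
    ``gene_scale``; the original-scale OLS coefficient on a transcript is
    therefore ``gene_scale * weight / sd(transcript)``.
    """
    sl = float(samples[fit.long_col].std(ddof=1))
    ss = float(samples[fit.short_col].std(ddof=1))
    return (
        fit.raw_coef_long_ * sl / spec.gene_scale,
        fit.raw_coef_short_ * ss / spec.gene_scale,
    )


# --------------------------------------------------------------------------
# locus / reads
# --------------------------------------------------------------------------


def _default_transcripts() -> dict[str, tuple[Interval, ...]]:
    return {
        LONG: ((200, 700), (7400, 7700), (10968, 16000)),
        SHORT: ((7289, 7700), (10968, 16000)),
        CANONICAL: ((10500, 16000),),
    }


def _default_repeats() -> dict[str, Interval]:
    return {
        "LTR5Hs": (10000, 10968),
        "HERVK-int": (10968, 17000),
        "LTR5Hs_3p": (17000, 17968),
    }


def _default_region_rules() -> dict[str, dict]:
    return {
        LONG: {"unique_to": LONG},
        SHORT: {"unique_to": SHORT},
        GENE: {"repeat_body": True},
    }


@dataclass
class LocusSpec:
    """Toy locus geometry and read-generation settings.

    The default geometry mirrors the structure of the real locus: the
    long form carries a distal unique exon (500 bp), the short form a
    111 bp unique region, both splice into the shared internal exon, and
    the canonical form initiates inside the 5' LTR and reads through
    into the internal region.
    """

    chrom: str = "toy1"
    genome_length: int = 20000
    strand: str = "+"
    transcripts: dict[str, tuple[Interval, ...]] = field(default_factory=_default_transcripts)
    repeats: dict[str, Interval] = field(default_factory=_default_repeats)
    region_rules: dict[str, dict] = field(default_factory=_default_region_rules)
    abundances: dict[str, int] = field(
        default_factory=lambda: {LONG: 3000, SHORT: 3000, CANONICAL: 0}
    )
    read_length: int = 75
    multimapper_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.multimapper_fraction <= 1.0:
            raise ValueError("multimapper_fraction must be in [0, 1]")
        for name, exons in self.transcripts.items():
            for s, e in exons:
                if s < 0 or e > self.genome_length:
                    raise ValueError(f"{name}: exon [{s}, {e}) outside toy genome")
        for name, (s, e) in self.repeats.items():
            if s < 0 or e > self.genome_length:
                raise ValueError(f"repeat {name}: interval outside toy genome")


def locus_transcripts(spec: LocusSpec) -> list[TranscriptModel]:
    return [
        TranscriptModel(name, GENE, spec.chrom, spec.strand, list(exons))
        for name, exons in spec.transcripts.items()
    ]


def locus_repeat_features(spec: LocusSpec) -> list[RepeatFeature]:
    return [
        RepeatFeature(name, GenomicInterval(spec.chrom, s, e, spec.strand))
        for name, (s, e) in spec.repeats.items()
    ]


def locus_repeat_body(spec: LocusSpec) -> RepeatFeature:
    start = min(s for s, _ in spec.repeats.values())
    end = max(e for _, e in spec.repeats.values())
    return RepeatFeature(GENE, GenomicInterval(spec.chrom, start, end, spec.strand))


def locus_regions(spec: LocusSpec) -> QuantRegionSet:
    return build_quantification_regions(
        locus_transcripts(spec), locus_repeat_body(spec), spec.region_rules
    )


def _blocks_for(exons: Sequence[Interval], tx_start: int, length: int) -> list[Interval]:
    """Genomic blocks of a read covering [tx_start, tx_start+length) in
    spliced transcript coordinates."""
    blocks: list[Interval] = []
    remaining = length
    offset = tx_start
    for s, e in exons:
        exon_len = e - s
        if offset >= exon_len:
            offset -= exon_len
            continue
        take = min(remaining, exon_len - offset)
        blocks.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past transcript end")
    return blocks


@dataclass
class ReadSimResult:
    reads: list[AlignedRead]
    n_reads: dict[str, int]
    expected_counts: dict[str, float]
    assignment_probs: dict[str, dict[str, float]]  # transcript -> feature -> p


def _assignment_probabilities(
    spec: LocusSpec,
    regions: QuantRegionSet,
    policy: CountingPolicy,
    transcripts: Sequence[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Exact per-transcript feature-assignment probabilities, by
    enumerating every uniform read start on the spliced sequence."""
    probs: dict[str, dict[str, float]] = {}
    for name, exons in spec.transcripts.items():
        if transcripts is not None and name not in transcripts:
            continue
        T = sum(e - s for s, e in exons)
        n_starts = T - spec.read_length + 1
        if n_starts <= 0:
            continue
        tallies = {fid: 0 for fid in regions.feature_ids()}
        for start in range(n_starts):
            blocks = _blocks_for(exons, start, spec.read_length)
            read = AlignedRead("enum", spec.chrom, blocks)
            for fid in assign_read(read, regions, policy):
                tallies[fid] += 1
        probs[name] = {fid: c / n_starts for fid, c in tallies.items()}
    return probs


def simulate_reads(
    spec: LocusSpec,
    regions: QuantRegionSet | None = None,
    policy: CountingPolicy | None = None,
    compute_expected: bool = True,
) -> ReadSimResult:
    """Draw spliced reads and compute the exact expected feature counts.

    Reads start uniformly along each transcript's spliced sequence and
    map to genomic blocks across exon junctions; a configured fraction
    is flagged non-unique (NH=2, mapq 0).  Expected counts are abundance
    x exact assignment probability x the fraction surviving the policy's
    uniqueness/quality filters.
    """
    policy = policy or CountingPolicy()
    regions = regions or locus_regions(spec)
    rng = np.random.default_rng(spec.seed)
    reads: list[AlignedRead] = []
    n_reads: dict[str, int] = {}
    for name, exons in spec.transcripts.items():
        n = int(spec.abundances.get(name, 0))
        n_reads[name] = n
        if n == 0:
            continue
        T = sum(e - s for s, e in exons)
        if spec.read_length > T:
            raise ValueError(
                f"read length {spec.read_length} exceeds spliced length {T} of {name}"
            )
        starts = rng.integers(0, T - spec.read_length + 1, size=n)
        multi = rng.random(n) < spec.multimapper_fraction
        for i in range(n):
            blocks = _blocks_for(exons, int(starts[i]), spec.read_length)
            reads.append(
                AlignedRead(
                    read_id=f"{name}:{i}",
                    chrom=spec.chrom,
                    blocks=blocks,
                    is_unique=not multi[i],
                    mapq=0 if multi[i] else 60,
                )
            )
    if not compute_expected:
        return ReadSimResult(reads, n_reads, {}, {})
    expressed = [t for t, n in n_reads.items() if n > 0]
    probs = _assignment_probabilities(spec, regions, policy, transcripts=expressed)
    template_multi = AlignedRead("m", spec.chrom, [(0, 1)], is_unique=False, mapq=0)
    keep_multi = 1.0 if read_passes(template_multi, policy) else 0.0
    survive = (1.0 - spec.multimapper_fraction) + spec.multimapper_fraction * keep_multi
    expected = {
        fid: sum(n_reads[t] * survive * probs[t].get(fid, 0.0) for t in probs)
        for fid in regions.feature_ids()
    }
    return ReadSimResult(reads, n_reads, expected, probs)


def junction_span_probability(
    spec: LocusSpec,
    transcript: str,
    region_a,
    region_b,
) -> float:
    """Exact probability that a uniform read from ``transcript`` has
    blocks overlapping both regions."""
    from .quantify import find_junction_reads

    exons = spec.transcripts[transcript]
    T = sum(e - s for s, e in exons)
    n_starts = T - spec.read_length + 1
    if n_starts <= 0:
        return 0.0
    hits = 0
    for start in range(n_starts):
        blocks = _blocks_for(exons, start, spec.read_length)
        read = AlignedRead("enum", spec.chrom, blocks)
        n, _ = find_junction_reads([read], region_a, region_b)
        hits += n
    return hits / n_starts


# --------------------------------------------------------------------------
# junction-activity cohort
# --------------------------------------------------------------------------


def simulate_junction_cohort(
    n_samples: int = 114,
    n_active: int = 11,
    extra_rate: float = 0.1,
    library_size: int = 20_000_000,
    seed: int = 0,
) -> list[JunctionResult]:
    """Junction-read counts across a panel of samples/cell types.

    An active sample is one whose canonical LTR produced at least one
    observable junction read; active samples draw ``1 + Poisson(extra_rate)``
    junction reads (shallow capture: the default gives a mean of ~1.1
    reads, i.e. ~0.05 CPM in a 20 M-read library), inactive samples draw
    none.
    """
    if n_active > n_samples:
        raise ValueError("n_active cannot exceed n_samples")
    rng = np.random.default_rng(seed)
    active_idx = set(rng.choice(n_samples, size=n_active, replace=False).tolist())
    results = []
    for i in range(n_samples):
        count = int(1 + rng.poisson(extra_rate)) if i in active_idx else 0
        results.append(
            JunctionResult(
                sample_id=f"sample_{i:03d}",
                junction_count=count,
                cpm=cpm(count, library_size),
            )
        )
    return results


# --------------------------------------------------------------------------
# methylation
# --------------------------------------------------------------------------


def simulate_methylation(
    region: GenomicInterval,
    n_sites: int = 200,
    true_p: float = 0.8,
    coverage_mean: float = 30.0,
    seed: int = 0,
) -> list[CpGSiteCall]:
    """Per-CpG calls: coverage ~ Poisson(coverage_mean), modified calls ~
    Binomial(coverage, true_p)."""
    if not 0.0 <= true_p <= 1.0:
        raise ValueError("true_p must be in [0, 1]")
    if n_sites > len(region):
        raise ValueError("more sites requested than bases in the region")
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(np.arange(region.start, region.end), size=n_sites, replace=False)
    )
    coverage = rng.poisson(coverage_mean, size=n_sites)
    modified = rng.binomial(coverage, true_p)
    calls = []
    for pos, cov, mod in zip(positions, coverage, modified):
        frac = mod / cov if cov > 0 else 0.0
        calls.append(CpGSiteCall(region.chrom, int(pos), "+", int(cov), float(frac)))
    return calls


# --------------------------------------------------------------------------
# single cell
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CellTypeSpec:
    """Per-cell-type abundance and expression settings.

    ``tissue_weight`` gives the relative abundance of the type in each
    tissue; ``expression`` maps feature -> (expressing probability,
    mean extra count), counts for expressing cells being 1 + Poisson(mean).
    """

    broad: str
    tissue_weight: Mapping[str, float]
    expression: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for feat, (p, _mean) in self.expression.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"expression probability for {feat!r} outside [0, 1]")
        for tissue, w in self.tissue_weight.items():
            if w < 0:
                raise ValueError(f"negative tissue weight for {tissue!r}")


def default_cell_type_specs() -> dict[str, CellTypeSpec]:
    """Preset: the long form restricted to tumor, AT2 and fibroblast cells
    (expressing fractions ~0.107 / 0.011 / 0.037), the short form and the
    composite gene expressed across all types; tumor cells only in tumor
    tissue."""
    return {
        "tumor": CellTypeSpec(
            "tumor",
            {"tumor": 0.35, "normal": 0.0},
            {LONG: (0.107, 8.0), SHORT: (0.08, 1.0), GENE: (0.10, 1.5)},
        ),
        "AT2": CellTypeSpec(
            "epithelial",
            {"tumor": 0.10, "normal": 0.30},
            {LONG: (0.0108, 1.0), SHORT: (0.06, 1.0), GENE: (0.08, 1.0)},
        ),
        "fibroblast": CellTypeSpec(
            "fibroblast",
            {"tumor": 0.15, "normal": 0.15},
            {LONG: (0.0372, 1.0), SHORT: (0.05, 1.0), GENE: (0.07, 1.0)},
        ),
        "immune": CellTypeSpec(
            "immune",
            {"tumor": 0.30, "normal": 0.35},
            {LONG: (0.0, 0.0), SHORT: (0.09, 1.0), GENE: (0.09, 1.0)},
        ),
        "endothelial": CellTypeSpec(
            "endothelial",
            {"tumor": 0.10, "normal": 0.20},
            {LONG: (0.0, 0.0), SHORT: (0.05, 1.0), GENE: (0.05, 1.0)},
        ),
    }


def simulate_cell_matrix(
    cell_type_specs: Mapping[str, CellTypeSpec] | None = None,
    n_patients: int = 12,
    cells_per_patient: int = 800,
    tumor_fraction: float = 0.5,
    seed: int = 0,
) -> CellTable:
    """Generate a cell-type-structured raw count matrix with metadata."""
    specs = dict(cell_type_specs or default_cell_type_specs())
    features = sorted({f for s in specs.values() for f in s.expression})
    rng = np.random.default_rng(seed)
    n_tumor = int(round(n_patients * tumor_fraction))

    cell_ids: list[str] = []
    obs_rows: list[dict] = []
    count_rows: list[list[int]] = []
    for p in range(n_patients):
        patient = f"P{p:02d}"
        tissue = "tumor" if p < n_tumor else "normal"
        names = [t for t in specs if specs[t].tissue_weight.get(tissue, 0.0) > 0]
        weights = np.array([specs[t].tissue_weight[tissue] for t in names], dtype=float)
        weights /= weights.sum()
        types = rng.choice(names, size=cells_per_patient, p=weights)
        for i, ct in enumerate(types):
            spec = specs[ct]
            row = []
            for feat in features:
                prob, mean = spec.expression.get(feat, (0.0, 0.0))
                if rng.random() < prob:
                    row.append(1 + int(rng.poisson(mean)))
                else:
                    row.append(0)
            cell_ids.append(f"{patient}_c{i:04d}")
            obs_rows.append(
                {
                    "cell_type": spec.broad,
                    "cell_type_detail": ct,
                    "patient_id": patient,
                    "tissue": tissue,
                }
            )
            count_rows.append(row)
    counts = pd.DataFrame(count_rows, index=cell_ids, columns=features, dtype=int)
    obs = pd.DataFrame(obs_rows, index=cell_ids)
    return CellTable(counts, obs)


# --------------------------------------------------------------------------
# MSA
# --------------------------------------------------------------------------

_BASES = "ACGT"


def simulate_msa(
    n_refs: int = 10,
    length: int = 60,
    substitution_plan: Sequence[tuple[int, str]] = (),
    noise_rate: float = 0.02,
    query_id: str = "query",
    seed: int = 0,
) -> dict[str, str]:
    """Reference rows drawn from a shared consensus with small noise; the
    query equals the consensus except at the planted substitutions.

    At each planted column the consensus is forced to differ from the
    planted base (T where possible), so the plan is guaranteed to create
    a divergence.
    """
    rng = np.random.default_rng(seed)
    consensus = list(rng.choice(list(_BASES), size=length))
    for col, base in substitution_plan:
        if not 0 <= col < length:
            raise ValueError(f"planted column {col} outside alignment of length {length}")
        if base not in _BASES:
            raise ValueError(f"planted base {base!r} not a nucleotide")
        consensus[col] = next(b for b in "TACG" if b != base)
    msa: dict[str, str] = {}
    for r in range(n_refs):
        row = []
        for col in range(length):
            if rng.random() < noise_rate:
                row.append(rng.choice([b for b in _BASES if b != consensus[col]]))
            else:
                row.append(consensus[col])
        msa[f"ref{r:02d}"] = "".join(row)
    query = list(consensus)
    for col, base in substitution_plan:
        query[col] = base
    msa[query_id] = "".join(query)
    return msa
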