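"""Read counting vs a per-base double-loop oracle; TPM/CPM; junction logic."""

import numpy as np
import pandas as pd
import pytest

from erviso.annotation import QuantRegionSet
from erviso.quantify import (
    CountingPolicy,
    CountTable,
    JunctionResult,
    classify_ltr_activity,
    count_reads,
    cpm,
    find_junction_reads,
    tpm_normalize,
)
from erviso.reads import AlignedRead


def read(rid, blocks, unique=True, mapq=60, chrom="chrA"):
    return AlignedRead(rid, chrom, blocks, is_unique=unique, mapq=mapq)


# ---------------------------------------------------------------- oracle ----


def oracle_counts(reads, regions, policy, genome=10_000):
    """Independent per-base, per-read, per-feature double loop."""
    masks = {}
    for fid, ivs in regions.features.items():
        m = np.zeros(genome, dtype=bool)
        for s, e in ivs:
            m[s:e] = True
        masks[fid] = m
    counts = {fid: 0 for fid in regions.features}
    for r in reads:
        if policy.unique_only and not r.is_unique:
            continue
        if r.mapq < policy.min_mapq:
            continue
        if r.chrom != regions.chrom:
            continue
        hits = []
        for fid, m in masks.items():
            if any(int(m[s:e].sum()) >= policy.min_overlap_bases for s, e in r.blocks):
                hits.append(fid)
        if len(hits) > 1 and not policy.allow_multioverlap:
            continue
        for fid in hits:
            counts[fid] += 1
    return counts


def random_instance(rng, n_reads=1000, n_features=10, genome=10_000):
    features = {}
    for i in range(n_features):
        n_iv = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(genome, size=2 * n_iv, replace=False))
        features[f"f{i}"] = [
            (int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n_iv)
        ]
    regions = QuantRegionSet("chrA", features)
    reads = []
    for j in range(n_reads):
        n_bl = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(genome, size=2 * n_bl, replace=False))
        blocks = [(int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n_bl)]
        unique = bool(rng.random() < 0.8)
        mapq = 60 if unique else int(rng.integers(0, 31))
        reads.append(read(f"r{j}", blocks, unique=unique, mapq=mapq))
    return reads, regions


# --------------------------------------------------------------- counting ---


class TestCountReads:
    def test_containment(self):
        regions = QuantRegionSet("chrA", {"A": [(0, 100)]})
        table = count_reads({"s": [read("r1", [(10, 30)])]}, regions)
        assert table.counts.at["A", "s"] == 1

    def test_ambiguity_policy(self):
        regions = QuantRegionSet("chrA", {"A": [(0, 50)], "B": [(190, 250)]})
        spliced = [read("r1", [(10, 20), (200, 210)])]
        strict = count_reads({"s": spliced}, regions, CountingPolicy())
        assert strict.counts["s"].sum() == 0  # discarded as ambiguous
        loose = count_reads(
            {"s": spliced}, regions, CountingPolicy(allow_multioverlap=True)
        )
        assert loose.counts.at["A", "s"] == 1 and loose.counts.at["B", "s"] == 1

    def test_unknown_chromosome_skipped_not_error(self):
        regions = QuantRegionSet("chrA", {"A": [(0, 100)]})
        table = count_reads({"s": [read("r1", [(0, 50)], chrom="chrZ")]}, regions)
        assert table.counts["s"].sum() == 0
        assert table.skipped_unknown_chrom["s"] == 1

    @pytest.mark.parametrize("unique_only", [True, False])
    @pytest.mark.parametrize("allow_multioverlap", [True, False])
    def test_matches_double_loop_oracle(self, unique_only, allow_multioverlap):
        rng = np.random.default_rng(42)
        reads, regions = random_instance(rng, n_reads=2000)
        policy = CountingPolicy(
            unique_only=unique_only,
            min_mapq=30 if unique_only else 0,
            allow_multioverlap=allow_multioverlap,
        )
        table = count_reads({"s": reads}, regions, policy)
        assert table.counts["s"].to_dict() == oracle_counts(reads, regions, policy)

    def test_removing_multimappers_never_increases_counts(self):
        rng = np.random.default_rng(5)
        reads, regions = random_instance(rng, n_reads=500)
        strict = count_reads(
            {"s": reads}, regions, CountingPolicy(unique_only=True, min_mapq=0)
        ).counts["s"]
        loose = count_reads(
            {"s": reads}, regions, CountingPolicy(unique_only=False, min_mapq=0)
        ).counts["s"]
        assert (strict <= loose).all()


# -------------------------------------------------------------------- TPM ---


class TestTPM:
    def test_length_ratio(self):
        counts = pd.DataFrame({"s": [100, 100]}, index=["a", "b"])
        tpm = tpm_normalize(counts, {"a": 1000, "b": 2000})
        assert tpm.at["a", "s"] == pytest.approx(2e6 / 3)
        assert tpm.at["b", "s"] == pytest.approx(1e6 / 3)

    def test_single_feature_is_one_million(self):
        counts = pd.DataFrame({"s": [7]}, index=["a"])
        assert tpm_normalize(counts, {"a": 500}).at["a", "s"] == pytest.approx(1e6)

    def test_conservation_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(20, 8)),
            index=[f"f{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(8)],
        )
        lengths = {f"f{i}": int(rng.integers(200, 5000)) for i in range(20)}
        tpm = tpm_normalize(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)
        np.testing.assert_allclose(
            tpm_normalize(counts * 3, lengths).to_numpy(), tpm.to_numpy(), rtol=1e-12
        )

    def test_zero_rate_sample_warns_and_zeroes(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="zero total rate"):
            tpm = tpm_normalize(counts, {"a": 100, "b": 100})
        assert (tpm["s"] == 0).all()

    def test_missing_length_errors(self):
        counts = pd.DataFrame({"s": [1]}, index=["a"])
        with pytest.raises(KeyError):
            tpm_normalize(counts, {})


def test_cpm():
    assert cpm(1, 20_000_000) == pytest.approx(0.05)
    assert cpm(0, 1000) == 0.0
    assert cpm(5, 1_000_000) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        cpm(1, 0)


# -------------------------------------------------------------- junctions ---


class TestJunctions:
    A = (0, 10)
    B = (12, 20)

    def test_single_block_readthrough_counted(self):
        n, ids = find_junction_reads([read("r1", [(5, 15)])], self.A, self.B)
        assert n == 1 and ids == ["r1"]

    def test_read_missing_one_side_not_counted(self):
        n, _ = find_junction_reads([read("r1", [(0, 8), (50, 60)])], self.A, self.B)
        assert n == 0

    def test_spliced_read_spanning_both_counted(self):
        n, _ = find_junction_reads([read("r1", [(5, 9), (13, 18)])], self.A, self.B)
        assert n == 1

    def test_overlapping_regions_error(self):
        with pytest.raises(ValueError, match="disjoint"):
            find_junction_reads([], (0, 10), (5, 15))

    def test_exon_union_accepted_as_side(self):
        n, _ = find_junction_reads(
            [read("r1", [(25, 35), (100, 110)])], [(0, 10), (20, 30)], (100, 200)
        )
        assert n == 1

    def test_junction_set_subset_of_individual_hits(self):
        rng = np.random.default_rng(9)
        reads = []
        for j in range(500):
            cuts = np.sort(rng.choice(1000, size=4, replace=False))
            reads.append(read(f"r{j}", [(int(cuts[0]), int(cuts[1])), (int(cuts[2]), int(cuts[3]))]))
        a, b = (100, 300), (600, 800)
        _, junction_ids = find_junction_reads(reads, a, b)
        hits_a = {r.read_id for r in reads if any(max(s, a[0]) < min(e, a[1]) for s, e in r.blocks)}
        hits_b = {r.read_id for r in reads if any(max(s, b[0]) < min(e, b[1]) for s, e in r.blocks)}
        assert set(junction_ids) <= (hits_a & hits_b)


class TestClassifyActivity:
    def make(self, counts, lib=20_000_000):
        return [
            JunctionResult(f"s{i}", c, cpm(c, lib)) for i, c in enumerate(counts)
        ]

    def test_threshold_one(self):
        flags, summary = classify_ltr_activity(self.make([0, 0, 3, 1]))
        assert [f for _, f in flags] == [False, False, True, True]
        assert summary["n_active"] == 2

    def test_all_zero(self):
        _, summary = classify_ltr_activity(self.make([0, 0, 0]))
        assert summary["n_active"] == 0 and summary["mean_cpm"] == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classify_ltr_activity([])
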