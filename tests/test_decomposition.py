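"""Contribution decomposition, driver regression and group statistics."""

import numpy as np
import pandas as pd
import pytest

from erviso.decomposition import (
    ContributionRegression,
    DriverRegression,
    contribution_log_ratio,
    fit_contribution_model,
    fit_driver_model,
    group_compare,
    zscore,
)
from erviso import simulate as sim


def one_group_spec(n=500, noise_sd=0.1, seed=0, **kw):
    return sim.CohortSpec(
        groups={"ALL": sim.GroupSpec(n, 2.5, 0.6, 2.0, 0.5)},
        noise_sd=noise_sd,
        seed=seed,
        **kw,
    )


class TestZscore:
    def test_symmetric_triple(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(5, 3, size=50)
            z = zscore(x)
            assert abs(z.mean()) < 1e-12
            assert z.std(ddof=1) == pytest.approx(1.0)
            np.testing.assert_allclose(z, (x - x.mean()) / x.std(ddof=1))

    def test_constant_vector_names_variable(self):
        with pytest.raises(ValueError, match="tpm_long"):
            zscore([2, 2, 2], name="tpm_long")


class TestContributionFit:
    def test_noiseless_mixture_recovered_exactly(self):
        """With zero noise the original-scale fit inverts to the true
        mixing weights to 1e-8 and R^2 = 1."""
        spec = one_group_spec(noise_sd=0.0, seed=4)
        samples, truth = sim.simulate_cohort(spec)
        fit = fit_contribution_model(samples)
        a_hat, b_hat = sim.estimated_mixing_weights(fit, samples, spec)
        assert a_hat == pytest.approx(truth["a_star"], abs=1e-8)
        assert b_hat == pytest.approx(truth["b_star"], abs=1e-8)
        assert fit.r_squared_ == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept_ == pytest.approx(0.0, abs=1e-10)

    def test_gene_equals_long_identity_limit(self):
        rng = np.random.default_rng(1)
        samples = pd.DataFrame(
            {
                "tpm_long": rng.lognormal(2, 0.5, 300),
                "tpm_short": rng.lognormal(2, 0.5, 300),
            }
        )
        samples["tpm_gene"] = samples["tpm_long"]
        fit = fit_contribution_model(samples)
        assert fit.a_ == pytest.approx(1.0, abs=1e-8)
        assert fit.b_ == pytest.approx(0.0, abs=1e-8)

    def test_monte_carlo_recovery(self):
        """Mean absolute mixing-weight error small over repeated cohorts."""
        errs = []
        for seed in range(20):
            spec = one_group_spec(seed=seed)
            samples, truth = sim.simulate_cohort(spec)
            fit = fit_contribution_model(samples)
            a_hat, b_hat = sim.estimated_mixing_weights(fit, samples, spec)
            errs.append(abs(a_hat - truth["a_star"]))
        assert np.mean(errs) <= 0.02

    def test_matches_pseudoinverse_oracle(self):
        samples, _ = sim.simulate_cohort(one_group_spec(seed=9))
        fit = fit_contribution_model(samples)
        zl = zscore(samples["tpm_long"].to_numpy())
        zs = zscore(samples["tpm_short"].to_numpy())
        zg = zscore(samples["tpm_gene"].to_numpy())
        design = np.column_stack([zl, zs, np.ones(len(samples))])
        coef = np.linalg.pinv(design) @ zg
        np.testing.assert_allclose([fit.a_, fit.b_, fit.intercept_], coef, atol=1e-10)

    def test_collinear_predictors_error(self):
        samples = pd.DataFrame(
            {"tpm_long": [1.0, 2, 3, 4], "tpm_short": [2.0, 4, 6, 8], "tpm_gene": [1.0, 2, 3, 5]}
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_contribution_model(samples)

    def test_too_few_samples(self):
        samples = pd.DataFrame({"tpm_long": [1, 2], "tpm_short": [2, 1], "tpm_gene": [1, 1]})
        with pytest.raises(ValueError, match="at least 3"):
            fit_contribution_model(samples)


class TestLogRatio:
    def fitted(self, a=1.0, b=1.0):
        m = ContributionRegression()
        m.a_, m.b_, m.intercept_ = a, b, 0.0
        m.r_squared_, m.n_samples_, m.degenerate_ = 1.0, 10, bool(a <= 0 or b <= 0)
        return m

    def test_symmetric_case_is_zero(self):
        df = pd.DataFrame({"tpm_long": [10.0], "tpm_short": [10.0]})
        out = self.fitted(0.5, 0.5).transform(df, epsilon=1e-12)
        assert out["log_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_direct_arithmetic(self):
        df = pd.DataFrame({"tpm_long": [20.0], "tpm_short": [5.0]})
        out = self.fitted(1.0, 1.0).transform(df, epsilon=0.01)
        assert out["log_ratio"].iloc[0] == pytest.approx(np.log2(20.01 / 5.01))

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"tpm_long": rng.lognormal(1, 1, 50), "tpm_short": rng.lognormal(1, 1, 50)}
        )
        fwd = self.fitted(0.7, 0.3).transform(df)["log_ratio"]
        swapped = df.rename(columns={"tpm_long": "tpm_short", "tpm_short": "tpm_long"})
        rev = self.fitted(0.3, 0.7).transform(swapped)["log_ratio"]
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_monotone_in_each_transcript(self):
        base = pd.DataFrame({"tpm_long": [10.0], "tpm_short": [10.0]})
        up_long = pd.DataFrame({"tpm_long": [20.0], "tpm_short": [10.0]})
        up_short = pd.DataFrame({"tpm_long": [10.0], "tpm_short": [20.0]})
        m = self.fitted(0.7, 0.3)
        r0 = m.transform(base)["log_ratio"].iloc[0]
        assert m.transform(up_long)["log_ratio"].iloc[0] > r0
        assert m.transform(up_short)["log_ratio"].iloc[0] < r0

    def test_degenerate_coefficients_flagged_not_fatal(self):
        rng = np.random.default_rng(6)
        n = 100
        samples = pd.DataFrame(
            {
                "tpm_long": rng.lognormal(2, 0.5, n),
                "tpm_short": rng.lognormal(2, 0.5, n),
            }
        )
        # gene anti-correlated with short -> negative b
        samples["tpm_gene"] = (
            10 * samples["tpm_long"].rank() - 5 * samples["tpm_short"].rank()
        ).clip(lower=0)
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_contribution_model(samples)
        out = contribution_log_ratio(fit, samples)
        assert out["degenerate"].all()
        assert np.isfinite(out["log_ratio"]).all()

    def test_sign_pattern_tumor_vs_normal(self):
        """Tumor groups (long-dominant) get positive mean log-ratio, the
        normal group (short-dominant) negative."""
        samples, _ = sim.simulate_cohort(sim.default_cohort_spec(seed=17))
        fit = fit_contribution_model(samples)
        out = fit.transform(samples).join(samples["group"])
        means = out.groupby("group")["log_ratio"].mean()
        assert means["LUAD"] > 0 and means["LUSC"] > 0
        assert means["NORMAL"] < 0


class TestDriverModel:
    def cohort(self, n=400, seed=0, effect=2.0, noise=0.1):
        rng = np.random.default_rng(seed)
        amp = rng.random(n) < 0.3
        df = pd.DataFrame(
            {
                "copy_number": np.where(amp, rng.uniform(3, 6, n), rng.uniform(1.5, 2.9, n)),
                "tnf_score": rng.standard_normal(n),
                "ifn_score": rng.standard_normal(n),
            }
        )
        df["tpm_gene"] = effect * amp + rng.normal(0, noise, n)
        df["tpm_gene"] -= df["tpm_gene"].min()  # keep TPMs non-negative
        return df, amp

    def test_amplification_cutoff_boundary(self):
        df, _ = self.cohort()
        df.loc[df.index[:2], "copy_number"] = [3.0, 2.99]
        fit = DriverRegression().fit(df)
        amplified = (df["copy_number"] >= fit.amplification_cutoff)
        assert bool(amplified.iloc[0]) and not bool(amplified.iloc[1])

    def test_recovers_amplification_effect(self):
        """The z-scale coefficient, de-standardised analytically, matches
        the constructed effect size."""
        df, amp = self.cohort(effect=2.0, noise=0.1, seed=3)
        fit = fit_driver_model(df)
        sd_out = df["tpm_gene"].std(ddof=1)
        est = fit.coef_["amplified"] * sd_out
        assert est == pytest.approx(2.0, abs=0.1)
        assert fit.pvalues_["amplified"] < 1e-10

    def test_constant_indicator_dropped_with_warning(self):
        df, _ = self.cohort()
        df["copy_number"] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_driver_model(df)
        assert "amplified" in fit.dropped_
        assert "amplified" not in fit.coef_.index

    def test_null_covariates_have_small_coefficients(self):
        rng = np.random.default_rng(8)
        n = 300
        df = pd.DataFrame(
            {
                "copy_number": rng.uniform(1.5, 4, n),
                "tnf_score": rng.standard_normal(n),
                "ifn_score": rng.standard_normal(n),
                "tpm_gene": rng.lognormal(1, 0.5, n),
            }
        )
        fit = fit_driver_model(df)
        assert (fit.coef_.abs() <= 0.2).all()


class TestGroupCompare:
    def test_identical_groups(self):
        t, p = group_compare([1, 2, 3, 4], [1, 2, 3, 4], test="student_t")
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_monotone_spearman(self):
        rho, _ = group_compare([1, 5, 9, 20], [2, 3, 40, 41], test="spearman")
        assert rho == pytest.approx(1.0)

    def test_paired_t_on_differences(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = x + np.array([1.0, 1.1, 0.9, 1.05, 0.95])
        t, p = group_compare(x, y, test="paired_t")
        assert t < 0 and p < 1e-4

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_compare([], [1, 2], test="student_t")

    def test_type_one_error_calibrated(self):
        """Under the null, the pooled-variance t test rejects at ~alpha."""
        rng = np.random.default_rng(21)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            _, p = group_compare(
                rng.standard_normal(50), rng.standard_normal(50), test="student_t"
            )
            rejections += p < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.025)
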