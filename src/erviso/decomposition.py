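"""Transcript-contribution decomposition and driver regression.

The composite gene signal of the locus is modelled as a linear mixture of
its two overlapping transcripts::

    a * long + b * short + c = gene

fitted by ordinary least squares on z-scored TPM values.  The fitted
coefficients then act as normalisation factors on each sample's raw TPMs,
and the per-sample statistic

    log2((a * tpm_long + eps) / (b * tpm_short + eps))

quantifies which transcript drives the composite expression in that
sample (positive: the long form dominates; negative: the short form).

Because the outcome is standardised, the z-scale coefficients (a, b) are
only identified up to the scale of the standardised mixture; the fit
therefore also exposes the algebraically equivalent original-scale OLS
coefficients (``raw_coef_*``), which are what a generative mixture's
weights map onto exactly.

A second multivariable regression relates the locus expression to its
candidate drivers: a binary copy-number-amplification indicator
(amplified when copy number >= 3) and z-scored pathway activity scores
(TNF receptor and IFN-gamma signalling), with two-sided t-test p-values.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "zscore",
    "ContributionRegression",
    "DriverRegression",
    "fit_contribution_model",
    "contribution_log_ratio",
    "fit_driver_model",
    "group_compare",
    "read_sample_table",
]


def zscore(values, name: str = "values", ddof: int = 1) -> np.ndarray:
    """Standardise to mean 0, sd 1 (sample sd, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("zscore expects a 1-D vector")
    if x.size < 2:
        raise ValueError(f"{name}: need at least 2 values to z-score")
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"{name}: constant (or non-finite) vector cannot be z-scored")
    return (x - x.mean()) / sd


def _check_tpm_columns(samples: pd.DataFrame, cols: Sequence[str]) -> None:
    for col in cols:
        if col not in samples.columns:
            raise KeyError(f"sample table lacks column {col!r}")
        vals = samples[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"column {col!r} contains non-finite values")
        if (vals < 0).any():
            raise ValueError(f"column {col!r} contains negative TPM values")


class ContributionRegression(BaseEstimator):
    """OLS decomposition of composite gene TPM onto two transcript TPMs.

    Parameters
    ----------
    long_col, short_col, gene_col:
        Column names in the sample table.
    epsilon:
        Pseudocount guarding the log-ratio against zeros (TPM units).

    Attributes
    ----------
    a_, b_, intercept_:
        Coefficients on the z-scale (all three variables standardised).
    raw_coef_long_, raw_coef_short_, raw_intercept_:
        Equivalent coefficients on the original TPM scale.
    r_squared_ : float
    n_samples_ : int
    degenerate_ : bool
        True when a_ <= 0 or b_ <= 0; the log-ratio is still computed
        (epsilon-guarded) but flagged.
    """

    def __init__(
        self,
        long_col: str = "tpm_long",
        short_col: str = "tpm_short",
        gene_col: str = "tpm_gene",
        epsilon: float = 0.01,
    ):
        self.long_col = long_col
        self.short_col = short_col
        self.gene_col = gene_col
        self.epsilon = epsilon

    def fit(self, X: pd.DataFrame, y=None) -> "ContributionRegression":
        cols = [self.long_col, self.short_col, self.gene_col]
        _check_tpm_columns(X, cols)
        n = len(X)
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        tl = X[self.long_col].to_numpy(dtype=float)
        ts = X[self.short_col].to_numpy(dtype=float)
        tg = X[self.gene_col].to_numpy(dtype=float)
        zl = zscore(tl, self.long_col)
        zs = zscore(ts, self.short_col)
        zg = zscore(tg, self.gene_col)
        if abs(np.corrcoef(zl, zs)[0, 1]) > 1 - 1e-12:
            raise ValueError("predictors are perfectly collinear")

        design_z = np.column_stack([zl, zs, np.ones(n)])
        coef_z, *_ = np.linalg.lstsq(design_z, zg, rcond=None)
        self.a_, self.b_, self.intercept_ = map(float, coef_z)

        design_raw = np.column_stack([tl, ts, np.ones(n)])
        coef_raw, *_ = np.linalg.lstsq(design_raw, tg, rcond=None)
        self.raw_coef_long_, self.raw_coef_short_, self.raw_intercept_ = map(float, coef_raw)

        resid = zg - design_z @ coef_z
        sst = float(((zg - zg.mean()) ** 2).sum())
        self.r_squared_ = float(max(0.0, min(1.0, 1.0 - (resid @ resid) / sst)))
        self.n_samples_ = n
        self.degenerate_ = bool(self.a_ <= 0 or self.b_ <= 0)
        if self.degenerate_:
            warnings.warn(
                "non-positive fitted coefficient(s); per-sample ratios are flagged degenerate",
                stacklevel=2,
            )
        return self

    def transform(self, X: pd.DataFrame, epsilon: float | None = None) -> pd.DataFrame:
        """Per-sample coefficient-normalised TPMs and contribution log-ratio."""
        if not hasattr(self, "a_"):
            raise RuntimeError("ContributionRegression is not fitted")
        eps = self.epsilon if epsilon is None else epsilon
        if eps <= 0:
            raise ValueError("epsilon must be positive")
        _check_tpm_columns(X, [self.long_col, self.short_col])
        norm_long = self.a_ * X[self.long_col].to_numpy(dtype=float)
        norm_short = self.b_ * X[self.short_col].to_numpy(dtype=float)
        # the epsilon guard also floors negative (degenerate-coefficient)
        # values at zero so the ratio stays finite
        log_ratio = np.log2(
            (np.maximum(norm_long, 0.0) + eps) / (np.maximum(norm_short, 0.0) + eps)
        )
        return pd.DataFrame(
            {
                "normalized_long": norm_long,
                "normalized_short": norm_short,
                "log_ratio": log_ratio,
                "degenerate": self.degenerate_,
            },
            index=X.index,
        )

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def fit_contribution_model(
    samples: pd.DataFrame,
    fit_on: pd.Series | np.ndarray | None = None,
    **params,
) -> ContributionRegression:
    """Fit the contribution decomposition, optionally on a sample subset.

    ``fit_on`` is a boolean mask restricting which samples enter the fit
    (default: pooled over the whole table, the single normalisation
    implied by applying one pair of coefficients to every patient).
    """
    model = ContributionRegression(**params)
    if fit_on is not None:
        samples = samples.loc[np.asarray(fit_on, dtype=bool)]
    return model.fit(samples)


def contribution_log_ratio(
    fit: ContributionRegression,
    samples: pd.DataFrame,
    epsilon: float | None = None,
) -> pd.DataFrame:
    return fit.transform(samples, epsilon=epsilon)


class DriverRegression(BaseEstimator):
    """Multivariable OLS of locus expression on its candidate drivers.

    The copy-number column is binarised at ``amplification_cutoff``
    (amplified: copy number >= cutoff); the outcome and the continuous
    pathway scores are z-scored; the binary indicator enters untouched.
    If the cohort is all-amplified or none-amplified the indicator is
    dropped with a warning.
    """

    def __init__(
        self,
        outcome_col: str = "tpm_gene",
        pathway_cols: Sequence[str] = ("tnf_score", "ifn_score"),
        copy_number_col: str = "copy_number",
        amplification_cutoff: float = 3.0,
    ):
        self.outcome_col = outcome_col
        self.pathway_cols = pathway_cols
        self.copy_number_col = copy_number_col
        self.amplification_cutoff = amplification_cutoff

    def fit(self, X: pd.DataFrame, y=None) -> "DriverRegression":
        for col in [self.outcome_col, self.copy_number_col, *self.pathway_cols]:
            if col not in X.columns:
                raise KeyError(f"sample table lacks column {col!r}")
            if X[col].isna().any():
                raise ValueError(f"column {col!r} has missing values")
        outcome = zscore(X[self.outcome_col].to_numpy(dtype=float), self.outcome_col)
        amplified = (
            X[self.copy_number_col].to_numpy(dtype=float) >= self.amplification_cutoff
        ).astype(float)

        design: dict[str, np.ndarray] = {}
        self.dropped_: list[str] = []
        if amplified.min() == amplified.max():
            warnings.warn(
                "amplification indicator is constant; dropped from the driver model",
                stacklevel=2,
            )
            self.dropped_.append("amplified")
        else:
            design["amplified"] = amplified
        for col in self.pathway_cols:
            design[col] = zscore(X[col].to_numpy(dtype=float), col)
        if not design:
            raise ValueError("no non-constant covariates left")

        exog = sm.add_constant(pd.DataFrame(design, index=X.index))
        res = sm.OLS(outcome, exog).fit()
        self.result_ = res
        self.coef_ = res.params.drop("const")
        self.intercept_ = float(res.params["const"])
        self.pvalues_ = res.pvalues.drop("const")
        self.n_samples_ = int(res.nobs)
        return self

    def summary_frame(self) -> pd.DataFrame:
        if not hasattr(self, "coef_"):
            raise RuntimeError("DriverRegression is not fitted")
        return pd.DataFrame({"coefficient": self.coef_, "p_value": self.pvalues_})


def fit_driver_model(
    samples: pd.DataFrame,
    amplification_cutoff: float = 3.0,
    **params,
) -> DriverRegression:
    return DriverRegression(amplification_cutoff=amplification_cutoff, **params).fit(samples)


def group_compare(x, y, test: str = "student_t") -> tuple[float, float]:
    """Two-sample/two-variable comparison.

    test:
        ``student_t`` — pooled-variance two-sided t test between groups
        ``x`` and ``y`` (each n >= 2);
        ``paired_t`` — two-sided t test on paired differences;
        ``spearman`` — Spearman rank correlation (average ranks for
        ties, p from the t approximation), ``x`` and ``y`` being the two
        numeric vectors (n >= 3).

    Returns (statistic, p_value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if test == "student_t":
        if x.size < 2 or y.size < 2:
            raise ValueError("student_t needs at least 2 values per group")
        stat, p = stats.ttest_ind(x, y, equal_var=True)
    elif test == "paired_t":
        if x.size != y.size:
            raise ValueError("paired_t needs equal-length vectors")
        stat, p = stats.ttest_rel(x, y)
    elif test == "spearman":
        if x.size != y.size or x.size < 3:
            raise ValueError("spearman needs two equal-length vectors, n >= 3")
        stat, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)


def read_sample_table(path) -> pd.DataFrame:
    """Read the per-sample covariate table (TSV).

    Expected columns: sample_id, group, tpm_long, tpm_short, tpm_gene and
    optionally copy_number, tnf_score, ifn_score.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    return df
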