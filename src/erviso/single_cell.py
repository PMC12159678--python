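"""Single-cell expressing-fraction and composition summaries.

Works on raw integer counts for a handful of locus features (the long
and short transcript forms and the composite gene) with cell-level
metadata.  "Expressing" means raw count >= 1 unless stated otherwise;
the long transcript form is expected to be restricted to a few cell
types (tumor, AT2, fibroblast) while the short form and the composite
gene appear across types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .decomposition import group_compare

REQUIRED_OBS = ("cell_type", "patient_id", "tissue")


@dataclass
class CellTable:
    """Raw counts (cells x features) plus per-cell metadata.

    ``obs`` must carry ``cell_type`` (broad label), ``patient_id`` and
    ``tissue`` ({tumor, normal}); a ``cell_type_detail`` column may hold
    the finer annotation.
    """

    counts: pd.DataFrame
    obs: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.obs.index):
            raise ValueError("counts and obs must be indexed by the same cells")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for col in REQUIRED_OBS:
            if col not in self.obs.columns:
                raise ValueError(f"cell metadata lacks column {col!r}")
            if self.obs[col].astype(str).eq("").any():
                raise ValueError(f"empty labels in metadata column {col!r}")

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    def feature(self, feature_id: str) -> pd.Series:
        if feature_id not in self.counts.columns:
            raise KeyError(f"unknown feature {feature_id!r}")
        return self.counts[feature_id]

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, feature_cols: Sequence[str] | None = None) -> "CellTable":
        """Single cells x features TSV with metadata columns mixed in.

        Metadata columns are those named in ``REQUIRED_OBS`` (plus
        ``cell_type_detail`` if present); every other non-index column is
        a feature unless ``feature_cols`` is given.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta_cols = [c for c in (*REQUIRED_OBS, "cell_type_detail") if c in df.columns]
        if feature_cols is None:
            feature_cols = [c for c in df.columns if c not in meta_cols]
        return cls(df[list(feature_cols)], df[meta_cols])

    @classmethod
    def from_mtx(cls, mtx_path, cells_path, features_path) -> "CellTable":
        """MTX (cells x features) + cells TSV (metadata) + features TSV."""
        mat = mmread(str(mtx_path)).toarray()
        obs = pd.read_csv(cells_path, sep="\t", index_col=0)
        features = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
        counts = pd.DataFrame(mat, index=obs.index, columns=features)
        return cls(counts, obs)

    def to_tsv(self, path: str | Path) -> None:
        pd.concat([self.obs, self.counts], axis=1).to_csv(path, sep="\t")


def composition_of_expressing_cells(
    cells: CellTable,
    feature: str,
    min_count: int = 1,
    annotation_col: str = "cell_type",
) -> pd.Series:
    """Cell-type composition (percentages) of the expressing cells.

    Among cells with raw count >= ``min_count`` for ``feature``, the
    percentage contributed by each cell type; percentages sum to 100.
    """
    expressing = cells.feature(feature) >= min_count
    if not expressing.any():
        raise ValueError(f"no cells express {feature!r} at min_count={min_count}")
    types = cells.obs.loc[expressing, annotation_col]
    return (types.value_counts() / expressing.sum() * 100.0).sort_index()


def fraction_expressing_by_celltype(
    cells: CellTable,
    feature: str,
    min_cells_per_type: int = 600,
    min_count: int = 1,
    annotation_col: str = "cell_type",
) -> tuple[pd.Series, list[str]]:
    """Per-type fraction of cells expressing the feature.

    Only cell types with *more than* ``min_cells_per_type`` cells are
    reported (strict >); the omitted types are returned alongside.
    """
    counts = cells.feature(feature)
    sizes = cells.obs[annotation_col].value_counts()
    kept = sizes.index[sizes > min_cells_per_type]
    omitted = sorted(sizes.index.difference(kept))
    fractions = {}
    for ct in kept:
        mask = cells.obs[annotation_col] == ct
        fractions[ct] = float((counts[mask] >= min_count).mean())
    return pd.Series(fractions).sort_index(), omitted


def stratify_cells_by_expression(
    cells: CellTable,
    feature: str,
    high_threshold: int = 10,
    tumor_only: bool = False,
    tumor_type: str = "tumor",
) -> pd.Series:
    """Partition cells into high/low expressors of a feature.

    high <=> raw count >= ``high_threshold`` (default 10 raw reads); low
    otherwise (including zero).  ``tumor_only`` restricts to tumor cells
    from tumor tissue before labelling.
    """
    counts = cells.feature(feature)
    if tumor_only:
        mask = (cells.obs["cell_type"] == tumor_type) & (cells.obs["tissue"] == "tumor")
        counts = counts[mask]
    return pd.Series(
        np.where(counts >= high_threshold, "high", "low"), index=counts.index, name="stratum"
    )


def patient_expressing_type_percentage(
    cells: CellTable,
    type_set: Iterable[str],
    annotation_col: str = "cell_type",
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-patient percentage of cells belonging to a designated type set,
    compared between tumor and normal tissue by Student t test.

    Returns a per-patient frame (percentage, tissue) and the (t, p) of
    the tissue comparison ((nan, nan) if a tissue group is missing).
    """
    type_set = set(type_set)
    known = set(cells.obs[annotation_col].unique())
    unknown = sorted(type_set - known)
    if unknown:
        warnings.warn(f"unknown cell types treated as absent: {unknown}", stacklevel=2)
    in_set = cells.obs[annotation_col].isin(type_set)
    per_patient = (
        pd.DataFrame({"in_set": in_set, "patient_id": cells.obs["patient_id"]})
        .groupby("patient_id")["in_set"]
        .mean()
        * 100.0
    ).rename("percentage")
    tissue = cells.obs.groupby("patient_id")["tissue"].first()
    frame = pd.DataFrame({"percentage": per_patient, "tissue": tissue})
    groups = frame.groupby("tissue")["percentage"]
    if frame["tissue"].nunique() == 2:
        (_, a), (_, b) = sorted(groups, key=lambda kv: kv[0] != "tumor")  # tumor first
        stat, p = group_compare(a.to_numpy(), b.to_numpy(), test="student_t")
    else:
        warnings.warn("need both tumor and normal patients for the comparison", stacklevel=2)
        stat, p = float("nan"), float("nan")
    return frame, (stat, p)
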