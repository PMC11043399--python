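"""Per-cell LOY classification, donor sex inference and %LOY summaries.

The classification rule: a cell is called LOY iff its raw count is
exactly zero for every retained gene of the male-specific-region (MSY)
panel — RPS4Y1, ZFY, USP9Y, DDX3Y, KDM5D, EIF1AY — and non-LOY
otherwise.  The rule operates on raw counts; raw zeros are invariant to
any normalization applied later, so calling precedes annotation and
scoring.  A donor is inferred male iff at least one of their cells
expresses at least one panel gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix, DatasetProfile, ValidationError

logger = logging.getLogger("mosaicloy")

DEFAULT_MSY_PANEL = ("RPS4Y1", "ZFY", "USP9Y", "DDX3Y", "KDM5D", "EIF1AY")


@dataclass
class MSYPanel:
    """Ordered panel of MSY gene symbols used as the LOY signature."""

    genes: tuple = DEFAULT_MSY_PANEL

    def __post_init__(self) -> None:
        self.genes = tuple(g.upper() for g in self.genes)
        if not self.genes:
            raise ValidationError("MSY panel must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("MSY panel symbols must be unique")


def _as_panel(panel) -> MSYPanel:
    if panel is None:
        return MSYPanel()
    if isinstance(panel, MSYPanel):
        return panel
    return MSYPanel(tuple(panel))


class LOYCaller(BaseEstimator):
    """Zero-expression LOY classifier over a cells x genes count frame.

    Parameters
    ----------
    panel : sequence of str, default the six-gene MSY panel
        Gene symbols whose joint absence defines a LOY call.

    Attributes
    ----------
    panel_genes_ : list of str
        Panel genes actually present in the fitted matrix (missing panel
        genes are dropped with a warning).
    feature_names_in_ : ndarray
        Column names seen during :meth:`fit`.
    """

    def __init__(self, panel=DEFAULT_MSY_PANEL):
        self.panel = panel

    def fit(self, X: pd.DataFrame, y=None) -> "LOYCaller":
        X = self._check_frame(X)
        panel = _as_panel(self.panel)
        present = [g for g in panel.genes if g in X.columns]
        missing = [g for g in panel.genes if g not in X.columns]
        if missing:
            warnings.warn(
                f"MSY panel genes absent from matrix and dropped: {missing}",
                UserWarning,
            )
        if not present:
            raise ValidationError("no MSY panel gene present in the matrix")
        self.panel_genes_ = present
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Per-cell call, "LOY" or "nonLOY"."""
        check_is_fitted(self)
        X = self._check_frame(X)
        panel_counts = X[self.panel_genes_].to_numpy()
        is_loy = (panel_counts == 0).all(axis=1)
        return np.where(is_loy, "LOY", "nonLOY")

    def msy_fraction(self, X: pd.DataFrame) -> np.ndarray:
        """Per-cell fraction of total counts falling on the retained panel."""
        check_is_fitted(self)
        X = self._check_frame(X)
        totals = X.to_numpy().sum(axis=1).astype(float)
        panel_sum = X[self.panel_genes_].to_numpy().sum(axis=1).astype(float)
        zero_total = totals == 0
        if zero_total.any():
            warnings.warn(
                f"{int(zero_total.sum())} cell(s) with zero total counts; "
                "MSY fraction reported as 0",
                UserWarning,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(zero_total, 0.0, panel_sum / np.where(zero_total, 1.0, totals))
        return frac

    @staticmethod
    def _check_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a cells x genes DataFrame with gene-symbol columns")
        if X.shape[1] == 0:
            raise ValidationError("matrix has no genes")
        arr = X.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        return X


# ---------------------------------------------------------------------------
# functional wrappers over CountMatrix


def _fitted_caller(matrix: CountMatrix, panel) -> tuple[LOYCaller, pd.DataFrame]:
    X = matrix.to_cells_by_genes()
    return LOYCaller(panel=_as_panel(panel).genes).fit(X), X


def msy_fraction_per_cell(matrix: CountMatrix, panel=None) -> pd.Series:
    """Fraction of each cell's total counts carried by the MSY panel."""
    caller, X = _fitted_caller(matrix, panel)
    return pd.Series(caller.msy_fraction(X), index=matrix.cell_ids, name="msy_fraction")


def call_loy_cells(matrix: CountMatrix, panel=None) -> pd.Series:
    """Zero-expression LOY call ("LOY"/"nonLOY") for every cell."""
    caller, X = _fitted_caller(matrix, panel)
    calls = pd.Series(caller.predict(X), index=matrix.cell_ids, name="loy_call")
    logger.info("LOY calling: %d cells in, %d called LOY", len(calls), int((calls == "LOY").sum()))
    return calls


def infer_donor_sex(matrix: CountMatrix, cells: pd.DataFrame, panel=None) -> pd.DataFrame:
    """Infer each donor's sex from MSY expression.

    A donor is male iff at least one of their cells has a nonzero count on
    at least one retained panel gene.  Returns one row per donor with the
    inferred sex and the donor-aggregate MSY count fraction for audit.
    Donors present in ``cells`` but owning no matrix cells are excluded
    with a warning.
    """
    caller, X = _fitted_caller(matrix, panel)
    cells = cells.set_index("cell_id")
    rows = []
    for donor, group in cells.groupby("donor_id", sort=True):
        barcodes = [b for b in group.index if b in X.index]
        if not barcodes:
            warnings.warn(f"donor {donor!r} has no cells in the matrix; excluded", UserWarning)
            continue
        sub = X.loc[barcodes]
        panel_total = float(sub[caller.panel_genes_].to_numpy().sum())
        grand_total = float(sub.to_numpy().sum())
        rows.append(
            {
                "donor_id": donor,
                "sex": "male" if panel_total > 0 else "female",
                "n_cells": len(barcodes),
                "msy_fraction": panel_total / grand_total if grand_total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def assign_loy_calls(
    matrix: CountMatrix, cells: pd.DataFrame, panel=None, exclude_female_donors: bool = True
) -> pd.DataFrame:
    """Attach per-cell LOY calls to a cell table.

    Cells of donors inferred female are left "unassigned" (the analysis
    removes female patients), unless ``exclude_female_donors`` is false.
    """
    calls = call_loy_cells(matrix, panel)
    out = cells.copy()
    out["loy_call"] = out["cell_id"].map(calls).fillna("unassigned")
    if exclude_female_donors:
        sexes = infer_donor_sex(matrix, cells, panel)
        female = set(sexes.loc[sexes["sex"] == "female", "donor_id"])
        if female:
            mask = out["donor_id"].isin(female)
            out.loc[mask, "loy_call"] = "unassigned"
            logger.info("excluded %d cells of %d female donor(s) from LOY calls",
                        int(mask.sum()), len(female))
    return out


def summarize_pct_loy(
    cells: pd.DataFrame, group_keys=("donor_id", "tissue", "cell_type")
) -> pd.DataFrame:
    """Per-group LOY summary: n_cells, n_loy, pct_loy = 100*n_loy/n_cells.

    Only cells with an assigned call (LOY or nonLOY) are counted.  One row
    per occupied group; an empty grouping yields an empty frame.  Pooled
    percentages and mean-of-donor percentages are both recoverable from
    the counts (see :func:`pooled_pct_loy` and :func:`mean_donor_pct_loy`).
    """
    group_keys = list(group_keys)
    called = cells[cells["loy_call"].isin(["LOY", "nonLOY"])]
    if called.empty:
        return pd.DataFrame(columns=group_keys + ["n_cells", "n_loy", "pct_loy"])
    agg = (
        called.assign(_loy=(called["loy_call"] == "LOY").astype(int))
        .groupby(group_keys, sort=True, observed=True)["_loy"]
        .agg(n_cells="size", n_loy="sum")
        .reset_index()
    )
    agg["pct_loy"] = 100.0 * agg["n_loy"] / agg["n_cells"]
    return agg


def pooled_pct_loy(summaries: pd.DataFrame) -> float:
    """%LOY pooling all cells across the given summary rows."""
    n = summaries["n_cells"].sum()
    return 100.0 * summaries["n_loy"].sum() / n if n else float("nan")


def mean_donor_pct_loy(summaries: pd.DataFrame) -> float:
    """Mean over donors of per-donor %LOY (each donor weighted equally)."""
    per_donor = summaries.groupby("donor_id")[["n_cells", "n_loy"]].sum()
    return float((100.0 * per_donor["n_loy"] / per_donor["n_cells"]).mean())


def filter_min_cells(summaries: pd.DataFrame, profile: DatasetProfile) -> pd.DataFrame:
    """Drop groups whose cell count is strictly below ``min_group_cells``.

    The removal is strict ("lower than"), so a group of exactly
    ``min_group_cells`` cells survives.
    """
    kept = summaries[summaries["n_cells"] >= profile.min_group_cells].reset_index(drop=True)
    logger.info("min-cell filter (>=%d): %d groups in, %d removed",
                profile.min_group_cells, len(summaries), len(summaries) - len(kept))
    return kept


def filter_min_patients(
    summaries: pd.DataFrame, profile: DatasetProfile, cancer_key: str = "cancer_type"
) -> pd.DataFrame:
    """Drop all groups of cancer types with fewer than
    ``min_patients_per_cancer`` distinct donors."""
    if cancer_key not in summaries.columns:
        raise ValidationError(f"summaries lack the {cancer_key!r} column required by this filter")
    donors_per_cancer = summaries.groupby(cancer_key)["donor_id"].nunique()
    keep = donors_per_cancer[donors_per_cancer >= profile.min_patients_per_cancer].index
    kept = summaries[summaries[cancer_key].isin(keep)].reset_index(drop=True)
    logger.info("min-patient filter (>=%d donors): %d cancers in, %d kept",
                profile.min_patients_per_cancer, donors_per_cancer.size, len(keep))
    return kept
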