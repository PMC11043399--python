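"""Control-bin gene-module scores and LOY-vs-nonLOY expression contrasts.

The score of a gene module in a cell is the mean normalized expression of
the module genes minus the mean of a pooled control draw matched on
expression level: genes are binned into ``n_bins`` equal-frequency bins
by their dataset-wide mean expression, and each module gene contributes
``n_ctrl`` control genes drawn uniformly (with replacement) from its bin.
Under the null where module genes are exchangeable with their bins the
expected score is zero.  Single-gene modules (e.g. PDCD1, TIGIT or IKZF2
alone) are modules of size one.

RNG/binning contract (tests and reimplementations rely on it):
genes are ordered by (mean expression, symbol) and split into bins with
``numpy.array_split``; module genes are processed in sorted-symbol order;
candidates within a bin are sorted by symbol; draws use
``numpy.random.default_rng(seed).choice(len(candidates), n_ctrl,
replace=True)`` sequentially over module genes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ValidationError
from .stats import wilcoxon_rank_sum

logger = logging.getLogger("mosaicloy")

#: Immunosuppressive gene panels examined in LOY vs non-LOY Tregs.
GENE_PANELS = {
    "ic_receptors": ("CTLA4", "PDCD1", "HAVCR2", "LAG3", "TIGIT", "ICOS"),
    "apc_manipulation": ("ENTPD1", "NT5E", "CD80"),
    "migration": ("CCR1", "CCR4", "CCR5", "CCR7", "CCR8"),
    "tf": ("IKZF2",),
}


class ModuleScorer(BaseEstimator, TransformerMixin):
    """Expression-bin-matched module score, one value per cell.

    Parameters
    ----------
    module_genes : sequence of str
        Gene symbols of the module; symbols absent from the matrix are
        dropped with a warning, at least one must remain.
    n_bins : int, default 24
        Equal-frequency expression bins for control matching.
    n_ctrl : int, default 100
        Control genes drawn per module gene.
    exclude_module_from_ctrl : bool, default True
        Exclude module genes from control pools so an additive shift on a
        module gene moves the score by exactly that shift.
    seed : int, default 0

    Attributes
    ----------
    module_genes_ : list of str
        Retained module genes (sorted by symbol).
    control_draw_ : ndarray of str
        Pooled control draw, with multiplicity.
    gene_means_ : pandas.Series
        Dataset-wide mean expression used for binning.
    """

    def __init__(self, module_genes=("TIGIT",), n_bins=24, n_ctrl=100,
                 exclude_module_from_ctrl=True, seed=0):
        self.module_genes = module_genes
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.exclude_module_from_ctrl = exclude_module_from_ctrl
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "ModuleScorer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a cells x genes DataFrame of normalized expression")
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ValidationError("n_bins and n_ctrl must be >= 1")
        if X.shape[1] < self.n_bins:
            raise ValidationError(
                f"{X.shape[1]} genes cannot fill {self.n_bins} expression bins"
            )
        wanted = [g.upper() for g in self.module_genes]
        present = sorted(g for g in set(wanted) if g in X.columns)
        missing = sorted(set(wanted) - set(present))
        if missing:
            warnings.warn(f"module genes absent and dropped: {missing}", UserWarning)
        if not present:
            raise ValidationError("no module gene present in the matrix")

        means = X.mean(axis=0)
        order = sorted(X.columns, key=lambda g: (means[g], g))
        bins = np.array_split(np.array(order, dtype=object), self.n_bins)
        bin_of = {g: i for i, chunk in enumerate(bins) for g in chunk}

        rng = np.random.default_rng(self.seed)
        module_set = set(present)
        pooled: list[str] = []
        for gene in present:  # sorted-symbol order
            members = sorted(bins[bin_of[gene]])
            candidates = [g for g in members if g not in module_set] \
                if self.exclude_module_from_ctrl else members
            if not candidates:  # bin exhausted by the module itself
                candidates = members
            idx = rng.choice(len(candidates), size=self.n_ctrl, replace=True)
            pooled.extend(candidates[i] for i in idx)

        self.module_genes_ = present
        self.control_draw_ = np.array(pooled, dtype=object)
        self.gene_means_ = means
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Per-cell score: mean over module genes minus mean over the
        pooled control draw (multiplicity respected)."""
        check_is_fitted(self)
        module_mean = X[self.module_genes_].to_numpy(dtype=float).mean(axis=1)
        ctrl_mean = X[list(self.control_draw_)].to_numpy(dtype=float).mean(axis=1)
        return module_mean - ctrl_mean


def score_gene_module(
    normalized: pd.DataFrame, module_genes, n_bins: int = 24, n_ctrl: int = 100,
    exclude_module_from_ctrl: bool = True, seed: int = 0,
) -> pd.Series:
    """Per-cell module score on a cells x genes normalized DataFrame."""
    scorer = ModuleScorer(
        module_genes=tuple(module_genes), n_bins=n_bins, n_ctrl=n_ctrl,
        exclude_module_from_ctrl=exclude_module_from_ctrl, seed=seed,
    ).fit(normalized)
    return pd.Series(scorer.transform(normalized), index=normalized.index, name="score")


def compare_loy_expression(scores: pd.Series, loy_calls: pd.Series, group: str = "") -> dict:
    """Two-sided rank-sum comparison of per-cell scores, LOY vs non-LOY.

    ``loy_calls`` must align with ``scores`` and contain "LOY"/"nonLOY".
    The statistical unit is the cell; the returned record carries an
    explicit pseudoreplication caveat because cells of one donor are not
    independent.
    """
    loy_calls = loy_calls.reindex(scores.index)
    a = scores[loy_calls == "LOY"].to_numpy(dtype=float)
    b = scores[loy_calls == "nonLOY"].to_numpy(dtype=float)
    label = f" in group {group!r}" if group else ""
    if a.size == 0:
        raise ValidationError(f"no LOY cells{label}")
    if b.size == 0:
        raise ValidationError(f"no non-LOY cells{label}")
    stat, p = wilcoxon_rank_sum(a, b)
    return {
        "group": group,
        "n_loy": int(a.size),
        "n_nonloy": int(b.size),
        "mean_loy": float(a.mean()),
        "mean_nonloy": float(b.mean()),
        "statistic": float(stat),
        "p_raw": float(p),
        "caveat": "per-cell test; cells within a donor are pseudoreplicates",
    }


def rank_gene_correlations(normalized: pd.DataFrame, target_gene: str) -> pd.DataFrame:
    """Genes ranked by product-moment correlation with ``target_gene``.

    Computed across the cells of ``normalized`` (restrict the frame to a
    subset, e.g. Tregs, before calling).  Zero-variance genes are
    excluded; ties break by symbol so the order is deterministic.
    """
    target_gene = target_gene.upper()
    if target_gene not in normalized.columns:
        raise ValidationError(f"target gene {target_gene!r} absent from matrix")
    if normalized.shape[0] < 3:
        raise ValidationError("need at least 3 cells to rank correlations")
    arr = normalized.to_numpy(dtype=float)
    y = normalized[target_gene].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValidationError(f"target gene {target_gene!r} has zero variance")
    centered = arr - arr.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((centered ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, centered.T @ yc / np.where(denom > 0, denom, 1.0), np.nan)
    out = pd.DataFrame({"gene": normalized.columns, "r": r})
    out = out[(out["gene"] != target_gene) & out["r"].notna()]
    variances = arr.std(axis=0)
    keep = pd.Series(variances > 0, index=normalized.columns)
    out = out[out["gene"].map(keep)]
    out = out.sort_values(["r", "gene"], ascending=[False, True]).reset_index(drop=True)
    return out
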