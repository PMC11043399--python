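"""CD4+ T-cell annotation: normalization, reclustering, Treg/Th labeling.

CD4+ T cells are reclustered on log-CP10K-normalized expression and each
cluster is labeled Treg iff its mean expression of every retained Treg
marker (default CTLA4 and IL23R) strictly exceeds the across-cluster
median for that marker; remaining clusters are Th.  CTL labels are
accepted from upstream annotation and never created here.  LOY calls are
made on raw counts upstream, so annotation can never change them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix, ValidationError

logger = logging.getLogger("mosaicloy")


class CP10KLogNormalizer(BaseEstimator, TransformerMixin):
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Stateless; ``fit`` only records feature names.  Zero-count cells map
    to all-zero rows with a warning.
    """

    def __init__(self, target_sum: float = 1e4):
        self.target_sum = target_sum

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        frame = isinstance(X, pd.DataFrame)
        arr = X.to_numpy(dtype=float) if frame else np.asarray(X, dtype=float)
        totals = arr.sum(axis=1)
        zero = totals == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-count cell(s) map to all-zero profiles", UserWarning
            )
        scaled = arr * (self.target_sum / np.where(zero, 1.0, totals))[:, None]
        out = np.log1p(scaled)
        if frame:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def normalize_log_cp10k(matrix: CountMatrix) -> pd.DataFrame:
    """Cells x genes log-CP10K matrix for a :class:`CountMatrix`."""
    X = matrix.to_cells_by_genes()
    return CP10KLogNormalizer().fit(X).transform(X)


@dataclass
class AnnotationRules:
    """Parameters of the Treg/Th categorization.

    clustering: "kmeans" (PCA embedding + k-means, k = resolution_or_k),
    "graph" (scanpy neighbors + Leiden at the given resolution) or "none"
    (pre-supplied labels pass through unchanged).
    """

    treg_markers: tuple = ("CTLA4", "IL23R")
    clustering: str = "kmeans"
    n_components: int = 10
    resolution_or_k: float = 2
    n_top_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.treg_markers = tuple(g.upper() for g in self.treg_markers)
        if not self.treg_markers:
            raise ValidationError("treg_markers must be non-empty")
        if self.clustering not in ("kmeans", "graph", "none"):
            raise ValidationError(f"unknown clustering mode {self.clustering!r}")
        if self.resolution_or_k <= 0:
            raise ValidationError("clustering granularity must be positive")


class TregThAnnotator(BaseEstimator):
    """Cluster CD4+ cells and label clusters Treg or Th by marker exceedance.

    Operates on a cells x genes DataFrame of *normalized* expression.
    ``fit_predict`` returns "Treg"/"Th" per cell.  With
    ``clustering="none"`` the ``labels`` argument supplies cluster ids.

    Attributes
    ----------
    cluster_ids_ : ndarray of int
        Per-cell cluster assignment.
    cluster_label_ : dict
        cluster id -> "Treg" | "Th".
    marker_genes_ : list of str
        Treg markers present in the matrix.
    """

    def __init__(self, treg_markers=("CTLA4", "IL23R"), clustering="kmeans",
                 n_components=10, resolution_or_k=2, n_top_genes=100, seed=0):
        self.treg_markers = treg_markers
        self.clustering = clustering
        self.n_components = n_components
        self.resolution_or_k = resolution_or_k
        self.n_top_genes = n_top_genes
        self.seed = seed

    def _rules(self) -> AnnotationRules:
        return AnnotationRules(
            treg_markers=tuple(self.treg_markers), clustering=self.clustering,
            n_components=self.n_components, resolution_or_k=self.resolution_or_k,
            n_top_genes=self.n_top_genes, seed=self.seed,
        )

    def fit(self, X: pd.DataFrame, y=None, labels=None) -> "TregThAnnotator":
        rules = self._rules()
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a cells x genes DataFrame of normalized expression")
        clusters = _cluster(X, rules, labels)
        self.cluster_ids_ = clusters
        self.marker_genes_, self.cluster_label_ = _label_clusters(clusters, X, rules)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X: pd.DataFrame, y=None, labels=None) -> np.ndarray:
        self.fit(X, labels=labels)
        return np.array([self.cluster_label_[c] for c in self.cluster_ids_], dtype=object)


def _cluster(X: pd.DataFrame, rules: AnnotationRules, labels=None) -> np.ndarray:
    n_cells = X.shape[0]
    if rules.clustering == "none":
        if labels is None:
            raise ValidationError("clustering='none' requires pre-supplied labels")
        labels = np.asarray(labels)
        if labels.shape[0] != n_cells:
            raise ValidationError("labels length must equal number of cells")
        _, as_int = np.unique(labels, return_inverse=True)
        return as_int
    if rules.clustering == "kmeans":
        k = int(rules.resolution_or_k)
        if n_cells < k:
            raise ValidationError(f"{n_cells} cells cannot form {k} clusters")
        n_comp = min(int(rules.n_components), n_cells, X.shape[1])
        arr = X.to_numpy(dtype=float)
        if rules.n_top_genes and arr.shape[1] > rules.n_top_genes:
            # embed on the most variable genes only, the usual workflow step
            top = np.argsort(arr.var(axis=0))[-int(rules.n_top_genes):]
            arr = arr[:, top]
        sd = arr.std(axis=0)
        scaled = (arr - arr.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        emb = PCA(n_components=n_comp, random_state=rules.seed).fit_transform(scaled)
        km = KMeans(n_clusters=k, random_state=rules.seed, n_init=10)
        return km.fit_predict(emb)
    # graph: scanpy neighbors + Leiden
    import scanpy as sc
    import anndata as ad

    adata = ad.AnnData(X=X.to_numpy(dtype=float))
    n_comp = min(int(rules.n_components), n_cells - 1, X.shape[1] - 1)
    sc.pp.pca(adata, n_comps=max(n_comp, 1), random_state=rules.seed)
    sc.pp.neighbors(adata, use_rep="X_pca", random_state=rules.seed)
    sc.tl.leiden(
        adata, resolution=float(rules.resolution_or_k), random_state=rules.seed,
        flavor="igraph", n_iterations=2, directed=False,
    )
    return adata.obs["leiden"].astype(int).to_numpy()


def _label_clusters(
    clusters: np.ndarray, X: pd.DataFrame, rules: AnnotationRules
) -> tuple[list[str], dict]:
    present = [g for g in rules.treg_markers if g in X.columns]
    missing = [g for g in rules.treg_markers if g not in X.columns]
    if missing:
        warnings.warn(f"Treg markers absent and dropped: {missing}", UserWarning)
    if not present:
        raise ValidationError("no Treg marker gene present in the matrix")
    ids = np.unique(clusters)
    means = pd.DataFrame(
        {g: [X[g].to_numpy()[clusters == c].mean() for c in ids] for g in present},
        index=ids,
    )
    medians = means.median(axis=0)
    # Treg iff strictly above the across-cluster median on every marker;
    # a single cluster can never exceed its own median, hence labels Th
    is_treg = (means > medians).all(axis=1)
    label = {int(c): ("Treg" if is_treg.loc[c] else "Th") for c in ids}
    logger.info("labeled %d/%d clusters Treg (markers %s)",
                int(is_treg.sum()), len(ids), present)
    return present, label


# ---------------------------------------------------------------------------
# functional wrappers


def recluster_cd4(normalized: pd.DataFrame, rules: AnnotationRules, labels=None) -> np.ndarray:
    """Cluster ids for CD4+ cells on normalized expression."""
    return _cluster(normalized, rules, labels)


def label_treg_th(clusters, normalized: pd.DataFrame, rules: AnnotationRules) -> np.ndarray:
    """Per-cell "Treg"/"Th" labels from cluster-level marker exceedance."""
    clusters = np.asarray(clusters)
    if clusters.shape[0] != normalized.shape[0]:
        raise ValidationError("clusters must cover every cell")
    _, mapping = _label_clusters(clusters, normalized, rules)
    return np.array([mapping[int(c)] for c in clusters], dtype=object)


def annotate_cd4_cells(
    matrix: CountMatrix, cells: pd.DataFrame, rules: AnnotationRules | None = None,
    cd4_types=("Treg", "Th", "unassigned"),
) -> pd.DataFrame:
    """Recluster the CD4 compartment and overwrite its cell_type labels.

    Cells whose current cell_type is CTL or other are passed through
    untouched; cells in ``cd4_types`` are reclustered and relabeled
    Treg/Th.  Returns an updated copy of the cell table.
    """
    rules = rules or AnnotationRules()
    out = cells.copy()
    cd4_mask = out["cell_type"].isin(cd4_types)
    if not cd4_mask.any():
        return out
    barcodes = out.loc[cd4_mask, "cell_id"].tolist()
    normalized = normalize_log_cp10k(matrix).loc[barcodes]
    annotator = TregThAnnotator(
        treg_markers=rules.treg_markers, clustering=rules.clustering,
        n_components=rules.n_components, resolution_or_k=rules.resolution_or_k,
        n_top_genes=rules.n_top_genes, seed=rules.seed,
    )
    out.loc[cd4_mask, "cell_type"] = annotator.fit_predict(normalized)
    logger.info("annotated %d CD4+ cells into Treg/Th", int(cd4_mask.sum()))
    return out
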