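"""Spot QC, normalization, embedding, graph clustering and marker detection.

The processing chain mirrors standard Visium practice for single-section
analyses: remove the 13 protein-coding mitochondrial genes, filter spots on
total UMIs (nCount) and detected genes (nFeature) with per-sample presets,
normalize by median-ratio depth scaling with a log1p transform, embed with
PCA (30 components), build a 20-nearest-neighbor graph and cluster it with
Leiden, then call one-vs-rest Wilcoxon rank-sum markers per cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA

from .errors import ConfigurationError
from .io import compute_qc

logger = logging.getLogger(__name__)

#: the 13 protein-coding mitochondrial genes removed before analysis
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive per-spot bounds on total UMIs and detected genes."""

    nCount_min: int
    nCount_max: int
    nFeature_min: int
    nFeature_max: int

    def __post_init__(self):
        if self.nCount_min > self.nCount_max or self.nFeature_min > self.nFeature_max:
            raise ConfigurationError(f"invalid QC thresholds: {self}")


#: per-sample filter presets for the four mouse muscle sections
QC_PRESETS = {
    "C57BL10": QCThresholds(150, 40_000, 150, 5000),
    "DBA2J": QCThresholds(100, 20_000, 200, 4000),
    "mdx": QCThresholds(200, 40_000, 250, 5000),
    "D2mdx": QCThresholds(100, 20_000, 150, 5000),
}


def drop_mito_genes(adata: ad.AnnData) -> ad.AnnData:
    """Remove the mitochondrial genes (when present) and refresh QC stats."""
    present = adata.var_names.isin(MITO_GENES)
    if present.any():
        logger.info("removing %d mitochondrial genes", int(present.sum()))
        adata = adata[:, ~present].copy()
        compute_qc(adata)
    return adata


def qc_filter(adata: ad.AnnData, thresholds: QCThresholds) -> ad.AnnData:
    """Retain spots inside the inclusive nCount/nFeature bounds."""
    if "nCount" not in adata.obs:
        compute_qc(adata)
    nc = adata.obs["nCount"].to_numpy()
    nf = adata.obs["nFeature"].to_numpy()
    keep = (
        (nc >= thresholds.nCount_min)
        & (nc <= thresholds.nCount_max)
        & (nf >= thresholds.nFeature_min)
        & (nf <= thresholds.nFeature_max)
    )
    if not keep.any():
        raise ConfigurationError(
            "QC filtering removed every spot; review the thresholds against the "
            "nCount/nFeature distributions"
        )
    logger.info("QC filter retained %d / %d spots", int(keep.sum()), adata.n_obs)
    return adata[keep].copy()


def normalize_matrix(X) -> tuple[sp.csr_matrix, np.ndarray]:
    """Median-ratio log normalization of a spots x genes count matrix.

    Each spot is scaled to the median total count and log1p-transformed:
    ``value = log1p(count * median(nCount) / nCount_spot)``.  Returns the
    normalized matrix and the per-spot size factors applied.
    """
    X = sp.csr_matrix(X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ConfigurationError(
            "zero-count spot encountered during normalization; apply qc_filter first"
        )
    factors = np.median(totals) / totals
    Xn = sp.diags(factors) @ X
    Xn.data = np.log1p(Xn.data)
    return sp.csr_matrix(Xn), factors


def normalize(adata: ad.AnnData, layer: str | None = None) -> ad.AnnData:
    """Return a copy whose ``X`` holds median-ratio log-normalized values.

    Raw counts are preserved in ``layers["counts"]``.
    """
    adata = adata.copy()
    counts = adata.layers[layer] if layer else adata.X
    if "counts" not in adata.layers:
        adata.layers["counts"] = sp.csr_matrix(counts).copy()
    Xn, factors = normalize_matrix(counts)
    adata.X = Xn
    adata.obs["size_factor"] = factors
    return adata


class MedianRatioNormalizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`normalize_matrix`.

    ``fit`` records the median depth of the training matrix so that new
    spots can be scaled onto the same reference depth.
    """

    def fit(self, X, y=None):
        totals = np.asarray(sp.csr_matrix(X).sum(axis=1)).ravel()
        if (totals == 0).any():
            raise ConfigurationError("zero-count spot in normalizer input")
        self.median_depth_ = float(np.median(totals))
        return self

    def transform(self, X):
        X = sp.csr_matrix(X, dtype=np.float64)
        totals = np.asarray(X.sum(axis=1)).ravel()
        if (totals == 0).any():
            raise ConfigurationError("zero-count spot in normalizer input")
        Xn = sp.diags(self.median_depth_ / totals) @ X
        Xn.data = np.log1p(Xn.data)
        return sp.csr_matrix(Xn)


def _row_moments(X) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and variance of a spots x genes matrix."""
    X = sp.csr_matrix(X)
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvg(X, gene_names, n: int, n_bins: int = 20) -> pd.Index:
    """Top-``n`` highly variable genes by binned normalized dispersion.

    Dispersion (variance / mean of the normalized values) is z-scored within
    20 gene-mean bins; genes are ranked by the z-score with ties broken by
    gene order.
    """
    if n <= 0:
        raise ConfigurationError("number of HVGs must be positive")
    gene_names = pd.Index(gene_names)
    if n > len(gene_names):
        raise ConfigurationError(f"requested {n} HVGs from {len(gene_names)} genes")
    mean, var = _row_moments(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    bins = pd.cut(mean, bins=n_bins, labels=False, duplicates="drop")
    z = np.zeros_like(disp)
    glob_mu, glob_sd = disp.mean(), disp.std()
    for b in np.unique(bins[~pd.isna(bins)]):
        mask = bins == b
        mu, sd = disp[mask].mean(), disp[mask].std()
        if sd > 0:
            z[mask] = (disp[mask] - mu) / sd
        elif glob_sd > 0:
            # singleton or degenerate bin: fall back to the global scale so
            # an isolated high-dispersion gene still ranks highly
            z[mask] = (disp[mask] - glob_mu) / glob_sd
    order = np.lexsort((np.arange(len(gene_names)), -z))
    return gene_names[order[:n]]


def embed_pca(X, n_components: int = 30, scale: bool = True) -> np.ndarray:
    """Centered (and unit-scaled) PCA embedding of a spots x genes matrix."""
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    n_components = int(n_components)
    if n_components >= min(X.shape):
        raise ConfigurationError("n_components must be < min(n_spots, n_genes)")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    rank = np.linalg.matrix_rank(X) if min(X.shape) <= 600 else n_components
    if rank < n_components:
        warnings.warn(f"data rank {rank} < {n_components} components; returning {rank}")
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full" if min(X.shape) <= 600 else "auto",
              random_state=0)
    return pca.fit_transform(X)


def build_knn(embedding: np.ndarray, k: int = 20) -> sp.csr_matrix:
    """Symmetrized (union) k-nearest-neighbor graph in embedding space.

    Distance ties are broken by spot index, so the graph is deterministic.
    """
    emb = np.asarray(embedding, dtype=np.float64)
    n = emb.shape[0]
    if k >= n:
        raise ConfigurationError(f"k={k} must be smaller than the number of spots ({n})")
    sq = (emb**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * emb @ emb.T
    np.fill_diagonal(d2, np.inf)
    # stable argsort => ties resolved by index
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    adj = sp.coo_matrix((np.ones(n * k), (rows, nn.ravel())), shape=(n, n)).tocsr()
    adj = ((adj + adj.T) > 0).astype(np.float64)
    return sp.csr_matrix(adj)


def cluster_graph(adjacency: sp.spmatrix, resolution: float, seed: int = 0) -> np.ndarray:
    """Leiden community detection; labels relabelled by decreasing size."""
    import igraph as ig
    import leidenalg

    adj = sp.coo_matrix(sp.triu(adjacency, k=1))
    graph = ig.Graph(n=adjacency.shape[0], edges=list(zip(adj.row, adj.col)))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=float(resolution),
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    order = np.lexsort((np.unique(labels), -np.bincount(labels)))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], dtype=int)


class KNNLeiden(ClusterMixin, BaseEstimator):
    """Leiden clustering on a k-nearest-neighbor graph of an embedding."""

    def __init__(self, n_neighbors: int = 20, resolution: float = 0.4, seed: int = 0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.seed = seed

    def fit(self, X, y=None):
        self.graph_ = build_knn(X, k=self.n_neighbors)
        self.labels_ = cluster_graph(self.graph_, self.resolution, self.seed)
        return self


def _log2_fold_change(in_vals: np.ndarray, out_vals: np.ndarray, pseudo: float = 1e-9):
    """log2 ratio of back-transformed group means (expm1 scale)."""
    mean_in = np.expm1(in_vals).mean(axis=0)
    mean_out = np.expm1(out_vals).mean(axis=0)
    return np.log2((mean_in + pseudo) / (mean_out + pseudo))


def wilcoxon_de(
    in_vals: np.ndarray,
    out_vals: np.ndarray,
    gene_names: pd.Index,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    min_cells_feature: int = 5,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two spot groups.

    Genes are tested only when expressed in at least ``min_pct`` of either
    group, detected in at least ``min_cells_feature`` spots of either group
    and showing ``log2FC > logfc_min``.  The test uses the normal
    approximation with tie and continuity correction; p-values are
    Bonferroni-corrected over the genes tested.  Only positive markers are
    reported (the fold-change gate is one-sided by construction).
    """
    pct_in = (in_vals > 0).mean(axis=0)
    pct_out = (out_vals > 0).mean(axis=0)
    det_in = (in_vals > 0).sum(axis=0)
    det_out = (out_vals > 0).sum(axis=0)
    log2fc = _log2_fold_change(in_vals, out_vals)
    testable = (
        ((pct_in >= min_pct) | (pct_out >= min_pct))
        & (np.maximum(det_in, det_out) >= min_cells_feature)
        & (log2fc > logfc_min)
    )
    cols = ["gene", "log2_fold_change", "pct_in", "pct_out", "p_value", "p_adjusted"]
    if not testable.any():
        return pd.DataFrame(columns=cols)
    idx = np.flatnonzero(testable)
    res = mannwhitneyu(
        in_vals[:, idx], out_vals[:, idx], alternative=alternative, method="asymptotic", axis=0
    )
    pvals = np.atleast_1d(res.pvalue)
    n_tested = len(idx)
    table = pd.DataFrame(
        {
            "gene": gene_names[idx],
            "log2_fold_change": log2fc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p_value": pvals,
            "p_adjusted": np.minimum(1.0, pvals * n_tested),
        }
    )
    return table[cols]


def rank_markers(
    X,
    gene_names,
    labels,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    min_cells_feature: int = 5,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """One-vs-rest cluster markers on a normalized spots x genes matrix.

    Returns rows of (gene, cluster, log2_fold_change, pct_in, pct_out,
    p_value, p_adjusted), per-cluster sorted by adjusted p-value.
    """
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    labels = np.asarray(labels)
    gene_names = pd.Index(gene_names)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ConfigurationError("marker detection needs at least two clusters")
    tables = []
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < 3:
            warnings.warn(f"cluster {cl!r} has fewer than 3 spots; skipped")
            continue
        tab = wilcoxon_de(
            X[mask],
            X[~mask],
            gene_names,
            min_pct=min_pct,
            logfc_min=logfc_min,
            min_cells_feature=min_cells_feature,
            alternative=alternative,
        )
        if not len(tab):
            continue
        tab.insert(1, "cluster", cl)
        tables.append(tab.sort_values(["p_adjusted", "gene"], kind="stable"))
    if not tables:
        return pd.DataFrame(
            columns=["gene", "cluster", "log2_fold_change", "pct_in", "pct_out",
                     "p_value", "p_adjusted"]
        )
    return pd.concat(tables, ignore_index=True)


def top_expressed_in_cluster(X, gene_names, labels, cluster, n: int = 50) -> pd.DataFrame:
    """Top-``n`` genes by mean normalized expression within one cluster.

    ``pct_expressing`` is the percentage of the cluster's spots detecting
    the gene.
    """
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    labels = np.asarray(labels)
    mask = labels == cluster
    if not mask.any():
        raise ConfigurationError(f"cluster {cluster!r} is empty or absent")
    sub = X[mask]
    means = sub.mean(axis=0)
    pct = 100.0 * (sub > 0).mean(axis=0)
    order = np.lexsort((np.arange(len(means)), -means))[: min(n, len(means))]
    return pd.DataFrame(
        {
            "gene": pd.Index(gene_names)[order],
            "mean_expression": means[order],
            "pct_expressing": pct[order],
        }
    )
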