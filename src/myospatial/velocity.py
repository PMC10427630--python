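"""Steady-state RNA velocity on spatial spots.

Each spot is treated as a single cell.  Per gene, the splicing/degradation
ratio ``gamma`` is the zero-intercept least-squares slope of unspliced on
spliced counts over the extreme-quantile spots, after k-NN pooling of both
layers over a 30-neighbor graph in 30-PC space; the velocity is
``v = u - gamma * s``.  The per-spot gene contribution is the squared entry
of the unit-normalized velocity vector, summarized per cluster by counting
how often a gene ranks in a spot's top-5 contributions.  Velocities are
projected onto the tissue coordinates by cosine-weighting each spot's
expression displacement toward its graph neighbors.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .errors import ConfigurationError
from .preprocess import build_knn, embed_pca, normalize_matrix, select_hvg

logger = logging.getLogger(__name__)


def splice_proportions(adata: ad.AnnData, labels=None) -> pd.DataFrame:
    """Spliced/unspliced count fractions per cluster and globally.

    Zero-count clusters get NaN fractions (flagged undefined).
    """
    for layer in ("spliced", "unspliced"):
        if layer not in adata.layers:
            raise ConfigurationError(f"layer {layer!r} is required for splice proportions")
    s = np.asarray(adata.layers["spliced"].sum(axis=1)).ravel()
    u = np.asarray(adata.layers["unspliced"].sum(axis=1)).ravel()
    if labels is None:
        labels = np.zeros(adata.n_obs, dtype=int)
    df = pd.DataFrame({"cluster": np.asarray(labels), "spliced": s, "unspliced": u})
    agg = df.groupby("cluster", observed=True).sum()
    agg.loc["global"] = [s.sum(), u.sum()]
    total = agg["spliced"] + agg["unspliced"]
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["fraction_unspliced"] = np.where(total > 0, agg["unspliced"] / total, np.nan)
    return agg


def knn_smooth(M, adjacency: sp.spmatrix) -> np.ndarray:
    """Average a spots x genes matrix over each spot's graph neighborhood
    (including the spot itself)."""
    M = np.asarray(M.todense() if sp.issparse(M) else M, dtype=np.float64)
    A = sp.csr_matrix(adjacency) + sp.eye(adjacency.shape[0], format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    return sp.diags(1.0 / deg) @ A @ M


def fit_gamma(spliced, unspliced, quantile: float = 0.05,
              min_spots: int = 10) -> pd.Series:
    """Per-gene steady-state ratio from extreme-quantile regression.

    ``gamma_g`` is the zero-intercept least-squares slope of u on s over the
    union of the top and bottom ``quantile`` spots of s.  Genes with fewer
    than ``min_spots`` usable spots or all-zero s are dropped.
    """
    if not (0 < quantile < 0.5):
        raise ConfigurationError("quantile must lie in (0, 0.5)")
    S = np.asarray(spliced.todense() if sp.issparse(spliced) else spliced, dtype=np.float64)
    U = np.asarray(unspliced.todense() if sp.issparse(unspliced) else unspliced,
                   dtype=np.float64)
    n_spots, n_genes = S.shape
    k = max(int(np.ceil(quantile * n_spots)), 1)
    order = np.argsort(S, axis=0, kind="stable")
    extreme = np.concatenate([order[:k], order[-k:]], axis=0)  # 2k x genes
    gammas = np.full(n_genes, np.nan)
    cols = np.arange(n_genes)
    Se = S[extreme, cols[None, :]]
    Ue = U[extreme, cols[None, :]]
    ss = (Se * Se).sum(axis=0)
    us = (Ue * Se).sum(axis=0)
    usable = (Se > 0).sum(axis=0) + (Ue > 0).sum(axis=0)
    ok = (ss > 0) & (usable >= min_spots) & (S.sum(axis=0) > 0)
    gammas[ok] = us[ok] / ss[ok]
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("gamma fit dropped %d genes (all-zero or too few usable spots)",
                    n_dropped)
    return pd.Series(gammas)


def compute_velocity(spliced, unspliced, gamma: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Velocity ``v = u - gamma * s`` and its per-spot L2 magnitude."""
    S = np.asarray(spliced.todense() if sp.issparse(spliced) else spliced, dtype=np.float64)
    U = np.asarray(unspliced.todense() if sp.issparse(unspliced) else unspliced,
                   dtype=np.float64)
    V = U - np.asarray(gamma)[None, :] * S
    return V, np.linalg.norm(V, axis=1)


def contributions(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared entries of the unit-normalized velocity vectors.

    Returns ``(C, included)`` where rows of ``C`` sum to 1 for included
    spots; spots with zero velocity are excluded (and logged).
    """
    V = np.asarray(V, dtype=np.float64)
    norms = np.linalg.norm(V, axis=1)
    included = norms > 0
    if (~included).sum():
        logger.info("%d zero-velocity spots excluded from contributions",
                    int((~included).sum()))
    C = np.zeros_like(V)
    C[included] = (V[included] / norms[included, None]) ** 2
    return C, included


def top_contributors(C: np.ndarray, gene_names, labels, cluster, k: int = 5,
                     included=None) -> pd.DataFrame:
    """Count, per gene, the cluster spots where it ranks in the top-k
    contributions; ties broken by gene order.

    Returns a table (gene, count, pct_spots) sorted by decreasing count,
    with ``pct_spots`` the percentage of the cluster's analyzed spots.
    """
    gene_names = pd.Index(gene_names)
    if k > len(gene_names):
        raise ConfigurationError(f"k={k} exceeds the number of fitted genes")
    labels = np.asarray(labels)
    mask = labels == cluster
    if included is not None:
        mask = mask & np.asarray(included)
    if not mask.any():
        raise ConfigurationError(f"cluster {cluster!r} has no analyzed spots")
    sub = C[mask]
    n_spots = sub.shape[0]
    counts = np.zeros(len(gene_names), dtype=int)
    gene_order = np.arange(sub.shape[1])
    for i in range(n_spots):
        top = np.lexsort((gene_order, -sub[i]))[:k]
        counts[top] += 1
    table = pd.DataFrame({"gene": gene_names, "count": counts,
                          "pct_spots": 100.0 * counts / n_spots})
    table = table[table["count"] > 0]
    table = table.sort_values(["count", "gene"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    table.attrs["cluster"] = cluster
    table.attrs["n_spots"] = n_spots
    return table


def project_spatial(V: np.ndarray, expression: np.ndarray, adjacency: sp.spmatrix,
                    pixel_coords: np.ndarray, kernel_scale: float = 0.1) -> np.ndarray:
    """Project velocities onto tissue coordinates.

    For spot ``i`` with graph neighbors ``j``: the expression displacement
    ``delta_ij = x_j - x_i`` (unit-normalized, velocity-gene space) is
    compared with ``v_i`` by cosine similarity; neighbor weights are a
    softmax of cosine / ``kernel_scale``; the arrow is the weighted mean of
    the unit pixel-space directions to the neighbors minus their plain mean
    (so an uninformative velocity yields a zero arrow).  Spots with zero
    velocity get zero arrows.
    """
    V = np.asarray(V, dtype=np.float64)
    X = np.asarray(expression, dtype=np.float64)
    P = np.asarray(pixel_coords, dtype=np.float64)
    A = sp.csr_matrix(adjacency)
    n = V.shape[0]
    arrows = np.zeros((n, 2))
    for i in range(n):
        v = V[i]
        vnorm = np.linalg.norm(v)
        if vnorm == 0:
            continue
        nbrs = A.indices[A.indptr[i]:A.indptr[i + 1]]
        nbrs = nbrs[nbrs != i]
        if len(nbrs) == 0:
            continue
        delta = X[nbrs] - X[i]
        dn = np.linalg.norm(delta, axis=1)
        keep = dn > 0
        nbrs, delta, dn = nbrs[keep], delta[keep], dn[keep]
        if len(nbrs) == 0:
            continue
        cos = (delta @ v) / (dn * vnorm)
        w = np.exp((cos - cos.max()) / kernel_scale)
        w /= w.sum()
        step = P[nbrs] - P[i]
        sn = np.linalg.norm(step, axis=1)
        sn[sn == 0] = 1.0
        shat = step / sn[:, None]
        arrows[i] = w @ shat - shat.mean(axis=0)
    return arrows


def plot_arrows(pixel_coords, arrows, path, color=None) -> None:
    """Render the spatial velocity arrows as a simple quiver plot file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    P = np.asarray(pixel_coords, dtype=np.float64)
    A = np.asarray(arrows, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.quiver(P[:, 0], P[:, 1], A[:, 0], A[:, 1], color=color, angles="xy",
              width=0.002)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: row coordinate grows downward
    ax.set_xlabel("pixel x")
    ax.set_ylabel("pixel y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class SteadyStateVelocity(BaseEstimator):
    """End-to-end steady-state velocity model on an AnnData with layers.

    ``fit`` selects HVGs on the normalized spliced layer, embeds with PCA,
    builds the neighbor graph, pools both layers over it, fits per-gene
    gamma and computes velocities and per-spot magnitudes.

    Attributes (after ``fit``): ``genes_``, ``gamma_``, ``velocity_``,
    ``magnitude_``, ``graph_``, ``embedding_``, ``ms_``, ``mu_``.
    """

    def __init__(self, n_hvg: int = 2000, n_pcs: int = 30, n_neighbors: int = 30,
                 quantile: float = 0.05, min_spots: int = 10, smooth: bool = True,
                 kernel_scale: float = 0.1):
        self.n_hvg = n_hvg
        self.n_pcs = n_pcs
        self.n_neighbors = n_neighbors
        self.quantile = quantile
        self.min_spots = min_spots
        self.smooth = smooth
        self.kernel_scale = kernel_scale

    def fit(self, adata: ad.AnnData):
        for layer in ("spliced", "unspliced"):
            if layer not in adata.layers:
                raise ConfigurationError(
                    f"velocity requires a {layer!r} layer; run the spliced/unspliced "
                    "quantification (or the kinetics simulation) first"
                )
        Sn, _ = normalize_matrix(adata.layers["spliced"])
        hvg = select_hvg(Sn, adata.var_names, min(self.n_hvg, adata.n_vars))
        hvg_idx = adata.var_names.get_indexer(hvg)
        self.embedding_ = embed_pca(Sn[:, hvg_idx], n_components=self.n_pcs)
        self.graph_ = build_knn(self.embedding_, k=self.n_neighbors)

        S = adata.layers["spliced"][:, hvg_idx]
        U = adata.layers["unspliced"][:, hvg_idx]
        if self.smooth:
            Ms = knn_smooth(S, self.graph_)
            Mu = knn_smooth(U, self.graph_)
        else:
            Ms = np.asarray(S.todense() if sp.issparse(S) else S, dtype=np.float64)
            Mu = np.asarray(U.todense() if sp.issparse(U) else U, dtype=np.float64)

        gamma = fit_gamma(Ms, Mu, quantile=self.quantile, min_spots=self.min_spots)
        fitted = gamma.notna().to_numpy()
        self.genes_ = pd.Index(hvg)[fitted]
        self.gamma_ = pd.Series(gamma.to_numpy()[fitted], index=self.genes_)
        self.ms_ = Ms[:, fitted]
        self.mu_ = Mu[:, fitted]
        V, mag = compute_velocity(self.ms_, self.mu_, self.gamma_.to_numpy())
        self.velocity_ = V
        self.magnitude_ = mag
        return self

    def spatial_arrows(self, pixel_coords) -> np.ndarray:
        return project_spatial(self.velocity_, self.ms_, self.graph_,
                               pixel_coords, kernel_scale=self.kernel_scale)
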