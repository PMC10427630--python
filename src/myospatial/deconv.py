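"""Seeded-NMF-regression spot deconvolution into cell types.

The model learns one non-negative topic per cell type from a labelled
single-nucleus reference: the gene x topic basis ``W`` is seeded with the
cell type's marker genes and the topic x nucleus coefficients ``H`` with the
nucleus labels, then refined by multiplicative Frobenius updates.  Per-type
topic signatures are the L1-normalized median of the ``H`` columns of that
type.  Spots are deconvolved in two non-negative least-squares stages:
spot profile -> topic coefficients on ``W``, then topic coefficients ->
cell-type weights on the topic signatures.  Weights below a pruning
threshold are zeroed and the rest renormalized to a proportion simplex.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.decomposition import NMF

from .errors import ConfigurationError, UnidentifiableModelWarning
from .preprocess import normalize_matrix, rank_markers, select_hvg

logger = logging.getLogger(__name__)


def subsample_reference(reference: ad.AnnData, n_per_type: int = 70,
                        seed: int = 0) -> ad.AnnData:
    """Uniform without-replacement subsample of nuclei per cell type.

    Types with fewer than ``n_per_type`` nuclei keep all of them (warned).
    """
    labels = reference.obs["cell_type"].astype(str)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for ct in pd.unique(labels):
        idx = np.flatnonzero((labels == ct).to_numpy())
        if len(idx) == 0:
            raise ConfigurationError(f"cell type {ct!r} has no nuclei")
        if len(idx) <= n_per_type:
            if len(idx) < n_per_type:
                warnings.warn(f"cell type {ct!r}: only {len(idx)} nuclei available")
            keep.append(idx)
        else:
            keep.append(np.sort(rng.choice(idx, size=n_per_type, replace=False)))
    return reference[np.concatenate(keep)].copy()


class SeededNMFDeconvolver(BaseEstimator):
    """Seeded NMF regression deconvolution (one topic per cell type).

    Parameters
    ----------
    n_hvg : int
        Highly variable genes selected on the normalized reference; the
        model gene space is their union with the reference marker genes.
    n_per_type : int
        Nuclei subsampled per cell type before factorization.
    min_contribution : float
        Per-spot cell-type weights below this fraction of the total are
        pruned to exactly zero.
    seed_eps : float
        Background value of the seeded initialization (the "on" entries
        start at 1).

    Attributes (after ``fit``)
    --------------------------
    W_ : ndarray, genes x topics non-negative basis.
    topic_signatures_ : DataFrame, cell type x topic, rows L1-normalized.
    genes_ : Index of the model gene space.
    cell_types_ : list of cell-type names (one topic each).
    identifiable_ : False when the learned signatures are mutually
        indistinguishable (no usable cell-type signal).
    """

    def __init__(self, n_hvg: int = 3000, n_per_type: int = 70,
                 min_contribution: float = 0.01, max_iter: int = 500,
                 tol: float = 1e-5, seed_eps: float = 1e-3, random_state: int = 0):
        self.n_hvg = n_hvg
        self.n_per_type = n_per_type
        self.min_contribution = min_contribution
        self.max_iter = max_iter
        self.tol = tol
        self.seed_eps = seed_eps
        self.random_state = random_state

    def fit(self, reference: ad.AnnData, markers: pd.DataFrame | None = None):
        """Learn the topic model from a labelled reference.

        ``markers`` is a marker table computed on the reference (cluster
        column = cell type); when omitted it is computed here with the
        default marker parameters.
        """
        reference = subsample_reference(reference, self.n_per_type, self.random_state)
        labels = reference.obs["cell_type"].astype(str).to_numpy()
        cell_types = list(pd.unique(labels))
        Xn, _ = normalize_matrix(reference.X)

        if markers is None:
            markers = rank_markers(Xn, reference.var_names, labels)
        marker_sets = {
            ct: set(markers.loc[markers["cluster"].astype(str) == ct, "gene"])
            for ct in cell_types
        }
        for ct, ms in marker_sets.items():
            if not ms:
                raise ConfigurationError(
                    f"cell type {ct!r} has no markers; recompute markers on the "
                    "reference (the signatures may carry no signal)"
                )

        n_hvg = min(self.n_hvg, reference.n_vars)
        hvg = select_hvg(Xn, reference.var_names, n_hvg)
        marker_genes = set().union(*marker_sets.values())
        genes = reference.var_names[
            reference.var_names.isin(set(hvg).union(marker_genes))
        ]
        gi = reference.var_names.get_indexer(genes)
        V = np.asarray(Xn[:, gi].todense()).T  # genes x nuclei

        k = len(cell_types)
        eps = self.seed_eps
        W0 = np.full((V.shape[0], k), eps)
        H0 = np.full((k, V.shape[1]), eps)
        gene_pos = pd.Series(np.arange(len(genes)), index=genes)
        for t, ct in enumerate(cell_types):
            mg = [g for g in marker_sets[ct] if g in gene_pos.index]
            W0[gene_pos.loc[mg].to_numpy(), t] = 1.0
            H0[t, labels == ct] = 1.0

        model = NMF(n_components=k, init="custom", solver="mu",
                    beta_loss="frobenius", tol=self.tol, max_iter=self.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter reached is acceptable
            W = model.fit_transform(V, W=W0, H=H0)
        H = model.components_

        signatures = np.zeros((k, k))
        for t, ct in enumerate(cell_types):
            med = np.median(H[:, labels == ct], axis=1)
            total = med.sum()
            signatures[t] = med / total if total > 0 else med
        self.W_ = W
        self.H_ref_ = H
        self.topic_signatures_ = pd.DataFrame(signatures, index=cell_types)
        self.genes_ = genes
        self.cell_types_ = cell_types
        self.reconstruction_err_ = float(model.reconstruction_err_)

        # identifiability: signatures must separate the types
        sig_norm = signatures / np.maximum(
            np.linalg.norm(signatures, axis=1, keepdims=True), 1e-12)
        cos = sig_norm @ sig_norm.T
        off = cos[~np.eye(k, dtype=bool)]
        self.identifiable_ = bool(len(off) == 0 or off.max() < 0.999)
        if not self.identifiable_:
            warnings.warn(
                "topic signatures are mutually indistinguishable; the model is "
                "unidentifiable on this reference", UnidentifiableModelWarning)
        return self

    def predict(self, spots: ad.AnnData) -> pd.DataFrame:
        """Deconvolve spots into cell-type proportions.

        Spots are median-ratio normalized, restricted to the model gene
        space, regressed on ``W`` (NNLS) and the resulting topic
        coefficients regressed on the topic signatures (NNLS); weights below
        ``min_contribution`` of the total are pruned before L1
        renormalization.  All-zero spots yield an all-zero, flagged row.
        """
        Xn, _ = normalize_matrix(spots.X)
        missing = ~self.genes_.isin(spots.var_names)
        if missing.any():
            warnings.warn(f"{int(missing.sum())} model genes absent from spots; treated as zero")
        gi = spots.var_names.get_indexer(self.genes_[~missing])
        Y = np.zeros((spots.n_obs, len(self.genes_)))
        Y[:, np.flatnonzero(~missing)] = np.asarray(Xn[:, gi].todense())

        S = self.topic_signatures_.to_numpy()  # types x topics
        k = len(self.cell_types_)
        props = np.zeros((spots.n_obs, k))
        residuals = np.zeros(spots.n_obs)
        degenerate = np.zeros(spots.n_obs, dtype=bool)
        for i in range(spots.n_obs):
            y = Y[i]
            if not y.any():
                degenerate[i] = True
                continue
            h, rnorm = nnls(self.W_, y)
            residuals[i] = rnorm
            w, _ = nnls(S.T, h)
            total = w.sum()
            if total <= 0:
                degenerate[i] = True
                continue
            w[w < self.min_contribution * total] = 0.0
            total = w.sum()
            if total <= 0:
                degenerate[i] = True
                continue
            props[i] = w / total
        if degenerate.any():
            logger.warning("%d spots had no usable signal; all-zero proportions",
                           int(degenerate.sum()))
        out = pd.DataFrame(props, index=spots.obs_names, columns=self.cell_types_)
        out.attrs["residual_norm"] = pd.Series(residuals, index=spots.obs_names)
        out.attrs["degenerate"] = pd.Series(degenerate, index=spots.obs_names)
        out.attrs["min_contribution"] = self.min_contribution
        return out


def fit_topics(reference: ad.AnnData, markers: pd.DataFrame | None = None,
               n_hvg: int = 3000, seed: int = 0, **kwargs) -> SeededNMFDeconvolver:
    """Functional wrapper: fit the seeded topic model on a reference."""
    return SeededNMFDeconvolver(n_hvg=n_hvg, random_state=seed, **kwargs).fit(
        reference, markers=markers)


def deconvolve(spots: ad.AnnData, model: SeededNMFDeconvolver,
               min_contribution: float | None = None) -> pd.DataFrame:
    """Functional wrapper over :meth:`SeededNMFDeconvolver.predict`."""
    if min_contribution is not None:
        model.min_contribution = min_contribution
    return model.predict(spots)


def enrichment_by_cluster(proportions: pd.DataFrame, labels
                          ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Mean cell-type proportion per cluster, overall, and enrichment ratio.

    The ratio is cluster mean / overall mean; undefined ratios (overall mean
    zero) are returned as NaN.  The size-weighted average of cluster means
    equals the overall mean by construction.
    """
    labels = pd.Series(np.asarray(labels), index=proportions.index, name="cluster")
    cluster_means = proportions.groupby(labels, observed=True).mean()
    overall = proportions.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cluster_means / overall
    ratio = ratio.where(np.isfinite(ratio))
    return cluster_means, overall, ratio
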