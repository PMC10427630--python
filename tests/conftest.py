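"""Shared fixtures: the default synthetic muscle section and derived stages.

Session scope keeps the expensive pieces (generation, clustering, the
deconvolution fit, the velocity fit) computed once for the whole suite.
"""

from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import rankdata

from myospatial import deconv, preprocess, simdata, velocity


def make_adata(counts, genes=None, barcodes=None, **layers):
    """Small helper to build a spots x genes AnnData from a dense array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(g)]
    barcodes = list(barcodes) if barcodes is not None else [f"bc{i}" for i in range(n)]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=pd.Index(genes)),
    )
    for name, mat in layers.items():
        adata.layers[name] = sp.csr_matrix(np.asarray(mat))
    from myospatial.io import compute_qc

    compute_qc(adata)
    return adata


def exact_rank_sum_p(x, y, alternative="two-sided"):
    """Exhaustive permutation p-value of the Wilcoxon rank-sum statistic."""
    comb = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(comb)
    obs = ranks[:n1].sum()
    stats = np.array(
        [ranks[list(c)].sum() for c in combinations(range(len(comb)), n1)]
    )
    mu = n1 * (len(comb) + 1) / 2.0
    if alternative == "greater":
        return float((stats >= obs - 1e-9).mean())
    if alternative == "less":
        return float((stats <= obs + 1e-9).mean())
    return float((np.abs(stats - mu) >= abs(obs - mu) - 1e-9).mean())


@pytest.fixture(scope="session")
def fixture_config():
    return simdata.default_config(seed=1)


@pytest.fixture(scope="session")
def dataset(fixture_config):
    """(reference, tissue, geometry, truth) for the default section, seed 1."""
    return simdata.generate_dataset(fixture_config)


@pytest.fixture(scope="session")
def clustered(dataset):
    """Normalized tissue, PCA embedding and Leiden labels."""
    _, tissue, _, _ = dataset
    normed = preprocess.normalize(tissue)
    emb = preprocess.embed_pca(normed.X, n_components=30)
    labels = preprocess.KNNLeiden(n_neighbors=20, resolution=1.0, seed=0).fit(emb).labels_
    return normed, emb, labels


@pytest.fixture(scope="session")
def deconv_model(dataset):
    ref, _, _, _ = dataset
    return deconv.SeededNMFDeconvolver(random_state=1).fit(ref)


@pytest.fixture(scope="session")
def proportions(dataset, deconv_model):
    _, tissue, _, _ = dataset
    return deconv_model.predict(tissue)


@pytest.fixture(scope="session")
def velocity_model(dataset):
    _, tissue, _, _ = dataset
    return velocity.SteadyStateVelocity().fit(tissue)
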