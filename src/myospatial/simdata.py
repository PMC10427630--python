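"""Synthetic Visium-style muscle sections with known ground truth.

The generator emulates the statistical structure of a dystrophic-muscle
capture area: a labelled single-nucleus reference with per-cell-type marker
signatures, a spot grid tiled by histological regions (healthy fibers, a
connective-tissue band, an inflamed/calcified focus and a "transitioning"
ring around it), region-structured Dirichlet cell-type mixtures per spot,
negative-binomial counts, and spliced/unspliced layers obeying steady-state
kinetics ``E[u] = gamma * s`` except for induced driver genes in the
transitioning ring where ``E[u] = gamma * s * (1 + beta)``.

Counts are split into spliced/unspliced by a per-gene binomial partition, so
the two layers always sum to the original counts and upstream QC sees the
same matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError

# marker vocabularies per cell type (muscle-field gene symbols); disjoint by
# construction and padded with synthetic names when more markers are asked for
MARKER_VOCAB = {
    "IIx": ["Myh1", "Actn3", "Mybph", "Tnnt3", "Tnni2", "Pvalb", "Atp2a1", "Pygm",
            "Eno3", "Tnnc2", "Acta1", "Aldoa", "Pfkm", "Pkm", "Tpi1"],
    "IIb": ["Myh4", "Mylpf", "Ckm", "Amd1", "Smox", "Actn2", "Pgam2", "Mybpc2",
            "Myot", "Ttn", "Neb", "Des", "Myoz1", "Capn3", "Casq1"],
    "MPH": ["Cd68", "Cd14", "Lyz2", "Spp1", "Mgp", "Ctsk", "Tyrobp", "Mpeg1",
            "Lgals3", "Tgfbi", "Ctsb", "Tnfrsf1a", "Tnfrsf1b", "Cxcl14", "Cd52"],
    "FAP": ["Cd34", "Pdgfra", "Lox", "Col1a1", "Fn1", "Col1a2", "Vim", "Thbs4",
            "Bgn", "Dcn", "Fbn1", "Postn", "Col3a1", "Lum", "Mmp2"],
    "TC": ["Fmod", "Tnmd", "Scx", "Comp", "Col12a1", "Kera", "Fibin", "Thbs1",
           "Cilp", "Cilp2", "Prg4", "Chad", "Emilin1", "Sparcl1", "Aspn"],
    "MTJ": ["Col22a1", "Ankrd1", "Adamtsl2", "Itgb1", "Lamb1", "Tigd4", "Pdzrn4",
            "Sorbs2", "Flnc", "Xirp2", "Lars2", "Mybpc1", "Enah", "Svil", "Palld"],
    "NMJ": ["Chrne", "Mpz", "Mbp", "Pmp22", "Chrna1", "Musk", "Agrn", "Chrnd",
            "Colq", "Ache", "Prph", "Ncam1", "Utrn", "Dok7", "Rapsn"],
    "RegMyon": ["Myog", "Myh3", "Myl4", "Igfbp7", "Hspg2", "Sparc", "Gsn", "Fhl1",
                "Myh8", "Tnnt2", "Mest", "Igf2", "Nrep", "Runx1", "Cdkn1a"],
}

MITO_GENE_NAMES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


@dataclass
class CellTypeSpec:
    name: str
    n_markers: int = 15
    marker_fold: float = 20.0
    n_nuclei: int = 150


@dataclass
class RegionSpec:
    """One histological region on the spot grid.

    ``shape`` is one of ``disc``, ``annulus``, ``strip`` or ``rest`` with
    shape parameters in ``params`` (grid units).  ``proportions`` is the
    Dirichlet mean over cell types; for annuli an optional
    ``proportions_far`` gives the mean at the outer edge, with a linear
    radial gradient in between (the transitioning-ring construction).
    ``concentration = inf`` makes per-spot proportions exactly the mean.
    """

    name: str
    shape: str
    params: dict = field(default_factory=dict)
    proportions: dict = field(default_factory=dict)
    proportions_far: dict | None = None
    concentration: float = 20.0
    induced: bool = False


@dataclass
class GridSpec:
    n_rows: int = 40
    n_cols: int = 40
    spacing: float = 100.0
    tissue_radius: float = 19.5
    center: tuple[float, float] = (19.5, 19.5)


@dataclass
class DepthSpec:
    """Negative-binomial depth model (mean total counts and dispersions)."""

    mean: float = 3000.0
    dispersion: float = 15.0       # NB size of the per-spot total
    gene_dispersion: float = 2.0   # NB size of per-gene counts; inf => Poisson
    ref_mean: float = 4000.0


@dataclass
class KineticsSpec:
    n_drivers: int = 12
    gamma_range: tuple[float, float] = (0.2, 0.6)
    induction_beta: float = 4.0
    baseline_unspliced_fraction: float = 0.20


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 1500
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    regions: list[RegionSpec] = field(default_factory=list)
    grid: GridSpec = field(default_factory=GridSpec)
    depth: DepthSpec = field(default_factory=DepthSpec)
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    include_mito: bool = True


@dataclass
class GroundTruth:
    """Known quantities behind a generated dataset."""

    signatures: pd.DataFrame | None = None      # cell type x gene relative expression
    markers: dict | None = None                 # cell type -> list of marker genes
    regions: pd.Series | None = None            # spot -> region name
    proportions: pd.DataFrame | None = None     # spot x cell type
    induced: pd.Series | None = None            # spot -> bool
    gamma: pd.Series | None = None              # gene -> true unspliced/spliced ratio
    drivers: list | None = None                 # induced driver genes


def default_config(seed: int = 0, marker_fold: float = 20.0) -> SimConfig:
    """The desk-scale muscle-section fixture: 40x40 grid (~1,200 in-tissue
    spots), 1,500 genes, 8 cell types, 4 regions."""
    types = [CellTypeSpec(name, marker_fold=marker_fold) for name in
             ("IIx", "IIb", "MPH", "FAP", "TC", "MTJ", "NMJ", "RegMyon")]
    # region mixtures give every cell type a distinct spatial pattern, the
    # way real sections localize NMJ nuclei, tenocytes or macrophages
    muscle = {"IIx": 0.46, "IIb": 0.33, "MPH": 0.03, "FAP": 0.04,
              "TC": 0.03, "MTJ": 0.03, "NMJ": 0.01, "RegMyon": 0.07}
    connective = {"IIx": 0.07, "IIb": 0.04, "MPH": 0.05, "FAP": 0.21,
                  "TC": 0.27, "MTJ": 0.19, "NMJ": 0.15, "RegMyon": 0.02}
    focus = {"IIx": 0.05, "IIb": 0.03, "MPH": 0.42, "FAP": 0.25,
             "TC": 0.04, "MTJ": 0.02, "NMJ": 0.01, "RegMyon": 0.18}

    def mix(a, b, t):
        return {k: (1 - t) * a[k] + t * b[k] for k in a}

    regions = [
        RegionSpec("focus", "disc", {"center": (20.0, 26.0), "radius": 5.0},
                   proportions=focus, concentration=20.0),
        RegionSpec("ring", "annulus",
                   {"center": (20.0, 26.0), "r_inner": 5.0, "r_outer": 10.0},
                   proportions=mix(muscle, focus, 0.60),
                   proportions_far=mix(muscle, focus, 0.25),
                   concentration=20.0, induced=True),
        RegionSpec("connective", "strip", {"col_max": 5.5},
                   proportions=connective, concentration=20.0),
        RegionSpec("muscle", "rest", proportions=muscle, concentration=20.0),
    ]
    return SimConfig(seed=seed, cell_types=types, regions=regions)


def _rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(3)
    return {name: np.random.default_rng(k)
            for name, k in zip(("reference", "tissue", "kinetics"), kids)}


def _gene_table(config: SimConfig) -> tuple[pd.Index, dict[str, list[str]]]:
    """Gene name list and the disjoint marker assignment per cell type."""
    markers: dict[str, list[str]] = {}
    seen: set[str] = set()
    for ct in config.cell_types:
        vocab = MARKER_VOCAB.get(ct.name, [])
        names = list(vocab[: ct.n_markers])
        while len(names) < ct.n_markers:
            names.append(f"{ct.name}.m{len(names):02d}")
        for g in names:
            if g in seen:
                raise ConfigurationError(f"marker gene {g!r} assigned to multiple cell types")
            seen.add(g)
        markers[ct.name] = names
    mito = list(MITO_GENE_NAMES) if config.include_mito else []
    n_fill = config.n_genes - len(seen) - len(mito)
    if n_fill < 0:
        raise ConfigurationError("n_genes too small for the marker sets")
    fill = [f"Gene{i:04d}" for i in range(n_fill)]
    genes = pd.Index([g for ms in markers.values() for g in ms] + mito + fill)
    return genes, markers


def _nb(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draw with mean/size parameterization (inf => Poisson)."""
    mean = np.asarray(mean, dtype=np.float64)
    if math.isinf(size_param):
        return rng.poisson(mean)
    p = size_param / (size_param + np.maximum(mean, 1e-300))
    return rng.negative_binomial(size_param, p)


def generate_reference(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate the labelled single-nucleus reference.

    Marker genes of type ``t`` have their expected expression multiplied by
    ``marker_fold`` in type ``t`` only; counts are negative-binomial around
    ``depth * signature``.
    """
    if len(config.cell_types) < 2:
        raise ConfigurationError("at least two cell types are required")
    for ct in config.cell_types:
        if ct.n_nuclei < 50:
            raise ConfigurationError(f"cell type {ct.name!r}: at least 50 nuclei required")
    rng = _rngs(config)["reference"]
    genes, markers = _gene_table(config)
    n_genes = len(genes)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    # give every type's marker block the same summed base expression, so the
    # realized cross-type marker enrichment equals marker_fold instead of
    # being distorted by the per-type signature normalization
    block_budget = base.mean()
    for ct in config.cell_types:
        idx = genes.get_indexer(markers[ct.name])
        base[idx] *= block_budget * len(idx) / base[idx].sum()
    signatures = {}
    for ct in config.cell_types:
        rel = base.copy()
        idx = genes.get_indexer(markers[ct.name])
        rel[idx] *= ct.marker_fold
        signatures[ct.name] = rel / rel.sum()
    sig_df = pd.DataFrame(signatures, index=genes).T

    rows, labels = [], []
    for ct in config.cell_types:
        depth = _nb(rng, np.full(ct.n_nuclei, config.depth.ref_mean), config.depth.dispersion)
        mean = depth[:, None] * sig_df.loc[ct.name].to_numpy()[None, :]
        rows.append(_nb(rng, mean, config.depth.gene_dispersion))
        labels.extend([ct.name] * ct.n_nuclei)
    X = sp.csr_matrix(np.vstack(rows))
    obs = pd.DataFrame({"cell_type": pd.Categorical(labels)})
    obs.index = [f"NUC-{i:05d}" for i in range(X.shape[0])]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    truth = GroundTruth(signatures=sig_df, markers=markers)
    return adata, truth


def _region_masks(config: SimConfig, rr: np.ndarray, cc: np.ndarray,
                  tissue: np.ndarray) -> pd.Series:
    """Resolve region shapes to a per-spot region label (tiling check)."""
    labels = np.array([""] * len(rr), dtype=object)
    claimed = np.zeros(len(rr), dtype=bool)
    rest = None
    for reg in config.regions:
        if reg.shape == "rest":
            if rest is not None:
                raise ConfigurationError("only one 'rest' region is allowed")
            rest = reg
            continue
        if reg.shape == "disc":
            r0, c0 = reg.params["center"]
            d = np.hypot(rr - r0, cc - c0)
            mask = d <= reg.params["radius"]
        elif reg.shape == "annulus":
            r0, c0 = reg.params["center"]
            d = np.hypot(rr - r0, cc - c0)
            mask = (d > reg.params["r_inner"]) & (d <= reg.params["r_outer"])
        elif reg.shape == "strip":
            mask = np.ones(len(rr), dtype=bool)
            if "col_min" in reg.params:
                mask &= cc >= reg.params["col_min"]
            if "col_max" in reg.params:
                mask &= cc <= reg.params["col_max"]
        else:
            raise ConfigurationError(f"unknown region shape {reg.shape!r}")
        mask &= tissue
        if (mask & claimed).any():
            raise ConfigurationError(f"region {reg.name!r} overlaps an earlier region")
        labels[mask] = reg.name
        claimed |= mask
    remaining = tissue & ~claimed
    if remaining.any():
        if rest is None:
            raise ConfigurationError("regions do not tile the tissue and no 'rest' region given")
        labels[remaining] = rest.name
    return pd.Series(labels)


def generate_tissue(config: SimConfig, truth: GroundTruth
                    ) -> tuple[ad.AnnData, pd.DataFrame, GroundTruth]:
    """Simulate one capture area from the reference ground truth.

    Each spot's expected expression is ``depth * sum_t p_t signature_t``
    with ``p ~ Dirichlet(region)``; counts are negative-binomial around the
    expectation.  Returns the AnnData (in-tissue spots), the full-grid
    geometry table and the augmented ground truth.
    """
    if truth.signatures is None:
        raise ConfigurationError("reference ground truth with signatures is required")
    rng = _rngs(config)["tissue"]
    grid = config.grid
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    rr, cc = rows.ravel().astype(float), cols.ravel().astype(float)
    tissue = np.hypot(rr - grid.center[0], cc - grid.center[1]) <= grid.tissue_radius
    region = _region_masks(config, rr, cc, tissue)

    barcodes = np.array([f"SYN-{i:04d}-1" for i in range(len(rr))])
    geometry = pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": tissue.astype(int).astype(bool),
            "array_row": rows.ravel(),
            "array_col": cols.ravel(),
            "pxl_row_in_fullres": rr * grid.spacing,
            "pxl_col_in_fullres": cc * grid.spacing,
        }
    )

    type_names = list(truth.signatures.index)
    sig = truth.signatures.to_numpy()
    reg_by_name = {r.name: r for r in config.regions}
    in_idx = np.flatnonzero(tissue)
    n_spots = len(in_idx)

    props = np.zeros((n_spots, len(type_names)))
    induced = np.zeros(n_spots, dtype=bool)
    for j, i in enumerate(in_idx):
        reg = reg_by_name[region.iloc[i]]
        mean = np.array([reg.proportions[t] for t in type_names])
        if reg.proportions_far is not None and reg.shape == "annulus":
            r0, c0 = reg.params["center"]
            d = np.hypot(rr[i] - r0, cc[i] - c0)
            t = (d - reg.params["r_inner"]) / (reg.params["r_outer"] - reg.params["r_inner"])
            far = np.array([reg.proportions_far[tn] for tn in type_names])
            mean = (1 - t) * mean + t * far
        if abs(mean.sum() - 1.0) > 1e-6:
            raise ConfigurationError(f"region {reg.name!r}: proportions do not sum to 1")
        if math.isinf(reg.concentration):
            props[j] = mean
        else:
            props[j] = rng.dirichlet(np.maximum(reg.concentration * mean, 1e-3))
        induced[j] = reg.induced

    depth = _nb(rng, np.full(n_spots, config.depth.mean), config.depth.dispersion)
    mean_expr = depth[:, None] * (props @ sig)
    counts = _nb(rng, mean_expr, config.depth.gene_dispersion)

    in_barcodes = barcodes[in_idx]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=geometry.iloc[in_idx].set_index("barcode", drop=False).rename_axis(None),
        var=pd.DataFrame(index=truth.signatures.columns),
    )
    adata.obs["region"] = region.iloc[in_idx].to_numpy()
    from .io import compute_qc

    compute_qc(adata)
    truth.regions = pd.Series(region.iloc[in_idx].to_numpy(), index=in_barcodes)
    truth.proportions = pd.DataFrame(props, index=in_barcodes, columns=type_names)
    truth.induced = pd.Series(induced, index=in_barcodes)
    return adata, geometry, truth


def generate_kinetics(config: SimConfig, adata: ad.AnnData, truth: GroundTruth
                      ) -> tuple[ad.AnnData, GroundTruth]:
    """Partition counts into spliced/unspliced layers with known kinetics.

    Per gene a split probability ``q = gamma / (1 + gamma)`` realizes the
    steady state ``E[u] = gamma * s``.  ``gamma_range`` sets the relative
    heterogeneity of the raw gammas; the split probabilities are then
    rescaled by one global factor so the expression-weighted unspliced
    fraction equals ``baseline_unspliced_fraction``, and the calibrated
    ratio is stored as the ground-truth gamma.  Driver genes in induced
    spots use ``q`` derived from ``gamma * (1 + beta)`` instead.
    """
    kin = config.kinetics
    if kin.n_drivers > adata.n_vars:
        raise ConfigurationError("n_drivers exceeds the number of genes")
    if truth.induced is None:
        raise ConfigurationError("tissue ground truth with induction flags is required")
    if kin.n_drivers > 0 and kin.induction_beta > 0 and not truth.induced.any():
        raise ConfigurationError("kinetics requested but no induced region present in tissue")
    rng = _rngs(config)["kinetics"]

    counts = np.asarray(adata.X.todense()).astype(np.int64)
    n_genes = adata.n_vars
    gamma_raw = rng.uniform(kin.gamma_range[0], kin.gamma_range[1], size=n_genes)
    q_raw = gamma_raw / (1.0 + gamma_raw)
    weights = counts.sum(axis=0).astype(np.float64)
    weights = weights / max(weights.sum(), 1.0)
    scale = kin.baseline_unspliced_fraction / float((weights * q_raw).sum())
    q = np.clip(scale * q_raw, 1e-4, 0.95)
    gamma_true = q / (1.0 - q)

    # drivers: markers of the focal-region-dominant cell types (the genes
    # the transitioning spots are actively inducing), taken in decreasing
    # order of tissue expression so the planted kinetic signal is carried by
    # well-detected genes
    candidates = []
    if truth.markers:
        for ct in ("MPH", "FAP"):
            candidates.extend(truth.markers.get(ct, []))
    candidates = [g for g in candidates if g in adata.var_names]
    totals = pd.Series(counts.sum(axis=0), index=adata.var_names)
    candidates.sort(key=lambda g: (-totals[g], g))
    if len(candidates) < kin.n_drivers:
        expressed = totals[totals > 0].sort_values(ascending=False).index
        candidates.extend([g for g in expressed if g not in candidates])
    drivers = list(candidates[: kin.n_drivers])
    driver_idx = adata.var_names.get_indexer(drivers)

    qmat = np.broadcast_to(q, counts.shape).copy()
    induced_rows = np.flatnonzero(truth.induced.to_numpy())
    g_ind = gamma_true[driver_idx] * (1.0 + kin.induction_beta)
    qmat[np.ix_(induced_rows, driver_idx)] = g_ind / (1.0 + g_ind)

    unspliced = rng.binomial(counts, qmat)
    spliced = counts - unspliced
    adata.layers["spliced"] = sp.csr_matrix(spliced)
    adata.layers["unspliced"] = sp.csr_matrix(unspliced)
    truth.gamma = pd.Series(gamma_true, index=adata.var_names)
    truth.drivers = drivers
    return adata, truth


def generate_dataset(config: SimConfig
                     ) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame, GroundTruth]:
    """Reference + tissue + kinetics in one call.

    Returns ``(reference, tissue, geometry, truth)``.
    """
    reference, truth = generate_reference(config)
    tissue, geometry, truth = generate_tissue(config, truth)
    tissue, truth = generate_kinetics(config, tissue, truth)
    return reference, tissue, geometry, truth


def write_dataset(outdir, reference: ad.AnnData, tissue: ad.AnnData,
                  geometry: pd.DataFrame, truth: GroundTruth) -> None:
    """Write the synthetic dataset in the on-disk formats the readers accept,
    plus ground-truth TSVs (proportions, regions, gammas)."""
    from pathlib import Path

    from .io import write_mtx_trio, write_tissue_positions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx_trio(outdir / "matrix", tissue.X, tissue.var_names, tissue.obs_names)
    for layer in ("spliced", "unspliced"):
        if layer in tissue.layers:
            write_mtx_trio(outdir / layer, tissue.layers[layer],
                           tissue.var_names, tissue.obs_names)
    write_tissue_positions(outdir / "tissue_positions.csv", geometry)
    write_mtx_trio(outdir / "reference", reference.X,
                   reference.var_names, reference.obs_names)
    reference.obs[["cell_type"]].to_csv(outdir / "reference_labels.tsv", sep="\t")
    if truth.proportions is not None:
        truth.proportions.to_csv(outdir / "truth_proportions.tsv", sep="\t")
    if truth.regions is not None:
        truth.regions.rename("region").to_csv(outdir / "truth_regions.tsv", sep="\t")
    if truth.gamma is not None:
        truth.gamma.rename("gamma").to_csv(outdir / "truth_gamma.tsv", sep="\t")
    if truth.drivers is not None:
        pd.Series(truth.drivers, name="driver").to_csv(
            outdir / "truth_drivers.tsv", sep="\t", index=False)
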