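"""End-to-end orchestration: load or simulate, QC, cluster, markers,
deconvolution, rule classification + DGE, velocity; artifacts and a
machine-readable summary are written to a run directory.

All stage defaults equal the published per-sample parameters (30 PCs / 20
neighbors for clustering, min.pct 0.1 / log2FC 0.25 markers, 70 nuclei per
type / 3000 HVG deconvolution, 2000 HVG / 30 PCs / 30 neighbors velocity);
the configuration file only needs to state deviations.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconv as deconv_mod
from . import histoclass, io, preprocess, simdata, velocity as velocity_mod
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": True,
    "sim": {"marker_fold": 20.0},
    "inputs": {
        "matrix_dir": None,
        "positions": None,
        "spliced_dir": None,
        "unspliced_dir": None,
        "reference_dir": None,
        "reference_labels": None,
    },
    "qc": {"preset": "D2mdx", "thresholds": None},
    "clustering": {"n_pcs": 30, "n_neighbors": 20, "resolution": 1.0, "seed": 0},
    "markers": {"min_pct": 0.1, "logfc_min": 0.25, "min_cells_feature": 5},
    "deconv": {"enabled": True, "n_per_type": 70, "n_hvg": 3000, "min_contribution": 0.01},
    "cluster_names": {
        "muscle": "muscle fibers",
        "connective": "connective tissue",
        "focus": "inflamed and/or calcified fibers",
        "ring": "transitioning fibers",
    },
    "rulesets": ["fibrosis", "calcification"],
    "velocity": {
        "enabled": True,
        "n_hvg": 2000,
        "n_pcs": 30,
        "n_neighbors": 30,
        "quantile": 0.05,
        "kernel_scale": 0.1,
        "top_k": 5,
    },
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        if key not in defaults and path not in ("cluster_names",):
            raise ConfigurationError(f"unknown config key {path + key!r}")
        if isinstance(value, dict) and isinstance(defaults.get(key), dict):
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def validate_config(config: dict | None) -> dict:
    """Normalize a run configuration: fill defaults, reject unknown keys,
    resolve QC presets and rule-set names."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    qc = cfg["qc"]
    if qc.get("thresholds"):
        t = qc["thresholds"]
        qc["resolved"] = preprocess.QCThresholds(
            t["nCount_min"], t["nCount_max"], t["nFeature_min"], t["nFeature_max"])
    else:
        preset = qc.get("preset")
        if preset not in preprocess.QC_PRESETS:
            raise ConfigurationError(
                f"unknown QC preset {preset!r}; known: {sorted(preprocess.QC_PRESETS)}")
        qc["resolved"] = preprocess.QC_PRESETS[preset]
    resolved_rules = []
    for rs in cfg["rulesets"]:
        if isinstance(rs, str):
            if rs not in histoclass.RULESETS:
                raise ConfigurationError(
                    f"unknown rule set {rs!r}; built-ins: {sorted(histoclass.RULESETS)}")
            resolved_rules.append(histoclass.RULESETS[rs])
        else:
            resolved_rules.append(histoclass.RuleSet.from_config(rs))
    cfg["rulesets_resolved"] = resolved_rules
    if not cfg["simulate"]:
        inputs = cfg["inputs"]
        if not inputs.get("matrix_dir") or not inputs.get("positions"):
            raise ConfigurationError("non-simulated runs need inputs.matrix_dir and inputs.positions")
        if cfg["velocity"]["enabled"] and not (
                inputs.get("spliced_dir") and inputs.get("unspliced_dir")):
            raise ConfigurationError(
                "velocity is enabled but inputs lack spliced/unspliced layer "
                "directories; disable velocity or provide the layers")
    return cfg


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh) or {}


def _load_inputs(cfg):
    """Return (tissue, reference, truth) either simulated or from disk."""
    if cfg["simulate"]:
        sim_cfg = simdata.default_config(seed=cfg["seed"],
                                         marker_fold=cfg["sim"]["marker_fold"])
        reference, tissue, _, truth = simdata.generate_dataset(sim_cfg)
        return tissue, reference, truth
    inputs = cfg["inputs"]
    layers = {}
    if inputs.get("spliced_dir"):
        layers["spliced"] = inputs["spliced_dir"]
    if inputs.get("unspliced_dir"):
        layers["unspliced"] = inputs["unspliced_dir"]
    tissue = io.assemble_dataset(inputs["matrix_dir"], inputs["positions"],
                                 layer_dirs=layers or None)
    reference = None
    if inputs.get("reference_dir"):
        X, genes, barcodes = io.read_mtx_trio(inputs["reference_dir"])
        labels = pd.read_csv(inputs["reference_labels"], sep="\t", index_col=0)
        import anndata as ad

        reference = ad.AnnData(X=X, obs=labels.loc[barcodes],
                               var=pd.DataFrame(index=genes))
    return tissue, reference, None


def _name_clusters(labels: np.ndarray, cfg: dict, truth) -> dict[int, str]:
    """Map integer cluster labels to annotation names.

    In simulated runs each cluster is named after its majority ground-truth
    region via the region -> name map; otherwise ``cluster_names`` maps the
    integer labels directly.
    """
    name_map = cfg["cluster_names"]
    out: dict[int, str] = {}
    if truth is not None and truth.regions is not None:
        regions = pd.Series(truth.regions.to_numpy())
        overall = regions.value_counts(normalize=True)
        for cl in np.unique(labels):
            inside = regions[labels == cl].value_counts(normalize=True)
            # name by the most enriched region, not the plain majority, so a
            # small focal region is not outvoted by surrounding spots
            enrich = (inside / overall.loc[inside.index]).sort_values(ascending=False)
            out[int(cl)] = name_map.get(enrich.index[0], str(enrich.index[0]))
    else:
        for cl in np.unique(labels):
            out[int(cl)] = str(name_map.get(str(cl), name_map.get(int(cl), cl)))
    return out


def run(config: dict | None, outdir) -> dict:
    """Execute the full pipeline and return the summary dictionary.

    Stage artifacts (cluster CSV, marker/proportion/DGE/velocity TSVs) and
    ``summary.json`` are written under ``outdir``.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": cfg["seed"]}

    tissue, reference, truth = _load_inputs(cfg)
    summary["n_spots_loaded"] = int(tissue.n_obs)
    summary["n_genes_loaded"] = int(tissue.n_vars)

    tissue = preprocess.drop_mito_genes(tissue)
    tissue = preprocess.qc_filter(tissue, cfg["qc"]["resolved"])
    if truth is not None:
        keep = tissue.obs_names
        truth.regions = truth.regions.loc[keep]
        truth.proportions = truth.proportions.loc[keep]
        truth.induced = truth.induced.loc[keep]
    summary["n_spots_after_qc"] = int(tissue.n_obs)
    summary["n_genes_after_mito"] = int(tissue.n_vars)

    normed = preprocess.normalize(tissue)
    clus = cfg["clustering"]
    embedding = preprocess.embed_pca(normed.X, n_components=clus["n_pcs"])
    model = preprocess.KNNLeiden(n_neighbors=clus["n_neighbors"],
                                 resolution=clus["resolution"], seed=clus["seed"]).fit(embedding)
    labels = model.labels_
    cluster_names = _name_clusters(labels, cfg, truth)
    named = np.array([cluster_names[int(l)] for l in labels], dtype=object)
    pd.DataFrame({"barcode": tissue.obs_names, "cluster": labels,
                  "cluster_name": named}).to_csv(outdir / "clusters.csv", index=False)
    sizes = pd.Series(labels).value_counts().sort_index()
    summary["n_clusters"] = int(sizes.size)
    summary["cluster_sizes"] = {str(k): int(v) for k, v in sizes.items()}
    summary["cluster_names"] = {str(k): v for k, v in cluster_names.items()}

    mk = cfg["markers"]
    markers = preprocess.rank_markers(normed.X, normed.var_names, labels, **mk)
    markers.to_csv(outdir / "cluster_markers.tsv", sep="\t", index=False)
    summary["n_marker_rows"] = int(len(markers))
    top_by_cluster = {}
    for cl, tab in markers.groupby("cluster"):
        top_by_cluster[str(cl)] = tab.nsmallest(5, "p_adjusted")["gene"].tolist()
    summary["top_markers"] = top_by_cluster

    if cfg["deconv"]["enabled"] and reference is not None:
        dc = cfg["deconv"]
        reference = preprocess.drop_mito_genes(reference)
        deconvolver = deconv_mod.SeededNMFDeconvolver(
            n_hvg=dc["n_hvg"], n_per_type=dc["n_per_type"],
            min_contribution=dc["min_contribution"], random_state=cfg["seed"]).fit(reference)
        proportions = deconvolver.predict(tissue)
        proportions.to_csv(outdir / "proportions.tsv", sep="\t")
        cluster_means, overall, ratio = deconv_mod.enrichment_by_cluster(proportions, named)
        cluster_means.to_csv(outdir / "enrichment_by_cluster.tsv", sep="\t")
        summary["deconv_overall_pct"] = {
            t: round(100.0 * float(v), 4) for t, v in overall.items()}
        summary["deconv_max_enrichment"] = {
            t: round(float(ratio[t].max()), 4) for t in ratio.columns}

    summary["categories"] = {}
    for ruleset in cfg["rulesets_resolved"]:
        try:
            cats = histoclass.classify_spots(tissue.layers.get("counts", tissue.X),
                                             tissue.var_names, named, ruleset)
        except ConfigurationError as exc:
            summary["categories"][ruleset.name] = {"skipped": str(exc)}
            continue
        cats.index = tissue.obs_names
        cats.rename("category").to_csv(outdir / f"categories_{ruleset.name}.csv")
        entry = {lab: int((cats == lab).sum())
                 for lab in ("affected", "unaffected", "excluded")}
        try:
            table = histoclass.dge_categories(normed.X, normed.var_names,
                                              cats.to_numpy(), **mk_dge(cfg))
            table.to_csv(outdir / f"dge_{ruleset.name}.tsv", sep="\t", index=False)
            entry["top_genes"] = table.head(5)["gene"].tolist()
        except ConfigurationError as exc:
            entry["dge_skipped"] = str(exc)
        summary["categories"][ruleset.name] = entry

    if cfg["velocity"]["enabled"]:
        if "spliced" not in tissue.layers or "unspliced" not in tissue.layers:
            raise ConfigurationError(
                "velocity stage requested but the dataset has no spliced/unspliced layers")
        vl = cfg["velocity"]
        vel = velocity_mod.SteadyStateVelocity(
            n_hvg=vl["n_hvg"], n_pcs=vl["n_pcs"], n_neighbors=vl["n_neighbors"],
            quantile=vl["quantile"], kernel_scale=vl["kernel_scale"]).fit(tissue)
        fractions = velocity_mod.splice_proportions(tissue, named)
        fractions.to_csv(outdir / "splice_proportions.tsv", sep="\t")
        C, included = velocity_mod.contributions(vel.velocity_)
        focal = "inflamed and/or calcified fibers"
        target = focal if focal in named else pd.Series(named).mode().iloc[0]
        contrib = velocity_mod.top_contributors(C, vel.genes_, named, target,
                                                k=vl["top_k"], included=included)
        contrib.to_csv(outdir / "top_contributors.tsv", sep="\t", index=False)
        pixels = tissue.obs[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy()
        arrows = vel.spatial_arrows(pixels)
        pd.DataFrame(arrows, index=tissue.obs_names,
                     columns=["dx", "dy"]).to_csv(outdir / "spatial_arrows.tsv", sep="\t")
        velocity_mod.plot_arrows(pixels, arrows, outdir / "spatial_arrows.png")
        summary["velocity"] = {
            "n_fitted_genes": int(len(vel.genes_)),
            "global_unspliced_fraction": round(
                float(fractions.loc["global", "fraction_unspliced"]), 6),
            "mean_magnitude": round(float(vel.magnitude_.mean()), 6),
            "analyzed_cluster": str(target),
            "top_contributors": contrib.head(10)["gene"].tolist(),
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("run complete; summary written to %s", outdir / "summary.json")
    return summary


def mk_dge(cfg: dict) -> dict:
    mk = cfg["markers"]
    return {"min_pct": mk["min_pct"], "logfc_min": mk["logfc_min"],
            "min_cells_feature": mk["min_cells_feature"]}
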