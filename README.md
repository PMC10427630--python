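# myospatial

Spatial-transcriptomics analysis of dystrophic skeletal muscle sections.

Visium slides capture a 55 µm-resolution picture of gene expression across a
muscle cross-section, but each spot mixes several cells, and connecting the
transcriptome to the histopathology (regeneration, fibrosis, calcification)
takes several coordinated analyses. `myospatial` packages that workflow for
muscle biologists and computational groups working with mouse models of
Duchenne muscular dystrophy (mdx, D2-mdx) or similar degenerative phenotypes:

1. **Spot QC and clustering** — mitochondrial-gene removal, inclusive
   nCount/nFeature filters (the four per-sample presets `C57BL10`, `DBA2J`,
   `mdx`, `D2mdx` ship built in), median-ratio log normalization, 30-PC
   embedding, a 20-neighbor graph and Leiden clustering, and one-vs-rest
   Wilcoxon rank-sum markers (min.pct 0.1, log₂FC > 0.25, Bonferroni).
2. **Seeded-NMF spot deconvolution** — one non-negative topic per cell type
   learned from a labelled snRNA-seq reference (70 nuclei per type, 3000
   HVGs), with the factorization seeded by marker genes and nucleus labels;
   spots are decomposed by two-stage non-negative least squares
   (spot → topics on `W`, topics → cell types on the per-type median topic
   signatures) into proportion vectors, summarized per cluster as enrichment
   ratios.
3. **Rule-based histopathology classification** — spots become
   `affected` / `unaffected` / `excluded` under integer-count rules scoped to
   annotated clusters (e.g. fibrosis: *Cd34* detected, or connective-tissue
   spots with *Lox* > 3 and *Col1a1* > 3), followed by one-sided Wilcoxon
   differential expression between the categories.
4. **Steady-state RNA velocity** — treating each spot as a single cell, the
   per-gene splicing ratio γ is the zero-intercept slope of unspliced on
   spliced counts over the extreme s-quantiles (after kNN pooling on a
   30-neighbor, 30-PC graph); velocity is **v** = u − γ·s, a spot's gene
   contribution is the squared entry of **v**/‖**v**‖₂, top-5 contributors
   are counted per cluster, and velocities are projected onto the tissue as
   arrows via cosine-weighted neighbor displacements.

A first-class synthetic-data generator (`myospatial.simdata`) emulates a
muscle capture area — region-structured Dirichlet cell-type mixtures,
negative-binomial counts, marker-gene signatures, and spliced/unspliced
layers with a transitioning region whose driver genes run off steady
state — so the entire pipeline is verifiable against known ground truth
without downloading anything.

## Worked example

Run the full pipeline on the default synthetic section (≈1,200 spots,
1,500 genes, 8 cell types):

```bash
myospatial run --seed 1 --outdir runs/demo
```

or in Python:

```python
from myospatial import pipeline
summary = pipeline.run({"seed": 1}, "runs/demo")
```

The run writes cluster assignments, marker tables, spot proportions,
category labels, DGE tables, velocity arrows and a `summary.json` that ends
with (abridged):

```json
{
  "n_spots_after_qc": 1184,
  "n_clusters": 6,
  "cluster_names": {"1": "inflamed and/or calcified fibers", "5": "connective tissue", "...": "muscle fibers"},
  "deconv_max_enrichment": {"MPH": 3.52, "NMJ": 9.75, "TC": 6.85, "...": "..."},
  "categories": {
    "fibrosis":      {"affected": 999, "unaffected": 56,  "top_genes": ["Cd34", "Lox", "..."]},
    "calcification": {"affected": 255, "unaffected": 161, "top_genes": ["Mgp", "Mpeg1", "..."]}
  },
  "velocity": {
    "global_unspliced_fraction": 0.2026,
    "analyzed_cluster": "inflamed and/or calcified fibers",
    "top_contributors": ["Tgfbi", "Tnfrsf1a", "Lyz2", "Cd68", "Fn1", "..."]
  }
}
```

Reading the numbers: macrophages (MPH) are 3.5× enriched in the
inflamed/calcified cluster relative to their section-wide average — the
deconvolution has localized the planted infiltrate; the calcification rule
set selects 255 affected spots whose top differential gene is *Mgp*, the
calcification marker the rule keys on, followed by independent macrophage
genes; and the velocity stage reports ~20% unspliced counts with top
contributing genes that are exactly the induced drivers planted in the
transitioning ring.

Other entry points: `myospatial simulate` writes the synthetic dataset in
Space Ranger-style on-disk formats (MTX trio + tissue positions CSV) with
ground-truth TSVs; `preprocess`, `deconv`, `classify` and `velocity`
subcommands run single stages on such a directory; `validate` checks and
prints a resolved run configuration.

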