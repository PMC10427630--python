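# Methods

This note documents the models and procedures implemented in `myospatial`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Preprocessing

Counts are spot × gene UMI matrices. The 13 protein-coding mitochondrial
genes (*mt-Nd1* … *mt-Cytb*) are removed before anything else; per-spot QC
statistics (nCount = total UMIs, nFeature = detected genes) are recomputed
afterwards. QC filtering keeps spots inside inclusive bounds; the four
shipped presets are the per-sample values used for the published mouse
sections:

| preset  | nCount        | nFeature   |
|---------|---------------|------------|
| C57BL10 | 150 – 40,000  | 150 – 5000 |
| DBA2J   | 100 – 20,000  | 200 – 4000 |
| mdx     | 200 – 40,000  | 250 – 5000 |
| D2mdx   | 100 – 20,000  | 150 – 5000 |

**Normalization.** Spots are scaled to the median section depth and
log-transformed: `value = log1p(count · median(nCount) / nCount_spot)`.
This median-ratio log normalization deliberately replaces SCTransform's
regularized negative-binomial regression: the downstream contracts
(Wilcoxon ranks, NNLS on a shared topic space) depend only on a monotone,
depth-corrected transform, and a 5-line normalization is auditable where a
re-implementation of SCTransform would not be. This is the package's one
intentional substitution of a named upstream method and the main caveat
when comparing against Seurat-processed data.

**HVG selection** ranks genes by dispersion (variance/mean of normalized
values) z-scored within 20 gene-mean bins; bins with degenerate spread fall
back to the global dispersion scale so an isolated high-dispersion gene
still ranks. Ties break by gene order. **PCA** centers and unit-scales each
gene (constant genes get scale 1); if the matrix rank is below the
requested 30 components, the available components are returned with a
warning. The **kNN graph** uses exact pairwise Euclidean distances with
stable argsort, so distance ties resolve by spot index and the graph is
fully deterministic; it is symmetrized by union. **Leiden** runs
RB-configuration modularity at the configured resolution with a fixed seed
(default 0) and two iterations; labels are relabelled by decreasing cluster
size. Resolution is a per-sample choice (the published sections used 0.4
or 0.8); the synthetic default runs at 1.0, which resolves the four planted
regions at the fixture's contrast.

**Marker detection** is one-vs-rest per cluster. A gene is tested when
expressed in ≥ 10% of either group, detected in ≥ 5 spots of either group,
and its log₂ fold change — `log2((mean expm1(in)+1e-9)/(mean
expm1(out)+1e-9))`, the expm1 back-transform with a small pseudocount —
exceeds 0.25; only positive markers are reported. The test is the Wilcoxon
rank-sum normal approximation with tie and continuity correction
(two-sided for cluster markers, one-sided *greater* for the
affected-vs-unaffected comparisons below, where upregulation is the stated
question). Bonferroni multiplies by the number of genes tested in that
comparison, capped at 1. Clusters with fewer than 3 spots are skipped.

The normal approximation is accurate to within ~10% of exhaustive
permutation enumeration for tie-free values with exact p ≳ 0.05; with heavy
integer ties at group sizes ≤ 8 it can deviate by 50% or more. The oracle
tests therefore exercise the approximation on continuous normalized values
in its validity regime; p-values for tiny, tie-heavy groups should be read
as approximate.

## Seeded-NMF deconvolution

The reference is subsampled to 70 nuclei per cell type (types with fewer
keep all, with a warning). On the union of 3000 HVGs and the reference
marker genes, the normalized reference (genes × nuclei) is factorized at
rank = number of cell types with multiplicative Frobenius NMF
(tolerance 1e-5, ≤ 500 iterations) from a seeded start: `W[g,t] = 1` for
markers `g` of type `t`, `H[t,c] = 1` for nuclei `c` of type `t`, ε = 1e-3
elsewhere. Topic signatures are the per-type median of `H` columns,
L1-normalized. Spots are normalized identically, restricted to the model
genes, and solved in two NNLS stages: spot profile → topic coefficients on
`W`, then topic coefficients → cell-type weights on the signature matrix.
Weights below 1% of their sum (`min_contribution`, configurable — no
published value exists) are zeroed and the rest renormalized to a simplex;
all-zero spots are flagged rather than dropped. A fitted model whose topic
signatures are mutually indistinguishable (pairwise cosine > 0.999) is
flagged unidentifiable; a reference without detectable markers for some
type refuses to fit. One topic per type is the simplest identifiable
seeding and matches the cited method's design; the inner factorization is
delegated to scikit-learn's multiplicative-update solver, which implements
exactly this update rule.

Cluster enrichment is the mean proportion per annotated cluster divided by
the section-wide mean; the size-weighted average of cluster means equals
the overall mean as an algebraic identity, which the tests assert to 1e-12
as a wiring check. Ratios over a zero overall mean are reported as NaN.

## Histopathology rule sets

Rules are boolean expressions over raw integer counts (`gene OP integer`
atoms with `>`, `>=`, `<`, `<=`, `==`, AND/OR, parentheses), each clause
scoped to named clusters. Raw counts are used because the thresholds are
literal integer cut-offs on observed UMIs. The three shipped sets:

* **regeneration** (mdx) — affected: regenerated-fiber clusters with
  (*Myog* > 0 ∧ *Igfbp7* > 0) ∨ (*Myh3* > 0 ∧ *Igfbp7* > 0); unaffected:
  "muscle fibers without CN" with all three markers absent.
* **fibrosis** (D2-mdx) — affected: *Cd34* > 0 in the three eligible
  clusters (the "solely *Cd34*" and "*Cd34* and *Lox*" branches are jointly
  equivalent to *Cd34* detected), plus connective-tissue spots with
  *Lox* > 3 ∧ *Col1a1* > 3; unaffected: muscle-fiber spots with *Cd34* = 0,
  *Lox* = 0, *Col1a1* < 2 (the "< 2" is read literally: counts ≤ 1).
* **calcification** (D2-mdx) — affected: inflamed/calcified-fiber spots
  with *Mgp* > 0; unaffected: muscle-fiber spots with *Mgp* = 0.

"Excluded" is an explicit third label so spot selection stays auditable.
Within each cluster scope the affected and unaffected predicates are
mutually exclusive by construction. Category DGE runs the one-sided
Wilcoxon described above and sorts by fold change. A two-sided mode is
available behind the `alternative` flag since reasonable readers can take
either convention for the published values.

## Steady-state RNA velocity

Each spot is treated as a single cell. The 2000 HVGs of the normalized
spliced layer are embedded in 30 PCs; a 30-neighbor graph smooths both raw
layers (mean over the neighborhood including self). Per gene, γ is the
zero-intercept least-squares slope of smoothed u on smoothed s restricted
to the union of the top and bottom 5% of s (the near-steady-state extremes);
genes with all-zero s or fewer than 10 usable extreme spots are dropped.
Velocity is `v = u − γ·s` on the smoothed values, magnitude its row L2
norm. This steady-state estimator replaces the dynamical EM model of the
scvelo lineage: every downstream statistic here (unit-vector contributions,
top-5 counting, spatial projection) is agnostic to how γ was estimated, and
the steady-state model is transparent and fast; γ estimates for genes far
from steady state (the induced drivers) are deliberately reported as-is.
γ accuracy degrades for weakly expressed genes — at the fixture's depth the
median relative error is ~11% overall, ~3% for well-detected genes.

Contributions: `c[spot,g] = (v[g]/‖v‖₂)²`, summing to 1 per spot;
zero-velocity spots are excluded and logged. Top-contributor summaries
count, per gene, the cluster spots whose top-5 contributions (ties by gene
order) include it, reported as absolute count and percentage of the
cluster's analyzed spots — "percentage of positive spots" is read as
percentage of analyzed cluster spots in which the gene makes the top-5
list; counting spots with positive velocity instead is available by
filtering on the velocity sign.

Spatial projection: for spot i and graph neighbor j, the expression
displacement δᵢⱼ (smoothed spliced space, unit-normalized) is scored by
cosine against vᵢ; weights are a softmax with scale 0.1 (no published
value; smaller sharpens toward the best-aligned neighbor), and the arrow is
the weighted mean of unit pixel-space directions to the neighbors minus
their unweighted mean, so an uninformative velocity cancels to a zero
arrow.

## The synthetic section

The generator is the package's test bed and defines its study conditions.
Default fixture: a 40 × 40 grid with a circular tissue mask (~1,184
in-tissue spots), 1,500 genes, 8 cell types (IIx, IIb, MPH, FAP, TC, MTJ,
NMJ, RegMyon) with 15 markers each at fold 20, and four regions — healthy
muscle, a connective-tissue band, an inflamed/calcified focus
(macrophage/FAP-dominated), and a transitioning ring around the focus whose
mixture grades radially from 60% to 25% focal character. Region mixtures
give every cell type a distinct spatial pattern, the way real sections
localize NMJ nuclei, tenocytes or macrophage infiltrates; per-spot
proportions are Dirichlet around the region mean (concentration 20;
∞ yields the mean exactly). Counts are negative-binomial: spot depth
NB(mean 3000, size 15) — within the real sections' median-UMI range — and
per-gene counts NB(size 2) around depth × mixed signature. Each cell
type's marker block is given the same summed baseline expression so the
realized cross-type enrichment equals the configured fold rather than
drifting with the draw.

Spliced/unspliced layers partition each count binomially, so the layers sum
exactly to the original matrix and QC sees the same counts. The split
probability per gene is `q = γ/(1+γ)`, which realizes `E[u] = γ·s`. The
configured `gamma_range` (0.2–0.6) sets per-gene heterogeneity only: the
probabilities are rescaled by one global factor so the expression-weighted
unspliced fraction equals `baseline_unspliced_fraction` (default 0.20,
inside the 17–23% band observed in real muscle Visium data), and the
post-calibration ratio is stored as the ground-truth γ. Without this
calibration the two constraints are inconsistent (uniform γ in 0.2–0.6
implies ~28% unspliced). Twelve driver genes — the most-expressed markers
of the focal cell types — run off steady state in the ring with
`E[u] = γ·s·(1+β)`, β = 4: a burst strong enough that the planted
transition is detectable at Visium-like depth after neighborhood smoothing,
which dilutes the induced signal roughly five-fold because a ring spot's
expression neighbors are mostly steady-state spots.

What passing on this fixture does **not** show: robustness to platform
effects between reference and spots (the generator draws both from the same
signatures), hexagonal Visium geometry (the grid is rectangular), spatial
autocorrelation of noise, SCTransform-normalized inputs, or the published
per-gene fold changes and p-values — those are statistics of one real
dataset and depend on its exact clustering, and are explicitly not
reproduction targets.

## Determinism and problem sizes

All randomness flows from explicit integer seeds (NumPy `SeedSequence`
children per generation stage; fixed seeds for Leiden and NMF), and full
pipeline reruns with the same configuration produce byte-identical summary
JSON. The shipped test suite and the acceptance script run the default
fixture (~1,200 spots × 1,500 genes, plus marker folds 2 and 5 for the
recovery curve), a scale chosen so known-truth recovery is measurable while
the whole suite completes in about half a minute on one CPU.

## Known limitations

* Median-ratio log normalization is not SCTransform; marker lists on real
  data will differ in the tail.
* The steady-state γ estimator is biased for genes far from steady state
  and noisy for weakly expressed genes; the dynamical model is out of scope.
* Rule classification requires the annotated cluster names to match the
  rule set's vocabulary exactly; the pipeline maps synthetic clusters to
  names by region enrichment, but real sections need a manual cluster-name
  map in the configuration.
* Single-section runs only; cross-sample integration and batch correction
  are out of scope.
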