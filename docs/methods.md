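# Methods

## Mixing model and solver

A bulk profile is modelled as a linear mixture of cell-type reference
profiles on the linear (TPM/FPKM) scale: `m = S w` with `w ≥ 0` summing to
one. Linearity holds for linear-scale expression but not for
log-transformed values, so `deconvolve` back-transforms LOG2 input
(`2^x − 1`) before solving; the log2(x+1) transform that
`normalize_expression` applies is treated purely as a display and
diversity preprocessing step.

Before solving, both the signature and the mixture are scaled per gene:
each signature row and the matching mixture entry are divided by the
row's root-mean-square across cell types. This equalizes the leverage of
high- and low-expressed signature genes in the residual. We deliberately
scale rather than z-score: subtracting the per-gene mean makes the
signature's columns sum to the zero vector (every row centered), which
destroys identifiability of the weights and breaks exact recovery of
noise-free mixtures. With scaling only, the mixing identity `m' = S' w` is
preserved exactly, so the solver recovers noise-free weights to machine
precision, and scaling a mixture column by a positive constant changes the
solution only up to the final sum-to-one renormalization.

The default solver is NNLS (`scipy.optimize.nnls`): deterministic, convex
and exactly testable. An optional linear `nu`-SVR solver is provided for
comparison with support-vector deconvolution tools. Because SVR fits an
unconstrained intercept, on sparse block-structured signatures the
intercept can absorb the weight mass of low-abundance types; we therefore
fold the fitted intercept back into weight space via its least-squares
preimage under the design (`argmin_δ ||A δ − c·1||`) before clipping
negative coefficients and renormalizing. `nu` is selected from
{0.25, 0.5, 0.75} by residual norm, per sample.

An all-zero solution vector raises an error rather than falling back to a
uniform composition: silently emitting 1/21 everywhere would fabricate
biology.

## Signature construction

Cell types whose replicate reference profiles have mean pairwise Pearson
correlation (computed on log2(x+1) values) below `consistency_threshold`
(default 0.5) are excluded and reported. For each surviving type, markers
are ranked by the fold change of that type's mean linear expression over
the highest other-type mean (with a 1e-9 guard for zero denominators).
The builder sweeps the per-type marker count G over `[g_min, g_max]`,
forms the union of top-G marker lists, and keeps the G minimizing the
2-norm condition number of the per-type-mean candidate matrix; ties break
toward smaller G (fewer genes, same conditioning). A condition number
above 1e6 triggers a near-singularity warning. The procedure is fully
deterministic: identical inputs give identical signatures.

## Diversity

* **Alpha**: Gini–Simpson `1 − Σ p²` by default (the probability that two
  randomly drawn cells differ in type); the inverse form `1/Σ p²` is
  available behind a flag. Input rows must be on the simplex within 1e-6.
* **Beta**: Bray–Curtis by default — the standard companion to NMDS in
  ecology toolkits; Euclidean and Jensen–Shannon are options.
* **NMDS**: Kruskal stress-1
  `sqrt(Σ (d − d̂)² / Σ d²)` minimized by alternating (a) isotonic
  regression (scikit-learn, weak/primary tie treatment: tied input
  dissimilarities collapse to a common fitted value) of the embedded
  Euclidean distances against the input dissimilarity order and (b) a
  Guttman-transform coordinate update toward the fitted disparities.
  Restarts (default 20) start from seeded Gaussian configurations; a
  restart terminates when the stress improvement falls below 1e-7 or the
  update would increase stress (the previous configuration is kept, so
  the recorded stress history is non-increasing by construction). The
  best restart wins; coordinates are centered at the origin. The
  embedding is unique only up to rotation/reflection, so tests compare
  stress values, not coordinates. Defaults: `n_restarts=20`,
  `max_iter=300`, k ∈ {2, 3}.

The NMDS optimizer is implemented in-package (rather than delegating to
`sklearn.manifold.MDS`) because the per-iteration stress trace is part of
the module's contract; sklearn's non-metric SMACOF serves as an
independent cross-check in the test suite.

## Pseudo-bulk validation protocol

1. **QC**: a cell is kept iff its expressed-gene count (genes with value
   > 0) lies in `[min_genes, max_genes]`, its UMI total is at most
   `max_umis`, its mitochondrial fraction (genes with the `MT-` symbol
   prefix over the cell total) is at most `max_mito_frac`, and — when a
   housekeeping list is configured — its mean log2(x+1) housekeeping
   expression reaches the threshold. A cell is counted under *every* rule
   it violates, so rule counts can exceed the number of removed cells.
   The filter is idempotent.
2. **Gating**: annotated T cells split by marker expression — CD4 above
   threshold with CD8A and CD8B at or below it gives CD4_T; CD8A and CD8B
   above with CD4 at or below gives CD8_T; everything else becomes
   `unassigned` and is excluded from the ground truth. The rules are
   stated as positive assignments only, so double-positive or
   double-negative cells are not forced into a class. The default
   threshold is 0 ("any expression"), configurable in data units.
3. **Ground truth**: per patient, the proportion of each immune panel
   type among that patient's immune-type cells. Patients with immune
   fraction below `min_immune_frac` or fewer than `min_immune_cells`
   immune cells are excluded and listed (defaults 0.0 and 50; the NSCLC
   profile sets the fraction cutoff to 0.20).
4. **Pseudo-bulk**: the arithmetic mean over all of a patient's QC-passed
   cells — all cell types, not only the immune panel, because a real bulk
   sample contains the tumor and stromal compartments too.
5. **Rescale**: truth and prediction restricted to their shared cell
   types, each row renormalized to sum 1 (both tables describe relative
   proportions over different panels; comparison is only meaningful on
   the common support).
6. **Score**: Pearson r and RMSE pooled over all (patient, type) pairs
   plus per-type across patients. Correlations against a constant vector
   are reported as undefined (NaN with a flag), never coerced to 0.

Dataset profiles: melanoma (`min_genes=1700`), HNSCC (`min_genes=2000`),
both with CD4/CD8 gating and Smart-seq2-style deep cells; NSCLC
(`min_genes=200`, `max_genes=5000`, `max_umis=30000`,
`max_mito_frac=0.30`, `min_immune_frac=0.20`) with the panel {T cell, B,
Mast, Neutrophil} and no T-subset gating. The HNSCC immune panel is {B,
CD4_T, CD8_T, Macrophage, Dendritic, Mast}. Per-dataset housekeeping
criteria are configurable rather than hard-coded, since the original
cohort-specific gene lists are inherited from the source studies.

## Synthetic cohorts

The generator emulates the structure of annotated tumor scRNA-seq cohorts:
patients × cells × genes with cell-type labels, TPM-like values (each
cell rescaled to a fixed total of 1e4), `MT-`-prefixed mitochondrial
genes, housekeeping genes and per-cell UMI totals derived from
pre-rescaling expression sums.

* Each of the default 21 panel types has a block of 10 dedicated marker
  genes (high in the owning type, zero elsewhere; blocks disjoint by
  default, with an overlap knob for stress testing) over a shared
  log-normal background. CD4_T and CD8_T carry CD4 and CD8A/CD8B as their
  leading markers and zero expression of the opposite subset's markers,
  so gating can recover subtype identity; in cohorts the two subtypes are
  emitted under the combined label "T cell" (configurable).
* Per-patient compositions are Dirichlet(α) draws (α=1 by default — a
  flat prior over the simplex); cell types are sampled per cell from the
  patient's composition.
* Expression noise is multiplicative log-normal (σ=0.2 by default),
  standard for positive TPM-like data; dropout is Bernoulli (rate 0.3 by
  default) independent of expression level — a simplification relative to
  real scRNA-seq, where dropout is expression-dependent.
* Default cohort size is 10 patients × 500 cells, matching the scale at
  which the end-to-end recovery checks are run.

What the generator does *not* model: negative-binomial count dispersion,
gene–gene correlation beyond cell-type structure, batch effects, ambient
RNA and doublets. Passing the end-to-end checks therefore demonstrates
that the pipeline's stages compose correctly and that the estimator
recovers truth under its own mixing model with realistic noise and
dropout — not that accuracy transfers unchanged to any particular real
cohort, where reference/mixture mismatch dominates error.

## Numerical choices and degenerate inputs

* Composition rows are validated to the simplex within 1e-9; alpha
  diversity accepts rows within 1e-6.
* Duplicate gene symbols collapse by mean at read time (configurable:
  max/error); symbols are uppercased at ingest so case differences cannot
  silently drop overlap.
* Distance ties in hierarchical clustering resolve by lexicographic
  sample order (samples are sorted before linkage, so scipy's index-order
  tie-break realizes it).
* `qc_filter` refuses to return an empty dataset; `deconvolve` refuses
  all-zero samples and sub-threshold gene overlap (default
  `min_overlap_frac=0.5`); NMDS refuses all-zero distance matrices and
  cohorts smaller than k+1.
* Single-patient cohorts abort validation with a clear error because a
  correlation over one point is undefined.

## Known limitations

* The signature builder assumes replicate reference profiles per type;
  with a single replicate, consistency cannot be checked (a warning is
  emitted and the type is kept).
* The SVR solver is heuristic compared to NNLS and is intended for
  method comparison, not as the default estimator.
* Absolute (per-volume) abundances are out of scope; all outputs are
  relative proportions.
* Batch correction between mixture and signature platforms is not
  performed; mixtures and signatures are assumed comparable after
  per-gene scaling.
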