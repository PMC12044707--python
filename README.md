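# immunosort

Immune-cell deconvolution of bulk transcriptomes, with composition
diversity analytics and a single-cell pseudo-bulk benchmarking protocol.

## Who this is for

Tumor tissue is a mixture of malignant, stromal and immune cells, and the
immune fraction — how much of it there is and which cell types dominate —
correlates with immunotherapy response. Bulk RNA-seq of a biopsy measures
the average transcriptome of that mixture. `immunosort` estimates, for
each bulk sample, the **relative proportions of a 21-type immune-cell
panel** from its expression profile, and provides the downstream analytics
a study needs: hierarchical clustering of samples by composition,
within-sample (alpha) and between-sample (beta) diversity, and NMDS
ordination. A validation module reproduces the standard benchmark for such
tools: building pseudo-bulk profiles from annotated single-cell RNA-seq
cohorts and scoring predictions against the counting-based ground truth.

## The model

A bulk expression profile **m** (genes, linear TPM/FPKM scale) is modelled
as a non-negative combination of cell-type reference columns:

```
m ≈ S w,   w ≥ 0,   Σ_j w_j = 1
```

where **S** is the *signature matrix* (signature genes × cell types). The
default solver is non-negative least squares (NNLS) over the genes shared
between mixture and signature, after per-gene scaling (each gene's
signature row and mixture entry divided by the row's root-mean-square),
followed by renormalization of **w** onto the probability simplex. A
`nu`-SVR solver is available behind the same interface.

The signature builder filters out cell types whose replicate reference
profiles are inconsistent (mean pairwise Pearson on log2(x+1) values below
a threshold), ranks candidate markers per type by fold change over the
highest other-type mean, and picks the per-type marker count G in
`[g_min, g_max]` that minimizes the 2-norm condition number of the
signature — the smaller the condition number, the more identifiable the
mixture weights.

Diversity analytics operate on the estimated compositions: Gini–Simpson
index `1 − Σ p_i²` per sample, Bray–Curtis dissimilarity
`1 − Σ min(u_i, v_i)` between samples, and non-metric multidimensional
scaling minimizing Kruskal stress-1 via alternating isotonic regression
and SMACOF updates.

The pseudo-bulk validation protocol chains: cell-level QC (expressed-gene
bounds, UMI cap, mitochondrial fraction, housekeeping expression) →
CD4/CD8A/CD8B marker gating of annotated T cells → per-patient ground
truth by label counting → per-patient averaging into pseudo-bulk →
deconvolution → restriction of truth and prediction to their shared cell
types with rows rescaled to sum 1 → Pearson r and RMSE, pooled and per
cell type. Presets ship for melanoma-, HNSCC- and NSCLC-style cohorts
(e.g. the NSCLC profile removes cells with <200 or >5000 expressed genes,
>30,000 UMIs or >30% mitochondrial content, and keeps patients with >20%
immune-cell content).

## Worked example

Every stage is runnable without external data via the synthetic cohort
generator (`examples/` has one narrative script per capability):

```
$ python examples/pseudobulk_benchmark.py
QC kept 5000/5000 cells
patients scored: 10 (excluded: none)
pooled Pearson r = 0.9891, pooled RMSE = 0.0070 over 210 (patient, cell type) points
five per-type correlations across patients:
  B_naive                  r=0.999 rmse=0.0050
  B_memory                 r=0.999 rmse=0.0041
  Plasma                   r=1.000 rmse=0.0021
  CD4_T                    r=0.995 rmse=0.0182
  CD8_T                    r=0.978 rmse=0.0201
```

Ten patients with 500 cells each are simulated at log-normal expression
noise σ=0.2 and 30% dropout; the pipeline recovers each patient's true
immune composition from the averaged pseudo-bulk with pooled r ≈ 0.99 —
near-perfect agreement between predicted and true proportions.

The same stages are exposed as a CLI:

```
immunosort simulate --preset smoke --seed 42 --out-dir sim/
immunosort build-signature --reference sim/reference.csv --labels sim/labels.tsv --out sig.csv
immunosort deconvolve --mixture sim/mixtures.csv --signature sim/signature.csv --out comp.csv
immunosort diversity --composition comp.csv --k 2 --seed 42 --out-dir plots/
immunosort pseudobulk --cells sim/cells.csv --annot sim/annot.tsv \
    --signature sim/signature.csv --preset smoke --out-dir run/
```

Bulk matrices are CSV/TSV with gene symbols as rows and sample names as
columns; single-cell input is dense CSV/TSV or a MatrixMarket triplet plus
a cell annotation table. Every run writes a `manifest.json` with the
resolved parameters, seed and input checksums.

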