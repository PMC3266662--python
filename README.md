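# sppr-omics

Correlating gene expression and proteome fold changes with the **specific
extracellular protein production rate (SPPR)** of chemostat cultivations of
a protein-secreting filamentous fungus (the *Trichoderma reesei* low-growth
protein-production setting: triplicate chemostats at D = 0.03 h⁻¹ low
density, D = 0.06 h⁻¹ low density, and D = 0.03 h⁻¹ high density).

The package is aimed at computational biologists who want the full analysis
chain as tested, scriptable components rather than a one-off notebook:

* **Physiology** — steady-state chemostat balances:
  SPPR = 1000·D·P/X (mg·g⁻¹·h⁻¹), q_s = D·(S_feed − S_res)/X,
  Y_xs = X/(S_feed − S_res), Y_ps = P/(S_feed − S_res); pooled-variance
  Student's t contrasts between conditions.
* **Correlation analysis** — per-gene Pearson correlation r of log2
  expression with SPPR, exact t-transform p-values, Storey q-value FDR
  (π₀ from a cubic-spline smoother over a λ grid,
  q₍ᵢ₎ = min_{j≥i} π₀·m·p₍ⱼ₎/j), significance selection at |r| > 0.8,
  sample-exclusion sensitivity, and moderated differential expression
  (empirical-Bayes variance shrinkage s̃² = (d₀s₀² + d_g s_g²)/(d₀+d_g)
  with (d₀, s₀²) by method of moments on log variances; numerically
  identical to limma's two-group moderated t on the same design).
* **Genome structure** — adjacent co-correlated gene pairs (|r| > 0.7, same
  sign), a position-shuffling permutation null for the number of genes in
  such pairs, chromosomal cluster detection (seed triplet of three
  consecutive qualifying genes, extension until the sign of r changes),
  divergent-promoter sharing, and linear-model comparisons of gene
  characteristics (max expression, fold change, GC%, distance to scaffold
  end, length).
* **Cluster conservation** — sliding windows of 16 (step 2) or 30 (step 5)
  genes across other genomes, InterPro domain-content overlap, orthology
  (protein-cluster) verification.
* **Metabolic network** — bidirectional-best-hit model transfer (bit score
  > 50 in either direction), reporter metabolites
  (Z_raw = Σᵢ Φ⁻¹(1−pᵢ)/√k, background-corrected per neighborhood size k),
  and enriched-path detection on the gene projection graph with the
  color-coding dynamic program and a weight-shuffling empirical null.
* **Proteome integration** — quadrant classification of transcript/protein
  log2 fold-change pairs (Q1–Q4, T0, T-0 at cut-offs 0.6/0.3) and the
  translational control efficiency ratio TCEr = 2^(ΔP − ΔT) with >3 / <1/3
  flags.
* **Calibration & enrichment** — AIC selection among nested TRAC-vs-array
  models m0/m1/m2 (m1: Array_ij = α_j + β·TRAC_ij + ε_ij), and
  hypergeometric/Fisher over-representation tests.
* **Synthetic data** — generators for every input with planted, recoverable
  structure (target correlations, clusters, reporter metabolites, a
  high-scoring path, TCEr targets, TRAC model parameters), so the whole
  pipeline runs and is testable without any external download.

## Worked example

Run the bundled synthetic study end to end (six scaffolds × 80 genes,
three planted clusters, 60 planted ±0.9 correlation genes):

```sh
sppr-omics run --seed 1 --out results/demo
```

prints the run summary

```json
{
  "n_genes": 480,
  "n_positive_selected": 42,
  "n_negative_selected": 35,
  "achieved_fdr": 0.037950364295295955,
  "pair_permutation_p": 0.0004997501249375312,
  "n_clusters_positive": 2,
  "n_clusters_negative": 3,
  "yield_contrast_p": 0.7099296755175128,
  "trac_selected_model": "m1",
  "trac_slope": 0.5334816497947145,
  "trac_sigma": 0.2624962530048676,
  ...
}
```

Reading the numbers: of 480 genes, 42 positively and 35 negatively
correlated genes pass |r| > 0.8 (the planted ±0.9 genes and cluster genes
that realized a strong correlation at n = 9), with an achieved FDR of 3.8%
at the cut. The permutation test rejects the hypothesis that adjacent
co-correlated pairs arise by chance placement (p ≈ 5·10⁻⁴), and the
planted chromosomal clusters are detected. The TRAC-vs-array comparison
selects the gene-specific-intercept model m1 and recovers slope ≈ 0.52 and
residual SD ≈ 0.25 — the generating values. Per-stage tables
(correlations, q-values, pairs, clusters, reporter metabolites, enriched
paths, transcript–protein classes with TCEr) and a reproducibility
manifest are written under `results/demo/`.

Every stage is equally usable as a library:

```python
from sppr_omics import synthetic as syn
from sppr_omics.correlation import correlate_to_sppr, add_qvalues

spec = syn.SyntheticSpec(n_scaffolds=2, genes_per_scaffold=50, seed=0)
expr = syn.generate_expression(syn.generate_genome(spec), spec)
records = add_qvalues(correlate_to_sppr(expr, spec.sppr))
```

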