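# Methods

## Study design and physiology

The analysis targets steady-state chemostat cultivations in three
conditions — D03 (D = 0.03 h⁻¹, 10 g/L feed substrate), D06 (0.06 h⁻¹,
10 g/L) and HD (0.03 h⁻¹, 40 g/L, high cell density) — with triplicates,
i.e. nine samples. At steady state the dilution rate D equals the specific
growth rate, which justifies the standard mass balances implemented in
`physiology`:

* SPPR = 1000 · D · P / X (mg protein · g biomass⁻¹ · h⁻¹),
* q_s = D · (S_feed − S_res) / X (g · g⁻¹ · h⁻¹),
* Y_xs = X / (S_feed − S_res), Y_ps = P / (S_feed − S_res) (g/g).

Residual substrate below detection is entered as 0, reflecting fully
substrate-limited cultures. Condition contrasts default to the
pooled-variance Student's t (the test named for such comparisons in this
literature); Welch's form is available via a flag. The SPPR formula is the
standard chemostat balance; a configuration option accepts precomputed
SPPR columns for data sets where the rate was derived differently.

## Per-gene correlation and FDR

Each gene's log2 expression is correlated with the per-sample SPPR by the
Pearson coefficient (the downstream machinery — t-transform p-values,
q-values, linear models — assumes it; Spearman is available by
configuration). Significance uses the exact transform
t = r√(n−2)/√(1−r²) on n−2 degrees of freedom; one-sided variants
(H₁: r > 0 / r < 0) feed the per-tail network analyses. Genes with zero
expression variance have undefined correlation and are excluded rather
than assigned r = 0. SPPR is used on its raw scale (log scale optional);
with only three distinct rate levels the choice is nearly immaterial for
rank-based conclusions.

False discovery rates are Storey q-values: π₀(λ) = #{p > λ}/(m(1−λ)) on
λ ∈ {0.05, …, 0.95}, smoothed with a cubic spline and evaluated at
λ = 0.95, clipped to (0, 1]; then q₍ᵢ₎ = min_{j≥i} π₀·m·p₍ⱼ₎/j. The
achieved FDR of a selection at |r| > r_cut is reported as the largest
q-value among the selected genes.

## Moderated differential expression

Between-condition comparisons use a per-gene two-group linear model with
empirical-Bayes variance moderation. Per-gene residual variances s_g²
(pooled within groups, d_g df) are assumed to follow a scaled
inverse-chi-square prior with parameters (d₀, s₀²) estimated by method of
moments on the log scale: the mean and variance of
log s_g² − ψ(d_g/2) + log(d_g/2) identify s₀² and, through trigamma
inversion, d₀. Moderated variances s̃² = (d₀s₀² + d_g s_g²)/(d₀ + d_g)
give t statistics on d₀ + d_g df; when the observed spread of log
variances is no larger than expected under a single common variance, d₀ is
infinite and the common variance is used with a normal reference. This is
the same moments system the established microarray tooling solves, and the
test suite verifies numerical agreement with limma (coefficients to 1e-9,
p-values to relative 1e-8) on a shared fixture, while keeping the
implementation self-contained. P-values are Benjamini–Hochberg adjusted
per contrast; the significance rule is adjusted p < 0.05 and
|log2 FC| > 0.5.

## Genome structure

Adjacent qualifying pairs are chromosomally consecutive genes (adjacency
never crosses scaffold boundaries) with |r| > 0.7 and equal sign. The
permutation null keeps every gene's position fixed and shuffles the vector
of correlation values over positions genome-wide — scaffold gene counts
are thereby preserved. The statistic is the number of genes belonging to
at least one qualifying pair (optionally per sign); the p-value uses the
add-one (Phipson–Smyth) estimator (1 + #{perm ≥ obs})/(1 + n_perm) so a
permutation p of exactly 0 cannot occur.

Clusters are seeded by three consecutive genes all |r| > 0.7 with the same
sign and extended over flanking genes while the sign of r matches —
extension requires only the sign, not the magnitude (a literal reading of
"until the direction of correlation changes"); magnitude-thresholded
extension is a flag. Genes with r exactly 0 (or undefined) terminate
extension and never seed. Consequently each reported cluster is a maximal
same-sign run containing a seed triplet, so same-sign clusters cannot
overlap.

Promoter sharing: a pair can share a promoter iff it is divergently
transcribed (upstream gene on −, downstream on +); the separation is
measured between the two transcription start positions (for a − strand
gene, its annotated end coordinate), with a 1000-base threshold.

Gene-characteristic contrasts (max expression, max |log2 FC| over the
three contrasts, GC%, distance to scaffold end, length) are compared
between gene sets with an ordinary linear model on a group indicator,
reporting the group coefficient and its two-sided p.

## Cluster conservation

Other genomes are scanned with windows of w consecutive genes (the paired
defaults w = 16/step 2 and w = 30/step 5), pooling each window's InterPro
domain content as a set (duplicates count once). The default match
criterion demands all distinct query-cluster domains in the window — the
strictest reading of domain-content "overlap" — with `min_shared`
configurable downward because biologically confirmed cases can conserve
only a subset of the cluster. Matches are then verified by orthology:
every shared domain must be carried by a window gene whose protein-cluster
(orthology group) also contains a query-cluster gene; missing orthology
mappings leave a match unconfirmed with a logged warning instead of
failing the run.

## Metabolic network analyses

Model transfer uses bidirectional best hits: a source/target gene pair is
mapped iff each is the other's unique best hit (ties are skipped with a
warning) and the bit score exceeds 50 in at least one direction ("either
direction" read literally; a strict both-directions mode is a flag).
Reactions of mapped source genes are copied to the target gene; the
mapping is an injective partial matching.

Reporter metabolites score each metabolite by
Z_raw = Σ_{i∈neighbors} Φ⁻¹(1−p_i)/√k over the k adjacent genes with
p-values, corrected against the mean and SD of the same statistic on
n_background random size-k gene draws (sampled with replacement from all
scored genes), with p = 1 − Φ(Z_corrected); metabolites require p < 0.05
and k > 1. The analysis runs separately per correlation tail using
one-sided p-values, mirroring the search for both positively and
negatively correlated neighborhoods.

Enriched paths are maximum-score simple paths of fixed length
k ∈ [3, 12] in the gene projection graph (genes adjacent iff they share a
metabolite; edge weight the rescaled product of the two genes'
bidirectional-hit scores). The node score is Φ⁻¹(1−p), consistent with
the reporter statistic; edge weights enter the path score with
coefficient λ, default λ = 0 since no mixing rule between node and edge
evidence is established — the weights remain available and λ is
configurable. Search is by color coding: each trial assigns k random
colors and a dynamic program over (end node, used-color set) states finds
the best colorful — hence simple — path; with n_colorings trials the true
optimum is found with probability ≥ 1 − (1 − k!/k^k)^n_colorings.
Significance is an empirical p from shuffling node weights over nodes (and
edge weights over edges, preserving topology) with the add-one estimator,
10,000 shuffles by default; overlapping significant paths (p < 0.025) are
merged by gene-set union into the reported paths. On graphs small enough
to enumerate every simple path, the implementation can switch to exact
enumeration (vectorizing the shuffle null); observed and shuffled data
always use the same search.

A property of this null worth knowing: on very small graphs (≈10 nodes)
the max-path statistic under weight shuffling has large upper atoms — the
few largest weights land on *some* k-path in a sizable fraction of
permutations — so very small p-values are unreachable by construction.
The calibration checks in the test suite therefore use 30-node sparse
graphs, where the empirical p is uniform to Monte-Carlo accuracy.

## Transcript–protein integration

Pairs of protein and transcript log2 fold changes between two conditions
are classified with cut-offs hi = 0.6 (1.5-fold: differentially
expressed) and lo = 0.3 (1.2-fold: not differentially expressed): Q1/Q3
concordant quadrants, Q2/Q4 discordant, T0/T-0 protein changed with flat
transcript. Transcript changes strictly between lo and hi are neither
flat nor changed, so such pairs stay unclassified. Each protein spot
(e.g. pI isoforms of one gene) is classified independently.
TCEr = 2^(ΔP − ΔT) inverts exactly under swapping the comparison
direction; the linear-ratio form is used. Flags mark TCEr > 3 and < 1/3.
Transcript-vs-protein fold-change agreement is summarized with both
Pearson and Spearman coefficients.

## TRAC calibration and enrichment

Paired TRAC/array signals are fit with three nested OLS models — m0
(common intercept and slope), m1 (gene-specific intercepts, common
slope), m2 (gene-specific intercepts and slopes) — ranked by the
Gaussian-likelihood AIC in the form n·ln(RSS/n) + 2·n_params with the
same constant convention across models; ties go to fewer parameters. Gene
intercepts are fixed effects: this keeps the AIC comparison elementary
and exactly reproducible, while a random-intercept variant would estimate
essentially the same slope and residual SD in this balanced design. The
reported σ is the df-corrected root-mean-square residual.

Enrichment is a one-sided over-representation test per category —
hypergeometric survival function, or Fisher's exact test for manually
curated annotations (identical on 2×2 tables; the suite checks agreement
to ≥10 significant digits) — restricted to categories with ≥1 hit, at a
raw p < 0.05 cut-off without multiple-testing correction (a BH flag
exists). "% of expressed" is the share of the query set annotated with
the category; "% of annotated" the share of the category's background
members inside the query set.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses assume:
nine samples in three triplicate conditions with condition-distinct SPPR
values (defaults 3.0/3.2/2.5, 1.5/1.6/1.4, 0.8/0.9/0.85 mg·g⁻¹·h⁻¹ for
D03/D06/HD — magnitudes chosen once to respect the observed ordering,
D03 highest and HD lowest, at rates typical for lactose-limited
*T. reesei* chemostats); Gaussian log2 expression noise (SD 0.25 by
default, matching post-normalization microarray behavior under a Pearson
analysis); planted per-gene target correlations implemented as linear
SPPR responses with slope b = sign(r)·σ·|r|/(sd(SPPR)·√(1−r²)), which
fixes the population correlation at the target (|r| = 1 becomes an exact
noise-free relation); planted adjacent-gene clusters; a bipartite network
with a planted gene path chained through dedicated metabolites and
reporter metabolites wired to planted-correlation genes; protein fold
changes equal to transcript fold changes plus log2 TCEr plus noise; and
TRAC/array pairs drawn exactly from the m1 model. GC% is generated as a
per-gene number per taxonomy class rather than from sequence — the
genome-characteristic statistics only need the numbers. Everything is
deterministic under a fixed seed.

What passing on this synthetic data does **not** show: robustness to
probe-level artifacts, normalization-damped fold changes, heteroscedastic
or heavy-tailed expression noise, correlated errors between conditions,
gel-quantification error structure, or annotation errors — none of these
are emulated. The suite demonstrates correctness of the statistical
machinery under its stated model, not performance on raw instrument data.

## Numerical choices and problem sizes

* Permutation/shuffle p-values always use the add-one estimator.
* π₀ is clipped to [1/m, 1]; q-values to [0, 1]; reporter p-values are
  floored at 1e-15 before the z transform to avoid infinities.
* Background-corrected reporter SDs below 1e-9 (degenerate all-equal
  p-value inputs) fall back to 1, yielding Z_corrected ≈ 0.
* AIC ties are resolved toward fewer parameters after rounding to 1e-9.
* Cluster detection treats NaN correlations as sign 0 (terminators).
* The default pipeline run uses a 480-gene genome, 2000 permutations and
  shuffles, and path lengths 3–6; the test suite scales resampling sizes
  to hundreds and the acceptance script uses 50 replicates of 31×9
  observations — sizes chosen so every planted effect is detected with
  comfortable Monte-Carlo margins while a full run stays in seconds.

## Known limitations

* The m1 intercepts are fixed effects; variance components of a
  random-intercept formulation are not estimated.
* The color-coding search is randomized; its guarantee is probabilistic
  and the shuffle null is exchangeable only under the implemented
  node/edge weight permutation scheme.
* Union-merging of overlapping significant paths can chain distinct
  pathways through shared hub genes; the per-k unmerged paths are always
  reported alongside.
* Enrichment p-values are raw, by design; with many categories the
  expected number of false positives at p < 0.05 scales accordingly.
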