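# Methods

This note documents the models, numerical choices and known limitations of
`colotype`.  It is written for users who want to know exactly what each
stage computes and what the bundled synthetic cohorts do — and do not —
demonstrate about real data.

## Synthetic cohort model

The generator (`colotype.sim`) draws a cohort of `n_samples` tumors from
six molecular subtypes C1..C6 with prevalences (0.21, 0.19, 0.13, 0.10,
0.27, 0.10), the proportions reported for a 443-sample colon-cancer
discovery cohort.  Defaults: `n_samples=300`, `n_genes=2000`,
`effect_size=1.5` (log2 units), `noise_sd=1.0`.

**Expression.**  Each gene has a baseline level drawn once from
N(7, 1) on the log2 scale (typical microarray intensities).  Each subtype
owns a disjoint, contiguous block of 180 marker genes — 90 shifted up and
90 down by `effect_size` in that subtype only — so planted structure is
auditable by eye in a heatmap.  With six subtypes this yields 1,080
discriminant genes among the 2,000, matching the proportions of the
motivating study (~1,108 discriminant probe sets among 1,459 variant ones).
Samples are the subtype mean plus i.i.d. N(0, `noise_sd`²) noise.  The
within-subtype variance of real cohorts is not published; `noise_sd` is
therefore a free parameter, with 1.0 (signal-to-noise 1.5 per marker gene)
as a deliberately non-trivial default.

**Annotations.**  Binary markers are Bernoulli draws conditional on
subtype.  Defaults encode the published subtype enrichments: dMMR 0.68 and
*BRAF* 0.40 in C2, *KRAS* 0.87 in C3, CIMP 0.59/0.18/0.34 in C2/C3/C4,
*TP53* and distal location enriched in the CIN subtypes C1/C5/C6.  TNM
stage is drawn independently of subtype (no stage association).

**Survival.**  Relapse times are exponential with per-subtype monthly
hazard λ_s = −ln(RFS₅y[s])/60 — the minimal constant-hazard model matching
the published 5-year RFS proportions (0.70, 0.77, 0.65, 0.52, 0.70, 0.61
for C1..C6).  Censoring is an independent exponential clock with rate
0.0135/month (ln 2 / 51.5, the cohort's median follow-up) plus an
administrative cap at 240 months.  Real RFS hazards are not constant;
the exponential choice affects curve shape, not the 5-year marginals.

**Copy number.**  The genome is modelled at chromosome-arm resolution
(44 autosome arms, approximate physical lengths).  CIN subtypes
(C1/C5/C6) carry the recurrent pattern +7, −8p, +8q, +13q, −17p, −18,
+20q, each arm altered with penetrance 0.9.  Because this pattern covers
only ~19% of the autosomal genome — just under the 20% CIN threshold —
while real CIN+ tumors additionally carry private aneuploidies, each
subtype also has a background rate (0.20/arm for CIN subtypes,
0.02–0.08 otherwise) of random-sign alterations on the remaining arms.
This puts CIN-subtype tumors at a mean altered fraction of ~0.33 and
non-CIN tumors at ≤ 0.06.

**Randomness.**  One global seed expands into independent per-component
generators (expression, annotations, survival, CGH) via spawned seed
sequences, so adding or re-running one component never perturbs another.

What the generator does *not* emulate: probe-level array artifacts, batch
effects, correlated noise or expression gradients within subtypes, partial
subtype overlap (all six planted subtypes are equally separated), gene-gene
correlation outside the planted blocks, and non-exponential hazards.
Passing tests on this cohort demonstrate correctness of the machinery and
recoverability of planted structure at realistic signal-to-noise, not
performance on any real cohort.

## Consensus clustering

The base clusterer is agglomerative clustering of samples with Ward's
criterion on d(i,j) = 1 − r(i,j), the Pearson-correlation distance
(scipy's nearest-neighbor-chain linkage applied to the precomputed
dissimilarity, i.e. the classical `hclust`-style Ward on a non-Euclidean
distance).  Samples with zero variance are rejected by name, as their
correlation is undefined.

Each consensus iteration draws ⌈0.9·n⌉ samples and ⌈0.9·p⌉ features
without replacement, clusters the subsample, and records co-membership.
The consensus value M[i,j] is the co-clustering count divided by the
co-sampling count (not the iteration count), the unbiased co-clustering
rate under subsampling; pairs never co-sampled (essentially impossible at
the default 1,000 iterations) are set to 0 with a warning.  A scan over a
k range re-uses each iteration's subsample and linkage tree, cutting it at
every k, so a full scan costs one clustering per iteration.  Final labels
come from average-linkage hierarchical clustering of 1 − M; average
linkage is the established default for consensus matrices, whose
ultrametric structure Ward would distort.

**Choosing k.**  `select_k` computes, for every k: the area under the
empirical CDF of the off-diagonal consensus values; the relative area
increase over k−1 (delta-area curve); and the proportion of ambiguous
consensus values (PAC: the fraction of pairs with consensus strictly
between 0.1 and 0.9).  The default selector takes the **largest k whose
PAC is within 0.01 of the scan minimum** — the most granular clustering
that is still (nearly) perfectly stable.  The delta-area rule ("largest k
with relative increase ≥ 0.025") is available as
`select_k(..., method="delta_area")` and the curves are always reported
for inspection.

The PAC default is a deliberate design choice.  On planted six-subtype
cohorts the delta-area rule systematically overshoots: cutting the Ward
tree one step past the true k splits the largest subtype (27% of samples)
in a way that is stable across resamples — the noise realization is fixed,
so the same split recurs — which moves more consensus mass than the true
5→6 step that merely separates the two smallest (10%) subtypes.  No fixed
delta threshold can order these correctly, a known limitation of
CDF-based consensus criteria; the spurious splits are, however, partially
unstable, so PAC is ≈ 0 up to the true k and jumps to ~0.1 beyond it.
On the default cohort the PAC selector recovers k = 6 in 10/10 seeds
(n_iter = 250), the delta-area rule in 1/10.

## Moderated t-statistics

One-vs-rest differential expression uses the empirical-Bayes moderated
t-statistic: gene-wise pooled two-sample variances s_g² (d_g = n₁+n₂−2
degrees of freedom) are shrunk toward a prior s₀² with d₀ prior degrees of
freedom,

    s̃_g² = (d₀·s₀² + d_g·s_g²) / (d₀ + d_g),
    t_g = (x̄₁ − x̄₂) / (s̃_g √(1/n₁ + 1/n₂)),   t_g ~ t(d₀ + d_g).

(d₀, s₀²) are estimated by moment-matching the log sample variances: the
mean and variance of log s_g² are equated to their theoretical values
under s_g² ~ s₀²·χ²_{d_g}/d_g scaled by an F-distributed factor, giving d₀
through an inverse-trigamma Newton iteration.  When the spread of log
variances does not exceed pure sampling noise, d₀ = ∞ and every gene
receives the common variance.  The implementation agrees with the
reference R implementation (limma's `eBayes`) to ~1e-14 on test fixtures,
and reduces exactly to the ordinary pooled t-test at d₀ = 0.  All-constant
genes receive a variance floor (10⁻⁸ × the median positive variance) and a
logged warning.  Multiple testing uses Benjamini-Hochberg throughout
(statsmodels); "adjusted p" always means BH-adjusted.

Discriminant genes per subtype satisfy adjusted p < 10⁻⁵ and
|log₂FC| > 0.5 (both configurable), ranked by |t|.

## Centroid classifier

The model keeps, per subtype, the top `d_pairs` up- and down-regulated
qualifying genes ranked by |moderated t| — |t| rather than raw fold change,
for consistency with the selection test; the union of markers (shared
genes counted once) defines the model genes, and each centroid is the
subtype mean of gene-median-centered training expression.  Assignment
centers the query cohort **by its own gene medians** (robust
cross-platform behavior; a single-sample cohort is left uncentered, since
it is its own median) and computes 1 − Pearson correlation over the model
genes present in the query (≥ 50% required; missing genes dropped
pairwise).  The call is the nearest centroid; when the two smallest
distances differ by less than 5% relatively (`mixed_delta=0.05`,
configurable) the pair is reported as a mixed call, mirroring tumors
genuinely intermediate between two expression programs.

`d_pairs` is chosen by stratified 10-fold cross-validation in which the
*entire* build — moderated t-statistics, gene ranking, centroids — is
refit within each training fold; the held-out misclassification curve over
d = 1..25 is pooled across folds, and the smallest d attaining the minimum
is selected (parsimony on ties).

## Characterization

Contingency tests are Pearson chi-squared with `correction="auto"`: Yates
continuity correction applied iff the table is 2×2 (the convention that
reproduces published cohort-comparison p-values; the multi-level stage
comparison requires the uncorrected statistic).  Gene-set enrichment is
the upper-tail hypergeometric probability P(X ≥ overlap) of a subtype
signature (default: top 1,000 genes by t, up and down separately) against
each set, BH-adjusted across sets within a direction; the universe
defaults to all genes on the matrix.  Signature scores are mean centered
expression over up genes minus down genes.  CIN calls use the
length-weighted fraction of bins in a non-neutral state, CIN+ at ≥ 0.20
(inclusive).  Per-region tests compare alteration proportions across
subtypes per bin and sign (uncorrected chi-squared, BH over testable
rows, significance at adjusted p < 0.01); bins with a zero margin are
skipped.  SEG input with continuous log2 ratios is discretized at ±0.1
(configurable), as the original calling thresholds are not published.

## Survival

Times are months; records beyond the 60-month horizon are truncated and
censored (the boundary itself is kept).  Kaplan-Meier and log-rank come
from lifelines; Cox models use lifelines' `CoxPHFitter` (Efron tie
handling — the ecosystem default, appropriate for monthly-resolution
ties; the original analysis's tie method is unstated).  Categorical
covariates are dummy-encoded against their first sorted level
(`stage=III (ref=II)` style).  The model p-value is the likelihood-ratio
test against the null model, whose Efron log partial likelihood is
computed in closed form.  Stepwise selection starts from the full model
on complete cases and takes, at each step, the single covariate addition
or removal that most decreases AIC = 2k − 2·log PL, stopping when no move
improves it; the procedure is deterministic and can return the null model
(with a warning).  The high-risk recoding pools C4 and C6 against the
rest.

## Problem sizes and known limitations

The bundled tests and the acceptance script run on desk-scale cohorts:
n = 300 samples × 2,000 genes for classifier cross-validation and
cluster-number recovery (250 consensus iterations per scan, 10 seeds),
n = 2,000–20,000 records for survival calibration checks.  These sizes
give Monte-Carlo margins comfortably inside the asserted tolerances.

Known limitations: the exact variance-class rule behind "most variant
genes" is approximated as top-n by standard deviation; published
cohort-table p-values for sex, *KRAS* and *BRAF* are not reproduced by
either Pearson or Yates chi-squared on the printed counts (documented,
not resolved); the classifier does not reproduce any published 57-gene list
(real-data dependent), though such a list can be supplied as data; and
multinomial association modelling, raw-array preprocessing (RMA, ComBat)
and external cohort retrieval are out of scope.
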