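# colotype

Molecular subtyping of colon-cancer gene-expression cohorts.

Colon cancer is molecularly heterogeneous: beyond the classical
mismatch-repair-deficient (dMMR) vs chromosomally unstable (CIN) dichotomy,
bulk expression profiles of resected tumors separate into reproducible
molecular subtypes with distinct mutation spectra (*KRAS*, *BRAF*, *TP53*),
methylator status (CIMP), copy-number patterns, and relapse-free survival
(RFS).  `colotype` implements the complete analysis workflow used to
discover and deploy such a classification:

1. **Feature selection** — the *n* most variant genes (default 1,459) of a
   log2 expression matrix.
2. **Consensus clustering** — hierarchical clustering (Ward linkage,
   d(i,j) = 1 − r(i,j) Pearson-correlation distance) repeated over random
   subsamples of 90% of samples and features (default 1,000 iterations).
   The consensus matrix M holds, for each sample pair, the co-clustering
   rate among iterations where both were drawn.  The number of clusters k
   is chosen from the distribution of consensus values (PAC criterion,
   with the CDF/delta-area curves reported alongside).
3. **Subtype signatures** — one-vs-rest empirical-Bayes moderated
   t-statistics with Benjamini-Hochberg adjustment; discriminant genes
   satisfy adjusted p < 10⁻⁵ and |log₂FC| > 0.5.
4. **Centroid classifier** — per subtype, the top d up- and d
   down-regulated genes (|t| ranking) form correlation-distance centroids;
   d is chosen by stratified 10-fold cross-validation, and samples nearly
   equidistant to two centroids receive a mixed call.
5. **Characterization** — chi-squared contingency tests of subtype vs
   annotation, hypergeometric gene-set enrichment of subtype signatures,
   up-minus-down signature scoring, CIN calling from array-CGH profiles
   (CIN+ when ≥ 20% of genome length is gained or lost), and per-region
   alteration-frequency comparisons.
6. **Survival** — RFS censored at 60 months, Kaplan-Meier curves, log-rank
   tests, Cox proportional-hazards models (Efron ties) with Wald CIs and
   bidirectional AIC covariate selection, plus the high-risk (C4 ∪ C6)
   recoding.

A synthetic-cohort generator (`colotype.sim`) emulates the statistical
structure of a six-subtype cohort — prevalences 21/19/13/10/27/10%,
subtype-conditional marker frequencies (e.g. dMMR 68% and *BRAF* 40% in C2,
*KRAS* 87% in C3), recurrent CIN copy-number patterns (+7, −8p, +8q, +13q,
−17p, −18, +20q) in C1/C5/C6, and subtype-specific 5-year RFS
(70/77/65/52/70/61%) — so the whole pipeline is testable end to end without
external data.

The discovery and assignment stages are scikit-learn estimators
(`ConsensusClustering`, `NearestCentroidSubtyper`, `MostVariantSelector`)
and compose with sklearn pipelines and model selection; module-level
functions mirror them for genes × samples DataFrames.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from colotype.sim import SimConfig, simulate_cohort
from colotype.features import select_most_variant
from colotype.consensus import ConsensusConfig, run_consensus_scan, select_k
from colotype.centroid import cv_scan_pairs, build_centroid_model
from colotype.surv import censor_at_horizon, logrank_test, cox_fit, recode_high_risk

expr, labels, annot, surv, cgh = simulate_cohort(SimConfig(seed=1))

sel = select_most_variant(expr, 1459)
runs = run_consensus_scan(expr.loc[list(sel.selected_gene_ids)],
                          ConsensusConfig(k_range=(2, 10), n_iter=250, seed=1))
ks = select_k(runs)
print("selected k:", ks.k_selected)
print("ARI vs planted:", adjusted_rand_score(labels, runs[ks.k_selected].labels))

curve, d = cv_scan_pairs(expr, labels, d_range=range(1, 26), folds=10, seed=1)
print(f"selected gene pairs: {d} (CV misclassification {curve[d]:.1f}%)")

rec = censor_at_horizon(surv)
stat, df, p = logrank_test(rec, labels)
print(f"log-rank across subtypes: chi2={stat:.1f}, df={df}, p={p:.3g}")
rec["high_risk"] = recode_high_risk(labels)
row = cox_fit(rec, ["high_risk"]).summary.loc["high_risk"]
print(f"high-risk (C4+C6) HR={row['hr']:.2f} "
      f"(95% CI {row['ci_lower']:.2f}-{row['ci_upper']:.2f}), p={row['p']:.3g}")
```

prints

```
selected k: 6
ARI vs planted: 1.0
selected gene pairs: 9 (CV misclassification 0.0%)
log-rank across subtypes: chi2=11.3, df=5, p=0.0451
high-risk (C4+C6) HR=2.21 (95% CI 1.27-3.87), p=0.00526
```

The consensus scan re-identifies the six planted subtypes exactly (adjusted
Rand index 1.0); the cross-validated centroid classifier is error-free at
nine gene pairs per direction; survival of the six subtypes differs
(log-rank p ≈ 0.05), and combining the two poor-prognosis subtypes into a
high-risk group roughly doubles the relapse hazard — the generator's planted
5-year RFS gap recovered by the Cox model.

A command line mirrors the stages:

```bash
colotype simulate --seed 1 --out cohort/
colotype discover --expr cohort/expression.tsv --iters 1000 --seed 1 --out disc/
colotype train-centroids --expr cohort/expression.tsv --labels disc/subtypes.csv \
    --pairs-max 25 --seed 1 --out model.json
colotype classify --model model.json --expr new_cohort.tsv --out calls.tsv
colotype run --seed 1 --out report/        # full pipeline + manifest
```

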