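# Methods notes

This note records the modelling choices behind `pathchemo`, what the
synthetic generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Enrichment statistic and permutation null

The enrichment score is the classic weighted running sum: walking down the
ranked signature, a gene in the query set adds `|s|^w / Σ_hits |s|^w` and a
gene outside it subtracts `1/(N − N_hit)`; ES is the extremum (the sign of
the larger absolute deviation, positive preferred at an exact tie). The
weight exponent defaults to `w = 1`. The leading edge is the hit genes at
or before the peak (after the trough for negative ES).

The null permutes gene labels — equivalently, places the hit set at
uniformly random ranks — with 1,000 permutations by default. Because the
running sum only falls between hits, the null ES is computed in O(k) per
permutation from the sorted hit positions; pathways with the same overlap
size share one permutation draw, exactly as gene-label permutation shares
draws across gene sets. At an exact `|max| = |min|` tie the fast path and a
sequential cumulative sum can disagree on the sign by float rounding; the
null is symmetric there, so NES and p are unaffected.

Normalization and significance are sign-conditioned, following common
GSEA practice: `NES = ES / |mean(null ES of the same sign)|` and
`p = (#{same-sign nulls with |ES_null| ≥ |ES|} + 1) / (#same-sign + 1)`.
The add-one estimator keeps p off zero; its floor is therefore
`1/(n_same + 1)`, which is at least `1/(n_perm + 1)`. If no null shares the
observed sign the p is floored and a degeneracy warning logged.

## Signed, absolute and composite enrichment

Signed enrichment runs on the raw differential scores and is
direction-aware. Absolute-valued enrichment runs on `|score|`, collapsing
the two signature tails so that sets with genes moving in both directions
still enrich at the top; negative NES in this mode means enrichment among
the *unchanged* genes and is never used. The composite per pathway is
whichever eligible result (signed, or positive-NES absolute) has the lower
p; ties go to the signed result so directional information is retained.
Composite p equals the minimum eligible input p by construction.

## Signatures

Signatures are oriented poor − favorable, so positive scores mean higher
in poor responders and NES signs are interpretable. Welch's t uses the
Welch–Satterthwaite statistic; features constant in both groups are
dropped. Methylation testing is parametric on M-values
(`M = log2(β/(1−β))`, β clipped to `[1e−6, 1 − 1e−6]` so boundary values
stay finite while ordering is preserved); fold changes stay on the β
scale. Site-per-gene selection maximizes the coefficient of variation of β
across all cohort samples (β rather than M because M can have near-zero
mean, making CV unstable); ties break to the lexicographically smallest
site id. In all-sites mode a pathway gene with several sites contributes
the site with the largest |score|, preserving the strongest signal.

## Cross-omics integration

Both composite pathway signatures are ranked by |NES| (ties by smaller p,
then name). The second-order GSEA treats pathways as items, |composite
NES| of the expression signature as scores, and the methylation-significant
pathways as the query set; nulls permute pathway labels (1,000 by
default). The query threshold is scanned over 0.001–0.05 in steps of
0.005; each threshold's enrichment is repeated (100 runs by default,
deterministic seed sequence) and the mean NES recorded because the
permutation p/NES is stochastic; the optimal threshold maximizes mean NES,
ties to the smallest θ. Candidates are the leading-edge pathways at the
optimal θ; when the pathway-level p exceeds 0.05 the candidate set is
flagged `no_dual_signal`.

Redundancy pruning tests every candidate pair's leading-edge overlap with
a two-sided Fisher exact test against a universe defaulting to the union
of all candidate leading edges and the signature genes, BH-corrects the
p-values, and joins pairs with q < 0.05 **and** overlap above its
independence expectation into connected components (the over-representation
guard exists because a two-sided test also flags significantly depleted
overlaps, which say nothing about parent–child redundancy). Each component
keeps the pathway with the lowest composite expression p (configurable to
the minimum over both omics).

## Single-sample activity

Matrices are z-scored per feature (sample sd, n − 1); each sample's
z-score vector is ranked and used as the reference of signed + absolute
enrichment for every candidate pathway, integrated per cell by the same
min-p rule. One permutation stream (per mode) is shared across samples, so
two patients with identical profiles receive identical activities.
Expression-level and methylation-level activities use the identical code
path; only the input matrix differs.

## Survival validation

Stratification embeds the pathway-activity vectors with t-SNE (perplexity
`min(10, ⌊(n−1)/3⌋)` by default, suited to the 23–40-patient validation
cohorts this design targets; raw NES input) and cuts the embedding with
2-means (10 restarts); the cluster with the larger mean activity is
labelled *high*, making the hazard-ratio orientation deterministic.
Log-rank and Cox fits come from lifelines; the headline HR is the
univariable high-vs-low fit, and model significance uses the
likelihood-ratio test, which is better behaved than Wald at these sample
sizes. Both random models use the add-one empirical p,
`(r + 1)/(n_draws + 1)`. LOOCV predicts the binary response indicator from
pathway activities with near-unpenalized logistic regression (ridge
fallback if a fold separates perfectly); AUROC uses the concordant-pair
formulation with ties counting one half.

A practical note on random model 1: random pathway sets are not perfectly
uninformative on cohorts with a strong planted (or real) signature,
because differentially expressed genes crowd the top of every single-sample
ranking and so depress the signed NES of *all other* pathways in affected
samples. Random-pathway empirical p-values are therefore conservative;
this compositional effect is a property of rank-based single-sample
scoring, not of the simulation.

## Read-out genes

Candidates are the union of a pathway's expression and methylation
leading edges. Correlation evidence is Pearson r between the gene's values
(expression values for expression/both genes, M-values for
methylation-only genes) and the pathway's per-sample activity, p via the t
transform with n − 2 df; survival evidence is the Cox likelihood-ratio p
of the single continuous gene covariate. Fisher's method combines the two
(`X = −2 Σ ln p`, chi-square with 2k df), and the gene with the smallest
combined p wins per pathway (ties: larger |r|, then name) — one gene per
pathway.

## Synthetic cohorts

The generator plants truth the pipeline should recover. Defaults are the
package's study conditions: 100 disjoint pathways × 30 genes, 5 pathways
planted on both levels, 4 + 4 extreme responders, expression shift 2σ on
planted genes in the poor group (Gaussian noise σ = 1), methylation shift
Δβ = +0.2 on planted sites. Methylation uses 1–3 CpG sites per gene with
site means drawn from Beta(2, 5) (a predominantly hypomethylated baseline)
and per-sample values from a Beta with concentration 50 around the site
mean, so values stay in [0, 1] naturally. Survival times are exponential
with log-hazard `log h = log h₀ + c·a`, where `a` is the sample's mean
expression over planted genes (h₀ = ln 2/365 per day, c = 1); a configured
fraction (default 30%) of samples is censored uniformly before their event.
A separate activity-space generator produces validation-style cohorts
(7 pathways, 20 + 20 patients, activity blobs Δ = 5, σ = 0.5, hazard
multiplier 4 for the high group) for exercising stratification and
survival directly.

What the generator does **not** emulate: correlated co-expression within
pathways, 450K probe-level covariance and bimodality, batch effects,
overlapping pathway memberships, and informative censoring. Passing tests
therefore demonstrate the machinery's correctness and calibration, not
performance on real cohorts. One structural consequence of the survival
contract: at the default hazard scale nearly every patient has an early
event, so the planted response groups travel with the cohort
(`SyntheticCohort.groups`, `response_groups.tsv`) instead of being
re-derivable from the simulated clinical table by the 1-year/2-year
thresholds — mirroring real studies, where extreme-responder selection
happens upstream of this pipeline.

## Problem sizes and determinism

Tests and the acceptance script run the discovery stage at n_perm = 500
with 10 scan repetitions, null-calibration checks at n_perm = 200 over
200–500 replicates, and random models at 50–1,000 draws; these sizes give
stable means and calibrated tails while keeping a full run in minutes on
one core. All stochastic stages consume `numpy.random.Generator` seeds
derived from a single master seed via `SeedSequence`, so every result in
this repository is exactly reproducible.

## Known limitations

- Sampling variability of the Cox hazard ratio at n = 40 with ~28 events
  is substantial (SE of log HR ≈ 0.38): point estimates for a true HR of 4
  fall outside [2.5, 6.5] in roughly a quarter to a third of cohorts even
  with perfect group recovery. Stratification accuracy and log-rank
  significance are the stabler read-outs at that size.
- Gene-label permutation tests the wrong null when genes are strongly
  co-expressed (inflated significance on real data); sample permutation is
  out of scope.
- The threshold scan inherits the discreteness of permutation p-values:
  at n_perm = 500 the smallest grid thresholds below the attainable p
  floor (1/(n_same+1) ≈ 0.004) have empty query sets and are reported as
  unavailable.
- t-SNE + 2-means always returns two groups; on cohorts without real
  structure the downstream log-rank p is approximately uniform, and the
  `no_dual_signal` flag plus the random models are the guards against
  over-interpretation.
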