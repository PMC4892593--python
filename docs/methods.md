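# Methods

This note documents the statistical model behind `comarker`, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical details a maintainer would
need to change anything safely.

## The consensus screen

The pipeline answers one question: *which genes are differentially
expressed between cases and controls in (nearly) every cohort of a
multi-cohort, multi-sample-type study, under both per-gene and
joint-model analysis?*  Its output, the common-marker set, is the
intersection of two pools.

**Marginal pool.**  Within each cohort every gene is scored three
ways on the log2 expression matrix:

* fold change `FC = 2^(mean_case − mean_control)` — the ratio of
  geometric-mean intensities; ranking uses the magnitude
  `max(FC, 1/FC)` by default so down-regulation competes equally
  (`fc_rank_mode="ratio"` restores up-only ranking, the convention of
  some published screens);
* a two-sample t-test, Welch by default — the cohort designs are
  grossly unbalanced (157 cases vs 20 controls) and the
  equal-variance assumption has no support there; Student's pooled
  form is available via `t_variant="student"`;
* Benjamini–Hochberg q-values of the t-test p-values across genes.

Per cohort: top `k = 100` genes by FC magnitude, top 100 by p-value,
and every gene with `q ≤ 0.001` (a level, hence inclusive).  Each
method then takes a cross-cohort vote: keep the genes selected in at
least `m = 3` of the `n = 4` cohorts.  The union of the three
post-vote sets is the marginal pool.  All rankings break ties by gene
symbol so selections are deterministic functions of the statistics.

**Joint pool.**  Per cohort, an L1-penalized logistic regression of
case/control on all standardized gene columns:

    min over (b0, beta) of  (1/n) sum_i log(1 + exp(-y_i (b0 + x_i' beta)))
                             + lambda * ||beta||_1

solved along a 100-point log-spaced grid descending from
`lambda_max = max_j |x_j'(y − ȳ)|/n` (the entry threshold below which
the first coefficient becomes nonzero) to `lambda_max × 0.01`
(`× 1e-4` when n > p, following glmnet's convention).  λ is chosen by
stratified 10-fold cross-validated binomial deviance; cohorts whose
smaller class cannot fill 10 folds (the 5-vs-5 monocyte design) fall
back to leave-one-out.  The pipeline default applies the **1-SE
rule** — the sparsest model within one standard error of the minimum
deviance — and aggregates per-cohort supports by **union** across
cohorts ("pooled").  Both choices deserve justification:

* CV-minimum λ is prediction-optimal, not selection-optimal; under a
  global null it retains spurious genes in a large fraction of runs
  (familiar to any cv.glmnet user).  The 1-SE rule is the standard
  parsimony correction when the support, not the prediction error, is
  the product.
* Requiring the same gene in 3 of 4 lasso supports (symmetric with
  the marginal vote) sounds natural but conflates *predictive
  sufficiency* with *association*: once a few strong markers separate
  the classes in a cohort, the lasso shrinks the remaining associated
  genes to zero, so each cohort contributes a small,
  partially-arbitrary subset of the true markers and their 3-of-4
  intersection is far smaller than the set of genes with real joint
  signal.  In simulation the symmetric vote recovers a median of ~10
  of 15 planted markers where the pooled union recovers 14–15 (see
  the acceptance suite).  Cross-cohort replication is already
  enforced by the marginal arm of the intersection; the joint arm
  contributes the multivariate-relevance filter.  The symmetric vote
  remains available (`joint_consensus="m_of_n"`), as does
  `lambda_rule="min_deviance"` (the `LassoConfig` default when the
  class is used standalone).

**Intersection.**  Common markers = marginal pool ∩ joint pool.  The
report lists, per marker per cohort, FC, p, q and which methods
selected it, plus min–max FC per sample type — the summary that makes
signal attenuation across sample types (monocyte > PBMC > whole
blood) visible at a glance.

## The path solver

The L1-logistic path is solved by a glmnet-style algorithm written in
this package: an outer iteratively-reweighted least-squares loop
(probability floor 1e-5 on the working weights) around a
numba-compiled cyclical coordinate descent on the weighted quadratic
approximation, restricted to an active set grown by KKT-violation
screening, warm-started along the descending grid.  Generic solvers
(scikit-learn's saga/liblinear) solve single instances but are an
order of magnitude too slow for the 4-cohort × 11-fit × 100-λ
workload this pipeline runs routinely; they serve instead as
independent oracles in the test suite, which checks (a) exact-zero
supports at `lambda_max`, (b) KKT residuals of the *true* logistic
objective below 1e-7 across whole paths and random instances, and
(c) coefficient agreement with saga and with a generic bound-
constrained L-BFGS-B formulation to ~1e-5.  Standardization uses
population variance; zero-variance columns are zeroed and therefore
unselectable.  Convergence: inner CD stops when the largest
scaled coordinate update falls below `tol` (default 1e-8), the IRLS
loop when coefficients stabilize; every fit is deterministic given
the fold seed.

## The synthetic generator

The generator emulates the study design the pipeline targets: four
case-control cohorts (5/5, 61/20, 99/30, 157/20) on three platforms
over monocyte, PBMC and whole blood.  On the log2 scale each gene has
a baseline `~ Uniform(4, 12)`; each sample adds `N(0, noise_sd)`;
planted markers add `attenuation[sample_type] × base_log2_effect` in
cases.  Genes expand to 1–3 probes per platform (constant per-probe
offset `N(0, 0.2)` plus iid `N(0, 0.1)` measurement noise), ~2% of
probes are unannotated, and each platform profiles the shared core
plus private genes so that the cross-cohort panel intersection equals
the core exactly.  One `SeedSequence` per run is spawned per cohort,
so adding a cohort never perturbs earlier cohorts' data; platform
structure is keyed by a hash of the platform id, independent of
cohort order.

Defaults: `attenuation = {monocyte: 1.0, pbmc: 0.6, whole_blood:
0.15}` reproduces the fold-change ladder observed for real
interferon-pathway markers (e.g. FC ≈ 8.8 in monocyte shrinking
to ≈ 1.2–1.4 in whole blood).  `noise_sd = 0.25` is a single global
within-group sd on the log2 scale: published per-cohort statistics
for such markers imply ~0.12–0.15 in whole blood and ~1.0 in the
small monocyte cohorts, so one number is necessarily a compromise;
0.25 keeps whole-blood planted effects (0.22–0.45 log2 after
attenuation) detectable at t ≈ 4–9, matching the order of magnitude
of the real whole-blood statistics, while leaving the monocyte cohort
cleaner than its real counterpart.  The flagship test configuration
plants 15 markers with base effects 1.5–3.0 log2.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: gene–gene correlation
(real expression is heavily co-regulated; lasso behavior under
correlated predictors is harsher), batch and platform intensity
effects, disease-activity and demographic covariates, non-normal
heavy-tailed noise, and probe-level cross-hybridization.  Recovery
rates measured here are best-case for the noise model.

## Harmonization details

Probe collapse precedes panel intersection (the only order under
which "commonly profiled genes" is well defined across platforms).
`max_mean_probe` is the default collapse rule (highest mean intensity
across all samples wins; ties break lexicographically by probe id),
with `mean_of_probes` as the alternative; the choice is exposed
because no convention dominates in practice.  The scale heuristic
log2-transforms (`log2(x+1)`) any matrix whose maximum exceeds 50 —
log2 microarray data rarely exceeds ~16 while linear intensities run
into the thousands; negative entries alongside a large maximum are
contradictory and raise.

## Degenerate inputs and numerical conventions

* Genes constant within both groups: `t = 0, p = 1` when the group
  means agree, `p = 0` with infinite t when they differ — totals are
  preferred to NaNs so downstream rankings stay defined.
* BH is computed by statsmodels and pinned to a definitional
  brute-force implementation (max deviation < 1e-12 over 1,000 random
  vectors) in the tests.
* Enrichment: hypergeometric upper tail `P(X ≥ k)`, `p = 1` at
  `k = 0`; the universe should be the commonly profiled genes, not
  the genome; term membership is intersected with the universe before
  testing and terms absent from the universe are not tested.  The
  published GO p-values for the motivating study came from a web
  service with an unstated universe and correction, so they are not
  reproduction targets.
* PPI "isolated" members of a study set A are those with no edge in
  the subgraph induced by A ∪ B; two-step indirection through outside
  nodes is deliberately out of scope.
* Cross-cohort vote counting and pool algebra assert the
  inclusion–exclusion identity `|A∪B| = |A|+|B|−|A∩B|` on every call.

## Problem sizes used in the acceptance suite

The flagship acceptance checks simulate the four-cohort design at
2,000 shared genes — large enough that the top-100 rules cover 5% of
the panel and the lasso runs at p ≫ n, small enough that twenty
replicate studies run in minutes.  Null calibration uses 20
marker-free replicates (plus a per-cohort binomial band check of the
t-test's 5% level on one replicate); parameter recovery uses 20
replicates with 15 planted markers.  At this desk scale the marginal
top-100 rules select 5% of the panel versus 1.5% at the original
6,643-gene scale, which inflates the by-chance marginal pool roughly
tenfold; consequences for the null behavior of the *pooled* joint
mode are discussed above.

## Known limitations

* Independent-gene simulation overstates lasso support recovery
  relative to correlated real data.
* The per-cohort lasso support is not a complete list of jointly
  associated genes (redundancy shrinkage); only the pooled union
  should be interpreted, and only through the intersection with the
  marginal pool.
* The log-scale heuristic can mis-classify unusual data (e.g. ratio
  arrays centered on 0 with spikes above 50 would raise).
* No meta-analytic effect pooling, moderated t statistics, or
  stability selection; these are deliberate non-goals.
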