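# Methods

This note documents the statistical models, conventions and design choices
behind `psascreen`, in the order a study runs: cohort emulation, data
preparation, feature screening, model benchmarking, index construction and
evaluation, triage.

## Synthetic cohort model

The generator's purpose is to produce labeled PSO/PSA cohorts whose
per-variable marginal distributions match published per-group summary
statistics, because subject-level data from the two source cohorts (a US
survey-based cohort of 574 PSO / 145 PSA subjects and a Chinese hospital
cohort of 98 / 37) are not publicly deposited.  Each variable in the
shipped catalogue (`data/cohort_catalogue.yaml`) carries a family and
per-group parameters:

* **Skewed variables** (summarized as median (Q1, Q3)) are sampled as
  `exp(Y)` where `Y` is a two-piece normal centred at `ln median` with
  per-side standard deviations `(ln median − ln Q1)/z₀.₇₅` and
  `(ln Q3 − ln median)/z₀.₇₅`, `z₀.₇₅ = 0.67449`.  This matches all three
  printed quartiles exactly and reduces to an ordinary lognormal whenever
  the printed quartiles are symmetric on the log scale.  A plain lognormal
  (the fit returned by `fit_lognormal_from_quartiles`, `mu = ln median`,
  `sigma = (ln Q3 − ln Q1)/(2 z₀.₇₅)`) reproduces the median exactly but
  biases both quartiles by the factor `median/√(Q1·Q3)` — up to +19% for
  the Chinese PSA CRP row and +41% for the US PSA eosinophil row — which is
  why the two-piece form is the generator default.  The headline
  simulation checks in `scripts/acceptance.py` deliberately use the plain
  symmetric fit, which is the simpler model stated for those checks.
* **Symmetric variables** (mean ± SD) are truncated normal with floor 0.01
  (counts, percentages and CRP must be positive) and ceiling 100 for
  percentages.
* **Binary and categorical variables** use the printed per-group count
  proportions; categories carry integer codes starting at 1 in printed
  order (sex: male 1 / female 0; yes/no: 1/0).

Every family is driven through a standard-normal vector, so dependence is a
configuration switch: independence (default) or a Gaussian copula with a
user-supplied latent correlation matrix.  Independence is the default
because the source material shows that nonzero correlations exist but does
not print a matrix.

One catalogue irregularity is carried as printed and flagged: the US-cohort
albumin row duplicates the white-blood-cell row (clearly a transcription
defect in the source table — the companion heterogeneity table puts albumin
near 4.2 g/dL).  Albumin is not a PSAII component, so the headline checks
are unaffected; CALLY values on the US-like cohort inherit the wrong scale
and should not be compared across cohorts.  The US basophil-count row has
non-positive printed quartiles (0 (0, 0.1)); they are clamped to the 0.01
positivity floor before the log-scale fit.

**What the generator does not emulate:** joint structure of the real
cohorts (unless a copula matrix is supplied), leukocyte-percentage closure
(the percentages are sampled marginally and do not sum to 100 — the index
formulas only use them marginally), measurement error, batch effects, and
any association between the serum panel and the auxiliary triage columns.
A model that performs well on these cohorts demonstrates that the pipeline
recovers marginal group differences; it says nothing about performance on
real, correlated clinical data.

The optional `arthralgia` and `topas` columns are synthetic plumbing to
exercise the triage rule end to end (arthralgia Bernoulli 0.25/0.85 for
PSO/PSA; ToPAS Poisson with mean 3/8 capped at 12).  No published marginal
exists for them; they are not used by any headline check.

## Data preparation

* **Missingness rule.**  Subjects missing more than 1/3 of their variables
  are dropped before imputation, mirroring the source cohorts' exclusion
  criterion.
* **Imputation** is iterative chained regression with a random-forest
  learner (scikit-learn's `IterativeImputer` with a
  `RandomForestRegressor`): each incomplete variable is regressed on all
  others, cycling until the relative change falls below 1e-3 or 10 rounds.
  Imputed values are clamped to the observed range; observed cells are
  never altered; output is deterministic given the seed.
* **Normalization** is min-max, `E(x) = (x − min)/(max − min)`, with min
  and max fitted on the training partition only and reused on held-out and
  external rows (which may therefore leave [0, 1]).  A constant variable
  maps to 0.  Fitting on training folds only is a deliberate
  leakage-prevention choice where the source description is silent.

## Feature screening

Univariate direction-free AUC (`max(AUC, 1 − AUC)`, all-pairs concordance
with ties ½) flags variables above 0.6 as having screening potential.  The
flag is advisory: a variable failing it is not excluded, because the
published final feature set itself contains a variable whose univariate
difference is negligible.  Correlation exclusion is a hard filter: from
every pair with Pearson |r| ≥ 0.8 (computed on encoded numeric variables),
the lower-AUC member is dropped, highest-correlation pairs first.

Selection is an L1-penalized logistic regression over a 50-point descending
penalty path, scored by 10-fold cross-validated log-loss.  The penalty is
chosen by the one-standard-error rule by default (the strongest penalty
whose mean CV score is within one SE of the best); the minimum rule is a
configuration switch, since the source material plots both and names
neither.  Variables with nonzero coefficients at the chosen penalty are
selected; an empty selection is a warning, not an error.

On synthetic cohorts at the published sizes the selection is broader than
the five features reported from the real data: several comorbidity and
demographic variables genuinely differ between groups per the printed
summaries, and with real signal present the penalized fit correctly keeps
them.  CRP, the dominant printed effect, is recovered essentially always
(the recovery test requires ≥ 18 of 20 seeded runs).

## Model benchmark

Five learners — logistic regression, k-nearest neighbours,
gradient-boosted trees, a one-hidden-layer neural network, and a random
forest — are compared under 5-fold cross-validation (719 subjects split
144/144/144/144/143).  Inside each fold, min-max scaling and
hyperparameter selection (3-fold inner CV over small grids: KNN
k ∈ {3,5,7,11,15}; RF 500 trees, depth {3,5,∞}; GBDT trees {100,300} ×
rate {0.05,0.1} × depth {2,3}; NN hidden units {4,8,16}; LR unpenalized vs
light ridge) happen strictly within the training folds.

Reported panels follow the training / held-out / external layout.
Training metrics are **resubstitution** on the k−1 training folds — this
is what makes the flexible learners (GBDT, RF) show near-perfect training
rows while their held-out rows drop, the classic overfitting signature.
Point estimates are means over folds; confidence intervals are computed on
the pooled predictions of the partition (fold-mean CIs are not
well-defined).  The screening cutoff balancing sensitivity and specificity
is fixed on the training partition of the final refit and reused for the
external cohort.  No class reweighting is applied.  The logistic model is
refit on all rows to report coefficients β and odds ratios exp(β).

## Index construction and evaluation

`construct_index_from_ors` encodes the development rule that produced
PSAII: among an explicit *eligible* set of serum features, OR > 1 goes to
the numerator, OR < 1 to the denominator, OR = 1 contributes nothing (by
continuity of the sign rule), with a fixed scale constant (10).
Eligibility is explicit because age (OR 1.04) sits in the published model
but not in the index; restricting eligibility to serum features encodes
that choice as a rule rather than an exception.

Classification of an index against a cutoff is strict: positive iff value
> cutoff (or < cutoff for CALLY); equality is negative.  The triage rule
intentionally uses ≥ instead — both conventions come from the source
descriptions and are kept distinct on purpose.

Cutoff selection enumerates the distinct observed scores and minimizes
|sensitivity − specificity|, breaking ties by larger Youden index and then
by smaller threshold (making the result deterministic).  Degenerate inputs
(a single distinct score) return that candidate with a warning.

AUC is pairwise concordance with ties ½.  Its default CI is DeLong's
structural-components estimator (implemented in-package; scikit-learn's
`roc_auc_score` serves as an independent cross-check in the tests);
a stratified percentile bootstrap (≥ 1000 resamples) is the alternative.
Proportion CIs are Wilson; the kappa CI is a 1000-resample bootstrap.  The
CI methods are package choices — the source prints intervals without
naming methods.

Decision curves use the standard net-benefit definition
NB(t) = TP/n − (FP/n)·t/(1−t) with classification at probability ≥ t, and
treat-all / treat-none references.  Calibration curves use ten equal-width
bins on [0, 1].

The adjusted association analysis is a maximum-likelihood logistic fit of
the outcome on the index plus covariates (Wald CI on exp(β); constant
covariates dropped with a warning; separation triggers a penalized refit
that is flagged in the output).  The dose–response analysis uses a
restricted cubic spline basis (natural cubic spline, linear beyond the
boundary knots, normalized by the squared knot range) with 4 knots at the
0.05/0.35/0.65/0.95 quantiles (3 or 5 knots at the corresponding Harrell
quantiles are options), the curve normalized to OR = 1 at the exposure
median, and nonlinearity tested by a likelihood-ratio comparison against
the linear-exposure model (df = knots − 2).

## Triage

With arthralgia: high risk iff PSAII ≥ 18 or ToPAS ≥ 7.  Without
arthralgia: low risk iff PSAII < 18 or ToPAS < 7, hence high risk iff both
thresholds are met.  The rule requires a precomputed ToPAS column and
errors when it is absent — no fallback is invented.  The implementation is
verified against the exhaustive 8-row truth table.

## Problem sizes and numerical conventions

The headline simulation checks sample ten times the published group sizes
(5 740/1 450 US-like and 9 800/3 700 Chinese-like), which puts the
Monte-Carlo standard error of the AUC near 0.005 while keeping each check
under a minute on one CPU.  Marginal-fidelity checks use 50 000 subjects
per group.  All randomness flows through `numpy.random.default_rng` seeds
derived from a single study seed; pipeline reports are written with sorted
keys and 10-decimal rounding so identical configurations produce
byte-identical output.

## Known limitations

* Marginals only: no claim about the joint distribution of real cohorts.
* The published performance tables derive from restricted subject-level
  data and are not exactly reproducible; the package targets the printed
  bounds and structural results (index definitions, construction rule,
  triage rule) instead.
* The published Youden-index column is inconsistent with
  sensitivity + specificity − 1 (e.g. 0.78 + 0.81 − 1 = 0.59 against a
  printed 0.33); the package implements the standard definition and makes
  no attempt to reverse-engineer the printed column.
* ToPAS scoring itself is out of scope; the triage stage consumes a
  precomputed score.
* CRP units are taken as mg/dL throughout; no inter-laboratory unit
  conversion is attempted.
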