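# Methods

## The evaluation problem

`fraxval` evaluates nested 10-year fracture-risk prediction models the way
prognostic-model validation studies do: a baseline score (here a surrogate
FRAX-like logistic score) is compared with expanded models adding clinical
covariates, on three surfaces — discrimination (AUC), category-based net
reclassification (NRI), and decile calibration (O/E). The package is built
around a synthetic cohort whose structure mirrors a large US postmenopausal
cohort, because the underlying individual-level data are not public.

## Synthetic cohort generator

One row per participant. The generative model, in order:

**Covariates.** Age, BMI, physical function (RAND-36 subscale, 0–100) and
lumbar-spine BMD are truncated normals; the location parameter is solved by
bisection so the *realized* (post-truncation) mean equals the configured
mean — published cohort tables report realized means of bounded variables,
so matching them is the right emulation target. Binary risk factors are
independent Bernoulli draws; falls in the past year is a four-level
categorical (0/1/2/≥3). Age and physical function optionally share a
Gaussian copula (`corr_age_physical_function`, default 0: the joint
covariate structure of the real cohort is unknown, so independence is the
default and the knob exists only for sensitivity exploration).

Key defaults (units in parentheses): age 63.0 ± 7.0 y truncated to 50–79;
BMI 27.8 ± 5.8 kg/m²; physical function 83.0 ± 18.5; lumbar-spine BMD
1.0 ± 0.2 g/cm²; falls probabilities (0.682, 0.198, 0.082, 0.039);
prevalences — vasomotor symptoms 22.8 %, prior fracture ≥55 9.2 %, parental
hip fracture 13.7 %, current smoking 5.9 %, glucocorticoid use 0.3 %,
rheumatoid arthritis 4.4 %, heavy alcohol 3 %, baseline osteoporosis-medication
use 2.3 %, self-reported hormone use 50 %. Treated diabetes defaults to 5 %:
cohort tables do not print it; US any-diabetes prevalence in women is about
11 % and pharmacologically treated diabetes is roughly half of that.

**Latent risk.** The 10-year MOF probability is
`p = expit(b0 + Σ βj (xj − cj))` with covariates centered at their
configured means/prevalences, so `b0 = logit(0.124)` is approximately the
marginal event rate (exactly, when all β are zero — Jensen's inequality
makes the marginal rate drift slightly above `expit(b0)` as covariate
variance grows). Default β (log-odds): age 0.055/y, BMI −0.010 per kg/m²,
treated diabetes 0.30, ≥2 falls 0.35, vasomotor symptoms 0.15, physical
function −0.012 per point, prior fracture 0.65, parental hip fracture 0.25,
smoking 0.20, glucocorticoids 0.50, rheumatoid arthritis 0.30, BMD −1.20
per g/cm² — effect sizes in the range epidemiological studies report for
these factors, and chosen so the added covariates carry real but modest
information beyond the baseline score.

**Hip nested in MOF.** A hip fracture is drawn only among MOF events, with
`P(hip | MOF) = expit(−1.97 + 0.11 (age − 63))`. The steep age slope makes
hip fractures concentrate at older ages, reproducing the qualitative fact
that risk scores discriminate hip fracture better than all-MOF. The
intercept sits below `logit(0.169)` — the target marginal hip share of MOF
events — because averaging the convex expit over ages, and the older age
distribution of MOF cases, both push the marginal share above the
intercept's own expit.

**Censoring.** Each participant gets an exponential censoring time with
hazard `dropout + death(age)`, where dropout is 0.03/y (≈26 % lost by 10
years) and the death hazard `0.005 · exp(0.09 (age − 63))` rises
log-linearly with age. Event times are uniform on (0, horizon); an event is
observed only if it precedes censoring. Because age drives both risk and
death, loss to follow-up is informative. No attempt is made to calibrate
absolute death rates.

**What the generator does not emulate.** Real joint covariate correlations
beyond the optional age–physical-function knob; secular trends; measurement
error and self-report misclassification of fractures; competing-risk
structure beyond the age-linked censoring; race/ethnicity strata. Tests
passing on this cohort therefore validate the *estimators and pipeline*,
not any claim about real-world model performance.

## Surrogate baseline score

`expit(−2.10 + 0.065 (age − 63) − 0.015 (BMI − 25) + 0.70·prior fracture +
0.35·parental hip fracture + 0.25·smoking + 0.60·glucocorticoids +
0.35·rheumatoid arthritis + 0.25·heavy alcohol [− 1.80 (BMD − 1.0)])`.

The true FRAX weights are proprietary; this explicit stand-in preserves the
tool's qualitative shape (monotone in age and prior fracture, decreasing in
BMD) and yields a realistic high-risk fraction (roughly 5–10 % of women at
≥20 % predicted MOF risk under the default cohort). Every evaluation treats
the score as an arbitrary monotone predictor: AUC is invariant to monotone
recalibration, the reclassification models refit the score's logit, and no
test depends on the exact weights.

## Eligibility filter

Exclusions are attributed to the first failing criterion, in the order:
baseline osteoporosis-medication use → insufficient follow-up (<horizon
years without the fracture outcome; an event before the horizon always
retains the participant) → missing required covariates → scenario
restrictions (minimum age; hormone-therapy use, where trial assignment
overrides self-report: active arm ⇒ user, placebo arm ⇒ nonuser).
The final sample is order-invariant; only the ledger attribution depends on
the order. Missing covariates are excluded, never imputed. Scenario
switches: `include_short_followup` drops the follow-up rule, `age_ge65`
sets min age 65, `no_hormone_therapy` excludes hormone users.

## Model fitting

Logistic regressions are maximum-likelihood Newton fits (statsmodels)
with tolerance 1e−8 on the log-likelihood change and at most 100
iterations; non-convergence (typically separation) raises an error with
iteration diagnostics rather than returning an unstable fit — no silent
ridge fallback. All evaluation models adjust for the two trial-arm
indicators (hormone and calcium/vitamin D; `not_randomized` is the
reference level). The MLE score equation guarantees mean predicted
probability = observed event rate, which is why the overall O/E ratio is
1.00 by construction under the default `refit` calibration mode; the
alternative `raw` mode assesses the surrogate score's own probabilities as
a fixed external tool would be assessed (meaningful for the MOF outcome
only, since the surrogate emits MOF-scale probabilities).

## Estimator conventions

* **AUC** — Mann–Whitney with ties ½; variance and paired covariance by
  the DeLong structural-components estimator (midrank algorithm,
  O(n log n)); Wald 95 % CI clipped to [0, 1]. Verified to machine
  precision against R `pROC` on a tied fixture. The CI method in the
  emulated study is unstated; DeLong is the documented default, standard
  for correlated ROC curves and required by the paired test anyway.
* **AUC comparison** — z = ΔAUC / SE(ΔAUC); z² referred to χ²(1)
  (two-sided). Unpaired mode pools independent variances and refuses
  overlapping subgroups; paired mode uses the DeLong covariance.
* **NRI** — two categories at the clinical thresholds (MOF 0.20, hip 0.03);
  "high" is the half-open `p ≥ threshold`. Component inference is a
  one-sided McNemar-style normal test of the off-diagonal movement,
  oriented toward improvement — matching the reporting convention where a
  worsening component shows p near 1. The reclassification table type
  stores k×k grids but NRI is always the 2-category computation.
* **Deciles** — sort-and-fill: each block of tied predictions lands wholly
  in the decile where its first member falls, giving unequal decile sizes
  under ties (as in published decile tables) and rank invariance.
* **Calibration slope** — the reported slope is the n-weighted least-squares
  slope of observed on mean-predicted decile proportions; the logistic
  (Cox) recalibration slope is also computed. Published slope values are
  estimator-ambiguous, so neither estimator is asserted against them.
* **Probability guard** — linear predictors are clipped at ±35 before
  expit, keeping predictions strictly inside (0, 1) in double precision.

## Reproducibility and problem sizes

Every random draw descends from one root seed (`numpy` `SeedSequence`
substreams), so a scenario run is byte-identical given config + seed. The
test suite and the acceptance script use cohorts of 10,000–200,000 rows:
200,000 for the null-model marginal check, 100,000 for marginal recovery
and truth-calibration checks, 50,000 for coefficient recovery (3-SE
criterion), 60,000 for the acceptance scenario, 1,000 replicates of
n = 2,000 per arm for the type-I-error simulation of the unpaired AUC test
— sizes at which the binomial/SE tolerances in the tests are informative.

## Known limitations

* The surrogate score is not FRAX; absolute AUC/NRI values on synthetic
  cohorts are not comparable to real-data values, only the qualitative
  pattern (hip AUC > MOF AUC; small covariate gains) is designed in.
* The NRI component test assumes independence of movements between
  strata and a normal approximation to the net movement; no bootstrap.
* `raw` calibration mode has no hip-scale score to assess; hip calibration
  is only meaningful under `refit`.
* Follow-up is reduced to (binary event within horizon, censoring time);
  no time-to-event modelling, by design — the evaluated tools output
  fixed-horizon probabilities.
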