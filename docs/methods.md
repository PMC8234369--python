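# Methods

## The prediction model and its update family

The package works with logistic models for a binary endpoint — safe
decannulation, meaning removal of the tracheal cannula without aspiration
or re-cannulation in the following days — evaluated on a cohort of adult
patients with severe acquired brain injury admitted to neurorehabilitation
with a tracheostomy.  The base instrument scores five admission
characteristics as ordinals and combines them linearly on the logit scale.

The canonical component encoding is:

| component | levels → score |
|---|---|
| age band | < 47 → 0, 47–61 → 1 (closed interval), > 61 → 2 |
| saliva aspiration | no → 0, yes → 1 |
| vegetative status | no → 0, yes → 1 |
| cough | neither → 0, voluntary only → 1, reflex only → 2, voluntary and reflex → 3 |
| pathogenesis | anoxia → 0, stroke → 1, other → 2, trauma → 3 |

The regression uses these raw indices; direction of effect is carried by
coefficient signs (the shipped synthetic set has negative age / saliva /
VS and positive cough / pathogenesis coefficients, matching clinical
expectation).  For the human-readable summed score the unfavorable
components are reversed, giving a 0–10 scale.  Any encoding can be
overridden in the coefficient JSON file; the degrees-of-freedom structure
of the closed test (below) presumes one numeric term per component.

Published coefficient values for the original instrument are an input
artifact (JSON: intercept, named slopes, provenance).  The shipped default
is **synthetic** and labelled `true_synthetic`; it is a stand-in for
simulation work, not the published instrument.

## Closed testing update

Four variants are fitted on the validation cohort: the original model
(log-likelihood evaluated at fixed coefficients, 0 free parameters);
calibration-in-the-large (original linear predictor as offset, new
intercept, 1); logistic calibration (new intercept plus one slope
multiplying the original linear predictor, 2); and full revision
(intercept + five component coefficients, 6).  Likelihood-ratio tests of
each simpler variant against the revision have df 6, 5 and 4.  Testing
proceeds in parsimony order at unadjusted alpha (default 0.05,
configurable) and the first non-rejected variant is selected; the revision
is adopted only if all three tests reject.  By construction the chain of
maximized log-likelihoods is monotone, and the test statistic is clipped
at zero (a violation beyond 1e-6 raises, since it can only mean an
optimizer failure).

The calibration slope is applied to the *full* original linear predictor,
intercept included; `slope_on_full_lp=False` rescales only the
intercept-free part.  The two parameterizations span the same model family
and give identical likelihoods; only the reported intercept differs.

Extended refits: the *continuous* model replaces the age band and VS score
with age in years and the CRS-r score (6 free parameters); the *complete*
model adds ICU length of stay in days (7).  Continuous covariates are
standardized internally and reported on their original scales.

## Fitting and the separation fallback

All maximizations are binomial GLM IRLS (statsmodels) run to deviance
tolerance 1e-10, max 200 iterations.  A fit is declared separated when it
fails to converge or any |linear predictor| exceeds 30 (fitted
probabilities within ~1e-13 of 0/1); the default is to fail loudly, since
silently penalized likelihoods would bias LR statistics.  An explicit
`ridge=True` switches to a penalized Newton solver with λ = 1e-6 on the
slopes (intercept unpenalized), reporting the unpenalized log-likelihood
at the penalized optimum.  This is intended for deliberately overfit
regimes (e.g. bootstrap resamples of 7-parameter fits on 80 patients).

## Metric battery

For predictions p and outcomes y (p clipped to [1e-10, 1−1e-10] before any
logit):

- **Brier score**: mean (p − y)².
- **AUC**: pairwise concordance with half credit for ties, computed from
  mid-ranks (identical to the exhaustive pair count, which the test suite
  verifies against a brute-force oracle).
- **Calibration intercept / slope**: slope is the coefficient of logit(p)
  in a logistic regression of y on logit(p); the intercept is fitted with
  logit(p) as a fixed offset (calibration-in-the-large convention; the
  free-intercept alternative from the slope fit is available from the same
  routine's internals).  A freshly refit model scores slope 1, intercept 0
  to optimizer tolerance — its score equations force it — which is why
  apparent slopes are uninformative and optimism correction matters.
- **Calibration curve**: locally weighted linear regression (tricube
  weights, no robustness iterations — robust reweighting is meaningless
  for 0/1 residuals), default span 0.75, evaluated at the observed
  predictions and clipped to [0, 1].  For n > 5000 an interpolation
  spacing of 1% of the prediction range is used (the R `lowess`
  convention), making the smoother effectively linear-time; pass
  `delta=0` for exact local fits.  A 10-group risk-decile summary (mean
  prediction, observed frequency, group size) accompanies the curve for
  plotting.
- **E_max / ICI**: maximum and subject-averaged |p − smooth(p)| over the
  observed prediction range (no trimmed variant; trimming can be applied
  upstream by subsetting).  ICI ≤ E_max by construction.
- **Continuous NRI**: net proportion of events whose risk rises plus net
  proportion of non-events whose risk falls, strict inequalities, ties
  contribute nothing; range −2 to 2.  **IDI**: change in discrimination
  slope (mean risk gap between events and non-events).

## Bootstrap optimism correction

Harrell loop with B resamples (default 500) drawn with replacement at the
original n: refit on the resample, evaluate each metric on the resample
(bootstrap performance) and on the original cohort (test performance);
optimism is their difference, and corrected = apparent − mean optimism
(an exact identity in the report).  Resamples with a single outcome class
are redrawn and counted; more than 10·B attempts raises.  95% CIs are
percentiles of the B bootstrap performances by default;
`ci_method="corrected"` uses the per-resample corrected values instead,
which is the informative choice for metrics whose bootstrap apparent value
is degenerate (the refit calibration slope is identically 1 on every
resample).  Two-model comparisons (NRI, IDI) refit both models on every
resample.  The whole report is a pure function of (cohort, model spec,
metric set, B, seed).  Stratified-by-outcome resampling is available
behind a flag; simple row resampling is the default.

## Synthetic cohort generator

The generator emulates the marginal structure of a post-acute ABI
tracheostomy cohort:

- **Age**: truncated normal, mean 53.01, SD 17.75, bounds [18, 95] years
  (adult inclusion; upper bound a pragmatic cap).  The implied age-band
  frequencies (35.5 / 31.7 / 32.8%) closely match the emulated cohort's
  35.9 / 31.5 / 32.6.
- **ICU length of stay**: log-normal, truncated at the 90-day admission
  cap, with log-scale parameters (3.6144, 0.4326) least-squares matched to
  quartiles 28 / 36 / 49 days (achieved: 27.5 / 36.7 / 48.7).
- **CRS-r**: rounded, range-clipped scaled beta on [0, 23] with shapes
  (0.548, 0.509) quantile-matched to median 11, IQR 5–21.  The beta family
  cannot hit all three targets exactly (achieved rounded quantiles
  4 / 12 / 20); the wide, near-U-shaped spread of the consciousness scale
  is preserved.
- **Categoricals**: exact cohort fractions (e.g. saliva aspiration 82/273,
  vegetative status 105/273, cough 111/46/50/66 over 273), which sum to
  one exactly, unlike the rounded percentages they derive from.
- **Outcome**: Bernoulli from a configurable true logistic model applied
  to each record.  The shipped default is score-based with slopes (−1.12,
  −1.54, −1.68, +1.12, +0.84) — chosen once so that a full refit on a
  273-patient cohort reaches apparent AUC ≈ 0.885, the regime of validated
  decannulation models — and intercept −0.360832, solved exactly for a
  61.5% decannulation rate by enumerating the 192 discrete score cells
  (`calibrate_intercept` exposes this).

Covariates are drawn independently (only marginals are reported for the
emulated population); a Gaussian-copula hook can induce age–CRS-r and
CRS-r–ICU correlation but is off by default, and no consistency is
enforced between the CRS-r value and the vegetative-status flag even
though they are clinically linked.  Five in-study deaths are carried as
screening metadata only (353 screened − 75 excluded − 5 deaths = 273
analyzed); mortality is not simulated.  Randomness is governed by one
seed, split into independent streams for covariates, scenario noise, and
outcomes; identical config + seed reproduces the table bit for bit.

**Miscalibration scenarios** distort the true model before outcomes are
drawn, mapping one-to-one onto the closed-test branches: `intercept_shift`
adds δ to the intercept (repairable by calibration-in-the-large);
`slope_shrinkage` multiplies all slopes by γ (repairable by logistic
calibration — note the true model then lies in the recalibration family
with slope γ and intercept β₀(1−γ) on the full linear predictor);
`coefficient_perturbation` adds independent N(0, σ) noise to each slope,
which generically requires full revision.  The intercept is left
unperturbed in the last scenario precisely so the distortion cannot be
absorbed by the simpler variants.

## What the synthetic studies do and do not show

Passing tests demonstrate the *procedures* behave correctly under known
truths: the closed test keeps a well-calibrated model at the nominal
1 − alpha rate, routes each distortion to the matching branch, extended
fits recover generating coefficients, and the bootstrap detects overfit
optimism.  They do not validate the clinical instrument itself: the
shipped coefficients are synthetic, covariate independence understates
real-world collinearity (age, consciousness, and ICU course are
correlated in practice), and under the default truth the continuous
predictors carry no incremental signal, so NRI/IDI against the kept model
are expectedly negative — the opposite of what a cohort with genuinely
informative CRS-r and ICU-stay effects would show.

## Numerical choices and degenerate inputs

- GLM deviance tolerance 1e-10 keeps both sides of every LR statistic
  tight; the calibration-slope identity holds to 1e-6 comfortably.
- Probabilities clipped at 1e-10 before logits; probability outputs of the
  linear predictor are strictly interior for |logit| ≤ ~36 (double
  precision rounds beyond that).
- Constant predictions: calibration slope raises (undefined); the
  calibration curve degenerates to the outcome mean; AUC is 0.5.
- Single-class outcomes raise everywhere fitting or discrimination is
  involved; bootstrap resamples with a single class are redrawn.
- Decile groups use quantile cuts with duplicate edges dropped, so heavy
  ties can yield fewer than 10 groups; sizes always partition the cohort.
- Problem sizes used in the shipped studies: operating characteristics at
  1000 replicates of n = 1000 (type-I) and 40 replicates of n = 2000–5000
  (routing); parameter recovery at n = 20,000; smoother consistency at
  n = 50,000; overfit-optimism at n = 80 with B = 200; study-scale
  validation at n = 273 with B = 500.

## Known limitations

- The loess grey band of a publication-style calibration plot is not
  produced directly; bootstrap percentiles of the curve would provide it.
- Only the continuous NRI is implemented; threshold-based NRI and
  decision-curve analysis are out of scope.
- The ridge fallback's λ is fixed (1e-6) and intended for rescuing
  degenerate resamples, not as a tuned regularizer.
- `calibrate_intercept` is exact only for score-based true models; models
  with continuous predictors would need Monte Carlo calibration.
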