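# decaval

Updating and internal validation of logistic prediction models for safe
tracheostomy decannulation in severe acquired brain injury (ABI).

## The problem

Patients with severe ABI often arrive at neurorehabilitation with a
tracheal cannula, and deciding early who can be safely decannulated shapes
the whole rehabilitation plan.  The DecaPreT score predicts the probability
of safe decannulation from five admission characteristics — age band,
pathogenesis of the brain lesion, saliva aspiration, cough capability, and
vegetative status — combined in a logistic model

&nbsp;&nbsp;&nbsp;&nbsp;logit P(decannulation) = β₀ + β₁·age + β₂·saliva + β₃·VS + β₄·cough + β₅·pathogenesis

with each component an ordinal score.  Carrying such a model to a new
cohort raises two questions this package answers:

1. **Does the published model need updating?**  The closed testing
   procedure fits four variants — the original coefficients untouched;
   *calibration-in-the-large* (new intercept, original linear predictor as
   offset); *logistic calibration* (new intercept plus one slope on the
   linear predictor); and full *revision* (all six parameters refit) — and
   runs likelihood-ratio tests of each simpler variant against the
   revision (df 6, 5, 4).  The most parsimonious variant the data do not
   reject is selected, so published coefficients survive unless there is
   real evidence against them.
2. **Do richer predictors help?**  A *continuous* model replaces the age
   band and vegetative-status score with age in years and the CRS-r
   consciousness score (0–23), and a *complete* model adds ICU length of
   stay.  All models are compared on Brier score, AUC, calibration
   intercept/slope, the loess-based calibration curve with E_max and the
   integrated calibration index (ICI), and — between models — continuous
   NRI and IDI.  Every metric is optimism-corrected by the Harrell
   bootstrap (default 500 resamples) with percentile 95% CIs.

Because patient-level decannulation cohorts are rarely shareable, the
package includes a synthetic cohort generator whose marginals emulate a
post-acute ABI population (n = 273, age 53 ± 17.8, ICU stay median 36 days
capped at 90, CRS-r median 11, 61.5% decannulated), with miscalibration
scenarios (intercept shift, slope shrinkage, coefficient noise) that
exercise each branch of the closed test with a known right answer.

## Worked example

```python
import decaval as dv

cohort   = dv.generate_cohort(dv.SimulationConfig(seed=11))
original = dv.synthetic_decapret_model()          # labelled true_synthetic

outcome = dv.closed_test_select(cohort, original)
for t in outcome.tests:
    print(f"{t.comparison:40s} df={t.df}  chi2={t.statistic:7.3f}  p={t.p_value:.4f}")
print("selected:", outcome.selected)

report = dv.bootstrap_validate(
    cohort, dv.ModelSpec("complete"), B=500, seed=11,
    comparison=dv.ModelSpec(outcome.selected, original=original),
)
for m in ("brier", "auc", "ici", "nri", "idi"):
    r = report.metrics[m]
    print(f"{m:6s} apparent={r.apparent: .3f} corrected={r.corrected: .3f} "
          f"CI=({r.ci_low:.3f}, {r.ci_high:.3f})")
```

prints

```
revision vs. original                    df=6  chi2=  3.389  p=0.7586
revision vs. calibration_in_the_large    df=5  chi2=  3.140  p=0.6784
revision vs. logistic_calibration        df=4  chi2=  1.985  p=0.7386
selected: original
brier  apparent= 0.157 corrected= 0.167 CI=(0.127, 0.177)
auc    apparent= 0.831 corrected= 0.816 CI=(0.792, 0.889)
ici    apparent= 0.018 corrected= 0.031 CI=(0.005, 0.044)
nri    apparent=-0.628 corrected=-0.680 CI=(-0.871, -0.024)
idi    apparent=-0.073 corrected=-0.089 CI=(-0.110, 0.004)
```

The cohort was generated from the original model itself, and the closed
test correctly keeps it (all three p ≫ 0.05, df 6/5/4).  The seven-predictor
complete model then shows positive AUC optimism (0.831 apparent → 0.816
corrected) and negative NRI/IDI versus the kept model: under this truth the
extra continuous predictors carry no signal, and the bootstrap says so.

A command-line interface wraps the same pipeline:

```bash
decaval simulate -o cohort.csv --seed 3
decaval validate -c run.yaml            # cohort -> closed test -> metrics
decaval report  runs/my-run             # pretty-print a finished run
```

`run.yaml` names the input (synthetic settings or a cohort CSV), the
original-coefficient JSON file, alpha, B, seed, and output directory; the
run writes the cohort summary, the closed-test table, the metric table,
per-model calibration curves with decile summaries, and a manifest that
makes reruns byte-identical.

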