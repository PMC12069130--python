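# retriage

Equity-aware triage of diabetic eye screening intervals.

Since late 2023, people in the English NHS Diabetic Eye Screening Programme
with no detectable retinopathy at two consecutive visits ("low risk", R0M0
twice) are recalled every two years instead of annually. Stretching the
interval saves appointments, but anyone who develops sight-threatening
diabetic retinopathy (STDR — grade R2, R3 or M1 in either eye) during a
skipped year receives a **delayed diagnosis**, and the burden of those delays
falls unevenly across ethnic groups, ages and diabetes durations.

`retriage` implements, as a tested pipeline, the simulation framework used to
study this problem and to evaluate remedies:

* **Protocol replay.** Historical appointment sequences are replayed under
  four recall protocols — *annual* (every appointment kept), *biennial*
  (alternate appointments less than 730 days after the previous seen one are
  "hidden"; background retinopathy R1M0 at a seen visit returns the person to
  annual recall), *risk-model triage* and *points triage* (hide only for
  people below a risk threshold). STDR at a hidden appointment is a delayed
  diagnosis.
* **Risk models.** Mixed-effect logistic regression of STDR within 590 days
  of a *qualifying appointment* (an R0M0 visit directly following an R0M0
  visit), with the person as a random intercept:

  logit P(STDR within 590 d | b_i) = x'β + b_i,  b_i ~ N(0, σ²),

  fitted by marginal maximum likelihood (Gauss–Hermite quadrature).
  Four nested covariate sets: (1) age, diabetes duration, type 1 diabetes,
  prior non-attendance; (2) + ethnicity; (3) set 1 + median HbA1c, SD of
  HbA1c, diastolic BP; (4) set 3 + ethnicity. The triage threshold flags the
  highest 20% of predicted risks.
* **Points protocol.** The ethnicity-aware model is simplified to a
  clinic-usable integer score: per-year age and duration coefficients and
  ethnic-group contrasts divided by a common scale and rounded to integers;
  score ≥ threshold ⇒ annual recall.
* **Equity metrics.** Per-appointment diagnosis rates (per 100,000), delayed
  fractions, appointment reductions, risk ratios of STDR diagnosis per
  appointment for each age/duration/ethnicity subgroup against the
  lowest-risk base group (white, age >40, duration <10 y), and Kaplan–Meier
  curves for time to STDR.
* **Synthetic cohorts.** The source programmes' records are not public, so a
  generator (`retriage.simulate`) emulates their structure — annual visits
  with jitter and non-attendance, ungradable encounters, a covariate-driven
  discrete-time STDR hazard with a person random intercept, and linked
  HbA1c/BP series — and exposes the ground truth for oracle tests.

## Worked example

```python
from retriage import *
from retriage.risk import STDRRiskModel, build_training_table

cohort = generate_cohort(SimConfig(n_people=2000, seed=7))
eligibles = eligible_cohort(cohort)

table = build_training_table(eligibles)
fit = STDRRiskModel.from_training_table(table, covariate_set=2).fit()
fit.calibrate_threshold()
print(fit.summary())
```

```
STDR risk model (covariate set 2)
Random-intercept logistic regression (marginal ML, 51-node Gauss-Hermite)
groups: 2000   rows: 10744   events: 251
log-likelihood: -1162.817
                   coef  std err       z      OR
intercept       -3.8372   0.4802 -7.9905  0.0216
age             -0.0239   0.0052 -4.5731  0.9764
duration         0.0246   0.0114  2.1642  1.0249
type1           -0.3899   0.3028 -1.2874  0.6771
prior_dna       -0.0660   0.1636 -0.4033  0.9362
eth_black        0.8689   0.2413  3.6014  2.3844
eth_south_asian  0.8453   0.2275  3.7159  2.3287
eth_other_asian  0.2585   0.3443  0.7510  1.2950
eth_mixed        0.4487   0.3585  1.2518  1.5663
eth_other        0.6861   0.3276  2.0944  1.9860
random-intercept SD: 1.5281 (var 2.3350)
calibrated probability threshold: 0.015295
```

Risk rises with diabetes duration and is markedly higher for non-white
groups (odds ratios ~1.3–2.4); it falls with age because the generator
concentrates hazard in people aged 40 or under. The threshold 0.0153 flags
the top 20% of appointment-level risks for annual recall.

```python
points = derive_points_table(fit)
calib = calibrate_points_threshold(points, eligibles)
points.threshold = calib.threshold

results = {
    "annual":   run_protocol(eligibles, TriagePolicy(kind="annual")),
    "biennial": run_protocol(eligibles, TriagePolicy(kind="biennial")),
    "points":   run_protocol(eligibles, TriagePolicy(kind="points"), points_table=points),
}
print(aggregate_results(results).round(1).to_string())
```

```
          appointments_seen  pct_appointments  stdr_total  stdr_nondelayed  pct_nondelayed  stdr_delayed  pct_delayed
protocol
annual                11499             100.0         284              284           100.0             0          0.0
biennial               6396              55.6         284              135            47.5           149         52.5
points                 7251              63.1         284              185            65.1            99         34.9
```

Blanket biennial recall saves 44% of appointments but delays 52% of STDR
diagnoses on this cohort; the points protocol recovers a third of those
delays (52% → 35%) while still saving 37% of appointments. A
`retriage` console script exposes the same pipeline
(`retriage simulate / fit / points / run / report`).

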