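# Methods

## The simulation problem

A diabetic eye screening programme grades each attended visit for
retinopathy (R0 none, R1 background, R2 pre-proliferative, R3
proliferative), maculopathy (M0/M1) or U (ungradable). Sight-threatening
diabetic retinopathy (STDR) is R2, R3 or M1 in either eye. A person enters
the low-risk ("biennial") pathway at the second of two consecutive gradable
R0M0 visits, provided at least one further gradable visit exists. Replaying
historical appointment sequences under counterfactual recall protocols
measures what each protocol would have cost (appointments kept) and missed
(STDR arising at a visit the protocol would have skipped — a delayed
diagnosis).

## Eligibility and censoring

Ungradable and non-attended visits carry no usable grade; they are removed
from the analysed appointment sequence before pairing (the next gradable
visit stands in), and excluded from all appointment counts. The original
record is kept alongside, because prior non-attendance is a model covariate.
A person is censored at the first post-entry visit showing *any* degree of
retinopathy — they would have left the biennial pathway there — with the
triggering visit retained since it carries the outcome. No gap-length filter
is applied to eligibility: people are included however reliably they
attended. Because censoring acts on any DR, the return-to-annual rule for
R1M0 (below) matters mainly when histories are replayed uncensored, which
the test suite does to exercise the full state machine.

## Protocol state machines

All four protocols share one machine over the post-entry sequence; the entry
visit is always seen.

* The visit after a hidden visit is always seen (hiding alternates).
* A visit is a hiding candidate only if it falls less than
  `window_hide_days` (default 730) after the previous *seen* visit;
  otherwise it is seen wherever it falls.
* A seen R1M0 switches the person to annual recall (no hiding) until they
  re-qualify with two consecutive seen R0M0 visits (re-entry is on by
  default; the observation that triggers it must be *seen* — R1M0 on a
  hidden visit is invisible to the programme and, by default, does not
  switch modes, though the underlying record still drives censoring).
* Risk and points triage add a decision at each seen qualifying visit (an
  R0M0 whose previous seen visit was R0M0): if the predicted 2-year STDR
  probability (or integer score) is at or above the threshold, the next
  visit is seen whenever it occurs; otherwise biennial hiding applies. Ties
  at the threshold count as high risk, erring toward detection.

Annual recall is the limit "always decide seen"; biennial is "never". These
limits are asserted exactly in tests. A delayed STDR is counted once, at the
hidden visit where it appears.

The outcome window for the *models* is 590 days ("within 2 years of the
last screening appointment"), deliberately distinct from the 730-day hiding
window; both are configuration fields of `TriagePolicy`.

## Risk models

The binary outcome at each qualifying visit is any STDR diagnosis within
the next 590 days. Models are random-intercept logistic regressions fitted
by marginal maximum likelihood: the per-person intercept is integrated out
with Gauss–Hermite quadrature (51 nodes by default; plain quadrature scaled
by σ√2 is accurate to well below 1e-6 at the σ ≤ ~2 seen here — the node
count is configurable for larger variance components). The optimiser is
L-BFGS-B with an analytic score and σ bounded at 0; standard errors come
from the numerically differentiated Hessian, with the σ row dropped when the
estimate sits on the boundary. Perfect separation is detected before
fitting and reported with the offending covariate's name; non-convergence
raises with the optimiser diagnostics rather than returning a bad fit.

Covariates follow four nested sets (age, duration, type 1, prior
non-attendance; + ethnicity; + HbA1c median/SD and diastolic BP; + both).
Age and duration enter in years as continuous terms. Smoking is excluded
(poorly recorded in the source setting); systolic BP is carried in the data
tables but not used by any model. Missing measurement summaries are imputed
with the fixed population medians 51 mmol/mol (HbA1c median), 6.2 mmol/mol
(HbA1c SD), 76 mmHg (diastolic) and 130 mmHg (systolic); a single observed
HbA1c value supplies the median while its SD is imputed. Only values dated
strictly before the reference visit are used.

Fractional-polynomial transforms for continuous covariates are selected by
the conventional closed test over powers {−2, −1, −0.5, 0, 0.5, 1, 2, 3}
(FP2 vs null, FP2 vs linear, FP2 vs FP1, each at 0.05), using plain
logistic deviances for the selection step; the covariate itself is never
dropped because the covariate sets are fixed. Selection is off by default —
on the synthetic cohort the true interval hazard is piecewise-constant in
the covariates and linear terms are retained almost always.

Predictions for triage are population-level (random intercept at zero);
person-level posterior intercepts would leak outcome information from the
training window into the triage decision. The probability threshold is the
lower (type-1) empirical quantile of predicted risks over qualifying rows at
1 − flag_fraction (default 20%), so the flagged share overshoots the target
by at most one row; ties flag as seen.

## Points protocol

The ethnicity-aware model is reduced to an integer score: the per-year age
and duration coefficients and the five ethnic-group contrasts are divided
by a common scale and rounded half-away-from-zero ("nearest integer" does
not fix tie behaviour, so the rule is pinned and serialised). Raw per-year
log-odds round to zero, so the scale matters; the default maps the
smallest-magnitude nonzero included coefficient to ±1 point. Attendance and
diabetes-type terms are dropped — the score uses only age, duration and
ethnicity, the fields a screening service always holds. Age and duration
components may be expressed as step schedules (points per N whole years) to
keep integers small; N is serialised with the table.

The integer threshold is the smallest t flagging at most 20% of people at
pathway entry, reported with the achieved fraction (integer granularity
makes exactly 20% generally unattainable; if no t up to the maximum score
qualifies — all scores equal, say — the maximum is returned with a
warning). The threshold may be negative: when risk falls with age the
per-year age points are negative and scores shift below zero. The published
reference configuration for this protocol family is a threshold of 4
points, which is the serialised default before calibration.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, not any
particular programme's numbers. Per person: demographics drawn from an
ethnically diverse urban mix (15% aged ≤40 at first visit; duration of
diabetes exponential with mean 7 y, populating both <10 y and ≥10 y
strata); roughly annual scheduled visits (365 ± 30 d jitter, 9 scheduled by
default) with 12% non-attendance and 2% ungradable encounters; the first
two gradable visits grade R0M0, putting nearly everyone on the low-risk
pathway, as in the study population. From the third gradable visit onward
each inter-visit interval carries a discrete-time STDR hazard

  logit p = base_logit + 0.69·[duration ≥ 10 y] + 0.90·[age ≤ 40]
            + ethnicity effect + b_i,   b_i ~ N(0, 0.5²),

with base_logit = −4.7 (≈1% per interval, the order observed in low-risk
screening populations) and ethnicity increments 0 (white), 0.85 (black),
0.65 (South Asian), 0.40 (other Asian), 0.75 (mixed), 0.50 (other), chosen
once to reflect the direction and rough size of the disparities reported
for urban English programmes. Covariates are evaluated at the interval
start. Non-events are transient R1M0 with probability 0.05, else R0M0;
events sample an STDR grade (R2M0/R3M0/R1M1) and truncate the history by
default. HbA1c and BP series are person-centred Gaussians around 51
mmol/mol, 130 mmHg and 76 mmHg, roughly annual, each series absent with
probability 0.10.

What the generator does **not** emulate: grade inter-rater noise, mortality
and competing risks, behavioural response to interval changes, seasonal
scheduling, and correlation between measurement levels and the STDR hazard
(HbA1c/BP carry no signal here, so models 3–4 cannot beat model 1 on
synthetic data — tests of those models check machinery, not discrimination).
Passing tests therefore demonstrate correctness of the pipeline under the
stated data-generating process, not clinical performance on real records.

`hazard_intervals` reconstructs the generator's at-risk design rows exactly
(one row per gradable visit after the second, covariates at interval start,
stopping at the first event), giving oracle tables for parameter-recovery
tests without re-using the fitting code under test.

## Numerical and testing choices

Problem sizes were chosen to make the statistical checks sharp while the
whole suite stays quick: the first-interval event-rate check pools 10 seeds
of 2,000 people and compares against the hazard marginalised over the
random intercept by 40-node quadrature, within 3 Monte-Carlo SEs;
parameter recovery fits 5,000 people (≈23k intervals) and requires every
fixed effect within 3 SEs of truth; fractional-polynomial behaviour is
checked over 100 replicates of 400 rows (linear truth retained ≥90% of the
time). Protocol state machines are verified against an independently coded
oracle over every grade/gap combination up to six visits, plus exact limit
equivalences. The marginal likelihood is pinned to brute-force adaptive
quadrature (scipy.integrate.quad) at 1e-6 on tiny instances, and to a plain
statsmodels logit when the random effect degenerates.

Known limitations: plain (non-adaptive) quadrature loses accuracy for
random-effect SDs well above ~2 (raise `n_quad`); risk-ratio confidence
intervals use the log-RR Wald form with a 0.5 continuity correction for
zero-event comparison groups, which is one of several defensible choices;
and the per-appointment diagnosis-rate convention counts every STDR once in
the diagnosed person's subgroup with seen appointments as the denominator —
sums over subgroups therefore reproduce protocol totals by construction.
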