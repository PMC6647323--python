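# Methods

This note documents the statistical model behind `aetrial`, the design
choices made where the design was genuinely open, the numerical
conventions, and what the simulation results do and do not show.

## Survival model and calibration

Event times are exponential.  The control hazard is anchored by the
control-arm survival probability at the follow-up horizon `F`:
`λ_C = −ln S_C(F) / F` (default `S_C(F) = 0.2`).  The experimental hazard
in subgroup `g ∈ {P, N}` is `λ_C · HR_g`, so proportional hazards hold
exactly and the experimental survival at any time is `S_C(t)^{HR_g}`.  The
exponential family is a modelling choice — constant hazards are the
simplest law consistent with a constant hazard ratio — and all hazard-ratio
scenarios share the same control calibration.  There is no loss to
follow-up and no cure fraction: every patient eventually has an event, and
censoring is purely administrative (a data cut, or the curtailment of
negative-subgroup follow-up on enrichment).

`F` is a *calibration horizon*, not a per-patient censoring time, for the
adaptive designs: patients are followed until the relevant data cut, which
is event-driven.  This choice makes prolonged trial periods possible — the
phenomenon the recruitment strategies are designed to mitigate — and is
what produces the longer durations seen under back-loaded accrual.

## Patient streams

A replicate draws `TSS` prospective patients (default 330).  Arrival times
are inverse-CDF samples from a uniform or truncated-exponential accrual law
on `[0, R]`; the truncated-exponential quantile is computed with
`expm1`/`log1p` and is stable down to `|γ| ≈ 1e-12`, converging to the
uniform quantile as `γ → 0`.

Biomarker status uses *deterministic interleaving* by default: patient `i`
(0-based) is positive iff `ceil((i+1)p) − ceil(ip) = 1`, which places
exactly `ceil(kp)` positives in every length-`k` prefix.  At 50% prevalence
the 165-patient stage-1 cohort therefore holds exactly 83 positives and the
remaining pool 82 — these integer extremes (165, 247 = 165+82, 83) are
structural constants of the design, and an iid Bernoulli assignment
(available as `biomarker_mode="bernoulli"`) would blur them.  Treatment
allocation is 1:1 in permuted blocks of two within each biomarker stratum
(exact balance); simple randomisation is available.

One master seed drives a `SeedSequence` tree: each replicate gets an
independent child stream, and the *same* patient stream is reused by every
recruitment strategy within a replicate (common random numbers), so
strategy comparisons are paired.

## Trial timeline

Stage 1 recruits the first `round(TSS · f)` arrivals, where `f` is the
interim fraction (at the default `f = 0.5`, exactly `TSS/2 = 165`).  Tying
the stage-1 cohort to the interim timing keeps the interim event target
`round(f · 270)` always reachable within the cohort (a 75%-information
interim needs 203 events, which a fixed 165-patient cohort could never
produce).

The interim data cut falls at the `round(f · 270)`-th event *within the
stage-1 cohort*; restricting the event clock to that cohort keeps the
stage-wise p-values cleanly separated by recruitment stage.  Interim Cox
hazard-ratio estimates for `O` and `P` are compared with thresholds
(`η = 1.00` by default); the decision takes effect after the interim
decision period (0.2 time units).  A hazard ratio exactly at its threshold
counts as "not beneficial" — a measure-zero tie-break that makes the
decision rule total.

Stage-2 enrollment then follows the strategy (halted-and-shifted, continued
from `O`, or continued from `P`; see the package docstrings).  Arrivals
deferred by the halt keep their inter-arrival gaps — the accrual process is
frozen, not discarded.  Patients arriving during the waiting window join
the *stage-2* cohort, so their data enter only the stage-2 p-value and the
stage-wise independence of the combination test is preserved.  Under
`continued_P`, negative arrivals in the window are skipped and never
replaced: the screening pool is fixed at `TSS` prospective arrivals.

The final data cut is event-driven: the 270th event among enrolled patients
on the continue-O path, or — after enrichment, when the negative subgroup
has been censored and the 270-event target is no longer meaningful — the
`round(270 · prevalence) = 135`-th event among enrolled positives, the
prevalence-scaled target consistent with the equal-information weighting of
the combination test.  If the enrolled pool can never reach its target
(possible under `continued_P` with a continue-O decision, since skipped
negatives shrink the pool), the cut falls at the last reachable event and
the replicate is flagged.  Stage-1 p-values at the final analysis use
stage-1 *cohort* data accumulated through the final cut — a patient
recruited in stage 1 whose event occurs in stage 2 is stage-1 data.

## Confirmatory testing

Stage-wise one-sided log-rank p-values (`p = 1 − Φ(Z)`, `Z > 0` favouring
the experimental arm) feed the weighted inverse-normal combination test
with design-time weights `w_k = √(I_k/ΣI_j)` from the planned stage-wise
event counts (equal at the default 50% interim: `w = √0.5`); weights are
never re-estimated from observed events.  Multiplicity over `H₀^O` and
`H₀^P` uses the closure principle with the Hochberg intersection p-value.
On the enrichment path stage 2 contributes positive-subgroup data only, the
intersection test becomes `C(p₁^{O,P}, p₂^P)`, and `H₀^O` can no longer be
rejected.  The rejection rule is applied on the statistic scale
(`C > Φ⁻¹(1−α)`); the p-value transform `1 − Φ(C) < α` is exposed and is
decision-identical.

Numerical conventions: p-values are clipped to `[1e−15, 1−1e−15]` before
`Φ⁻¹` (with a warning); the two-sample Cox estimate is a damped Newton
iteration on the Efron-adjusted partial likelihood, capped at `HR = 10³`
(or its reciprocal) under a monotone likelihood; a stage with no events or
a single arm contributes the noninformative p-value 0.5; all patient and
event targets use round-half-up.

## The non-enriched comparator

The comparator is a group-sequential design with early termination for
futility only: recruitment never halts, one interim look at the interim
event count stops the trial iff `HR_O ≥ η_O` (no decision lag — its
recruitment is never waiting on the decision), and otherwise the final
analysis is a single one-sided log-rank test on `O` at level α at the
*fixed calendar horizon* `R + F`, the design's planned duration.  A fixed
horizon (rather than a 270-event trigger) is what makes `R + F` the
comparator's reference duration across scenarios, including strong-effect
scenarios where 270 events would not have accrued by `R + F`; the expected
patient count falls below `TSS` exactly when futility stops occur.

## Operating characteristics

Per grid cell (scenario × (R,F) × accrual × interim fraction × strategy)
the runner reports mean/min/max enrolled counts in `O` and `P`, mean and
quartiles of the total trial period, interim-decision probabilities,
rejection probabilities, and the bias and RMSE of
`log(HR_P^interim) − log(HR_P^true)` — the interim-accuracy metric of the
timing study.

Default problem sizes: 1000 replicates per cell for study-style runs, 2000
for the error-control and extreme-count checks in the test suite, 4000 for
the minimum-enrollment headline (its futility path has probability ≈ 0.3%
in Scenario 5 and must be visited reliably), and 200–500 for purely
directional checks.  The integer extremes and the directional contrasts
are stable at these sizes; distribution shapes (boxplot whiskers, outlier
sets) stabilise only at much larger replicate counts and are not a target.

## What the simulations do and do not show

The generator emulates the *study conditions*: exponential event times,
exact 50% prevalence, perfectly observed biomarker status, instantaneous
randomisation, no dropout, hazard ratios constant over time and across
stages.  Passing tests therefore demonstrate the scheduling and
error-control properties of the design machinery under those idealised
conditions; they do not speak to non-proportional hazards, biomarker
misclassification, operational bias after an interim decision, or
accrual rates that react to enrichment — all outside the model.

Known limitations:

- Under `continued_P` with a continue-O decision the fixed screening pool
  means the 270-event target is met from a smaller enrolled cohort, so the
  trial can run slightly *longer* than under the typical strategy; the
  continued-from-`O` strategy is the one that shortens the trial in every
  decision path.  Replacing skipped negatives is deliberately out of scope.
- The comparator's fixed `R + F` horizon means its final analysis may occur
  with fewer than 270 events under strong treatment effects; its power is
  correspondingly conservative relative to an event-driven reading.
- Interim fractions other than 0.5 rescale the stage-1 cohort (see above);
  the combination weights follow the planned information split, so designs
  with very asymmetric stages lean heavily on one stage's data.
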