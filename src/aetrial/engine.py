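"""Calendar-time orchestration of a single trial replicate.

The engine walks one replicate through the trial timeline: stage-1
enrollment, the event-driven interim data cut, the interim decision after
the decision period, strategy-dependent stage-2 enrollment, the final data
cut, and the closed-testing decision.  All analysis data cuts are
administrative: a patient event-free at a cut contributes censored
time-on-study up to that cut, and no information beyond a cut influences
statistics computed at it.

The non-enriched comparator is a group-sequential design with early
termination for futility only: recruitment never halts, one interim look is
taken at the interim event count, and - absent a futility stop - the final
analysis is a single one-sided log-rank test on the overall population at a
fixed calendar horizon of R + F (recruitment plus follow-up period), the
design's reference duration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import analysis
from .analysis import (
    CombinationWeights,
    FinalDecision,
    InterimResult,
    StageData,
    closed_testing_decision,
    estimate_hazard_ratio,
    one_sided_logrank_p,
)
from .population import AccrualPattern, PatientStream, SurvivalModel, generate_patient_stream
from .recruitment import (
    Decision,
    EnrollmentLog,
    Strategy,
    StrategySpec,
    apply_strategy,
    censor_negatives_on_enrichment,
)

__all__ = ["TrialDesign", "TrialResult", "interim_trigger_time",
           "final_trigger_time", "run_trial", "simulate_interim"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TrialDesign:
    """All design constants of the adaptive enrichment trial.

    Parameters
    ----------
    recruitment_period, follow_up : float
        Planned recruitment duration R and follow-up duration F (the
        follow-up horizon anchors the 20% control survival calibration and,
        for the non-enriched comparator, the fixed trial duration R + F).
    hr_positive, hr_negative : float
        True hazard ratios used for data generation in the two subgroups.
    tss : int
        Planned total sample size of the overall population.
    total_events : int
        Event target triggering the final analysis on the continue-O path.
    interim_fraction : float
        Fraction of ``total_events`` at which the interim data cut occurs.
    alpha : float
        One-sided significance level of the confirmatory analysis.
    eta_O, eta_P : float
        Interim hazard-ratio thresholds.
    decision_period : float
        Calendar lag between the interim cut and the decision enactment.
    prevalence : float
        Biomarker-positive fraction of the overall population.
    """

    recruitment_period: float
    follow_up: float
    hr_positive: float = 0.5
    hr_negative: float = 0.5
    tss: int = 330
    total_events: int = 270
    interim_fraction: float = 0.5
    alpha: float = 0.025
    eta_O: float = 1.0
    eta_P: float = 1.0
    decision_period: float = 0.2
    prevalence: float = 0.5
    control_survival_at_F: float = 0.2
    biomarker_mode: str = "deterministic"
    allocation: str = "blocked"

    def __post_init__(self) -> None:
        if not 0.0 < self.interim_fraction < 1.0:
            raise ValueError("interim_fraction must lie in (0, 1)")
        if self.total_events > self.tss:
            raise ValueError("total_events cannot exceed the total sample size")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")

    @property
    def stage1_target(self) -> int:
        """Stage-1 recruitment target, scaled with the interim timing.

        At the default interim fraction of one half this is exactly half
        the planned sample size; an earlier (later) interim pairs with a
        smaller (larger) stage-1 cohort so the interim event count is
        always reachable within the cohort.
        """
        return _round_half_up(self.tss * self.interim_fraction)

    @property
    def interim_events(self) -> int:
        return _round_half_up(self.interim_fraction * self.total_events)

    @property
    def positive_event_target(self) -> int:
        """Final event target in P after enrichment (prevalence-scaled)."""
        return _round_half_up(self.total_events * self.prevalence)

    @property
    def survival_model(self) -> SurvivalModel:
        return SurvivalModel(
            follow_up=self.follow_up,
            hr_positive=self.hr_positive,
            hr_negative=self.hr_negative,
            control_survival_at_F=self.control_survival_at_F,
        )

    @property
    def combination_weights(self) -> CombinationWeights:
        """Design-time weights from planned stage-wise information levels."""
        i1 = self.interim_events
        return CombinationWeights.from_planned_events(i1, self.total_events - i1)

    def strategy_spec(self, strategy: Strategy | str) -> StrategySpec:
        return StrategySpec(
            name=Strategy(strategy),
            stage1_target=self.stage1_target,
            decision_period=self.decision_period,
        )

    def make_stream(self, pattern: AccrualPattern,
                    rng: np.random.Generator | int | None) -> PatientStream:
        return generate_patient_stream(
            self.tss,
            self.survival_model,
            pattern,
            rng,
            prevalence=self.prevalence,
            biomarker_mode=self.biomarker_mode,
            allocation=self.allocation,
        )

    def with_scenario(self, scenario: int) -> "TrialDesign":
        from .population import SCENARIO_HAZARD_RATIOS

        hr_p, hr_n = SCENARIO_HAZARD_RATIOS[scenario]
        return replace(self, hr_positive=hr_p, hr_negative=hr_n)


@dataclass(frozen=True)
class TrialResult:
    """Per-replicate trial outputs."""

    n_enrolled_O: int
    n_enrolled_P: int
    total_period: float
    interim_decision: Decision
    rejected_O: bool
    rejected_P: bool
    interim_hr_O: float
    interim_hr_P: float
    interim_time: float
    decision_time: float
    final_time: float
    strategy: Strategy
    final_target_truncated: bool = False


def interim_trigger_time(event_times: np.ndarray, target_events: int) -> float:
    """Earliest calendar time at which ``target_events`` events have occurred.

    ``event_times`` are the calendar event times (enrollment + latent time)
    of the cohort whose events drive the trigger.
    """
    if target_events < 1:
        raise ValueError("target_events must be at least 1")
    if target_events > event_times.size:
        raise ValueError(
            f"cohort of {event_times.size} patients can never reach "
            f"{target_events} events"
        )
    return float(np.partition(event_times, target_events - 1)[target_events - 1])


def final_trigger_time(event_times: np.ndarray, target_events: int) -> tuple[float, bool]:
    """Final-analysis data-cut time, with a truncation fallback.

    Returns ``(time, truncated)``; when the enrolled pool can never produce
    ``target_events`` events the cut falls at the last reachable event and
    ``truncated`` is True (a warning is emitted).
    """
    if target_events <= event_times.size:
        return interim_trigger_time(event_times, target_events), False
    warnings.warn(
        f"final event target {target_events} unreachable with "
        f"{event_times.size} enrolled patients; analysing at the last event",
        RuntimeWarning,
        stacklevel=2,
    )
    return float(event_times.max()), True


def _stage_data(
    stream: PatientStream,
    log: EnrollmentLog,
    mask: np.ndarray,
    cut_time: float,
) -> StageData:
    """Administratively censored survival records for ``mask`` at a cut."""
    enrol = log.enrollment_time[mask]
    event_cal = enrol + stream.latent_event_time[mask]
    cens_cal = np.minimum(log.censoring_time[mask], cut_time)
    time = np.minimum(event_cal, cens_cal) - enrol
    event = event_cal <= cens_cal
    return StageData(time=np.maximum(time, 0.0), event=event, arm=stream.arm[mask])


def _safe_logrank_p(data: StageData) -> float:
    """One-sided log-rank p, falling back to 0.5 on degenerate data.

    A stage with no events or a single arm carries no comparative
    information; its p-value is set to the noninformative 0.5 so the
    combination test relies on the informative stage alone.
    """
    try:
        return one_sided_logrank_p(data)
    except ValueError:
        return 0.5


def simulate_interim(design: TrialDesign, stream: PatientStream) -> tuple[InterimResult, float]:
    """Interim analysis of the stage-1 cohort.

    The interim data cut falls when the interim event count is reached in
    the stage-1 cohort (the first ``stage1_target`` arrivals).  Returns the
    interim result and the cut time.
    """
    k = design.stage1_target
    arrivals = stream.arrival_time[:k]
    event_cal = arrivals + stream.latent_event_time[:k]
    t_cut = interim_trigger_time(event_cal, design.interim_events)

    in_view = arrivals <= t_cut
    time = np.minimum(event_cal[in_view], t_cut) - arrivals[in_view]
    event = event_cal[in_view] <= t_cut
    data_O = StageData(time=time, event=event, arm=stream.arm[:k][in_view])
    pos = stream.biomarker[:k][in_view]

    hr_O = estimate_hazard_ratio(data_O)
    hr_P = estimate_hazard_ratio(data_O.subset(pos))
    decision = analysis.interim_decision(hr_O, hr_P, design.eta_O, design.eta_P)
    return (
        InterimResult(hr_O=hr_O, hr_P=hr_P, eta_O=design.eta_O,
                      eta_P=design.eta_P, decision=decision),
        t_cut,
    )


def run_trial(
    design: TrialDesign,
    stream: PatientStream,
    strategy: Strategy | str,
    interim: tuple[InterimResult, float] | None = None,
) -> TrialResult:
    """Execute one trial replicate under a recruitment strategy.

    Parameters
    ----------
    design : TrialDesign
    stream : PatientStream
        Prospective patients; must hold exactly ``design.tss`` patients.
    strategy : Strategy or str
    interim : optional
        Pre-computed ``(InterimResult, cut_time)`` from
        :func:`simulate_interim`, reusable across strategies that share the
        stream (the interim is strategy-independent for the adaptive
        designs).
    """
    strategy = Strategy(strategy)
    if stream.n != design.tss:
        raise ValueError(f"stream holds {stream.n} patients, design plans {design.tss}")
    if strategy is Strategy.NON_ENRICHED:
        return _run_comparator(design, stream)

    if interim is None:
        interim = simulate_interim(design, stream)
    interim_result, t_cut = interim
    decision = interim_result.decision
    t_dec = t_cut + design.decision_period

    spec = design.strategy_spec(strategy)
    log = apply_strategy(stream, spec, t_cut, decision, t_dec)
    if decision is Decision.ENRICH_P:
        log = censor_negatives_on_enrichment(log, stream, decision, t_dec)

    truncated = False
    if decision is Decision.FUTILITY:
        t_fin = t_dec
        final = FinalDecision(False, False, design.alpha, {"path": decision.value})
    else:
        event_cal = log.enrollment_time + stream.latent_event_time
        if decision is Decision.CONTINUE_O:
            pool = log.enrolled
            target = design.total_events
        else:  # enrichment: positive-subgroup events drive the final cut
            pool = log.enrolled & stream.biomarker
            target = design.positive_event_target
        t_fin, truncated = final_trigger_time(event_cal[pool], target)

        # patients who would enroll only after the final cut never enter
        drop = log.enrolled & (log.enrollment_time > t_fin)
        if np.any(drop):
            log.enrolled[drop] = False
            log.cohort[drop] = 0

        s1 = log.enrolled & (log.cohort == 1)
        s2 = log.enrolled & (log.cohort == 2)
        d1 = _stage_data(stream, log, s1, t_fin)
        p1_O = _safe_logrank_p(d1)
        p1_P = _safe_logrank_p(d1.subset(stream.biomarker[s1]))
        if decision is Decision.CONTINUE_O:
            d2 = _stage_data(stream, log, s2, t_fin)
            p2_O = _safe_logrank_p(d2)
            p2_P = _safe_logrank_p(d2.subset(stream.biomarker[s2]))
            final = closed_testing_decision(
                decision, design.combination_weights, design.alpha,
                p1_O=p1_O, p1_P=p1_P, p2_O=p2_O, p2_P=p2_P,
            )
        else:
            d2 = _stage_data(stream, log, s2, t_fin)
            p2_P = _safe_logrank_p(d2)
            final = closed_testing_decision(
                decision, design.combination_weights, design.alpha,
                p1_O=p1_O, p1_P=p1_P, p2_P=p2_P,
            )

    return TrialResult(
        n_enrolled_O=log.n_enrolled,
        n_enrolled_P=int(np.count_nonzero(log.enrolled & stream.biomarker)),
        total_period=t_fin,
        interim_decision=decision,
        rejected_O=final.rejected_O,
        rejected_P=final.rejected_P,
        interim_hr_O=interim_result.hr_O,
        interim_hr_P=interim_result.hr_P,
        interim_time=t_cut,
        decision_time=t_dec,
        final_time=t_fin,
        strategy=strategy,
        final_target_truncated=truncated,
    )


def _run_comparator(design: TrialDesign, stream: PatientStream) -> TrialResult:
    """Non-enriched group-sequential comparator with futility stop only."""
    event_cal = stream.arrival_time + stream.latent_event_time
    t_cut = interim_trigger_time(event_cal, design.interim_events)

    in_view = stream.arrival_time <= t_cut
    time = np.minimum(event_cal[in_view], t_cut) - stream.arrival_time[in_view]
    event = event_cal[in_view] <= t_cut
    data_int = StageData(time=time, event=event, arm=stream.arm[in_view])
    hr_O = estimate_hazard_ratio(data_int)
    pos_int = stream.biomarker[in_view]
    hr_P = estimate_hazard_ratio(data_int.subset(pos_int))

    if hr_O >= design.eta_O:  # futility stop; no decision lag, no tests
        n_enr = int(np.count_nonzero(in_view))
        n_pos = int(np.count_nonzero(stream.biomarker & in_view))
        return TrialResult(
            n_enrolled_O=n_enr, n_enrolled_P=n_pos, total_period=t_cut,
            interim_decision=Decision.FUTILITY, rejected_O=False, rejected_P=False,
            interim_hr_O=hr_O, interim_hr_P=hr_P, interim_time=t_cut,
            decision_time=t_cut, final_time=t_cut,
            strategy=Strategy.NON_ENRICHED,
        )

    t_fin = design.recruitment_period + design.follow_up
    time = np.minimum(event_cal, t_fin) - stream.arrival_time
    event = event_cal <= t_fin
    data_fin = StageData(time=np.maximum(time, 0.0), event=event, arm=stream.arm)
    p_O = _safe_logrank_p(data_fin)
    return TrialResult(
        n_enrolled_O=stream.n,
        n_enrolled_P=int(np.count_nonzero(stream.biomarker)),
        total_period=t_fin,
        interim_decision=Decision.CONTINUE_O,
        rejected_O=bool(p_O < design.alpha),
        rejected_P=False,
        interim_hr_O=hr_O,
        interim_hr_P=hr_P,
        interim_time=t_cut,
        decision_time=t_cut,
        final_time=t_fin,
        strategy=Strategy.NON_ENRICHED,
    )
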