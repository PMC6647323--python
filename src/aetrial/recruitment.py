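"""Enrollment logic of the patient recruitment strategies.

A two-stage adaptive enrichment trial recruits a stage-1 cohort of half the
planned sample size, then waits for the interim analysis and its decision.
Three strategies differ in what happens to prospective patients arriving
between the end of stage-1 recruitment and the enactment of the interim
decision (the "waiting window"):

``typical``
    Recruitment halts.  Arrivals during the halt are deferred: their
    enrollment times are shifted forward by the halt duration, preserving
    inter-arrival gaps (a frozen accrual process), and they enroll only if
    the decision keeps their subgroup in the trial.
``continued_O``
    Recruitment continues from the overall population throughout the window;
    window enrollees stay enrolled whatever the decision.
``continued_P``
    Only biomarker-positive arrivals enroll from the end of stage-1
    recruitment onward; negative arrivals in the window are permanently
    skipped (not replaced), anticipating enrichment.
``non_enriched``
    Comparator group-sequential design: a single uninterrupted recruitment
    phase with no adaptation (handled mostly by the trial engine).

After the decision: continue-O admits every remaining arrival, enrichment
admits biomarker-positive arrivals only, and futility stops enrollment.  On
enrichment, biomarker-negative patients already enrolled have their
follow-up curtailed at the decision time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import PatientStream

__all__ = [
    "Strategy",
    "Decision",
    "StrategySpec",
    "EnrollmentLog",
    "apply_strategy",
    "censor_negatives_on_enrichment",
]


class Strategy(str, enum.Enum):
    """Patient recruitment strategy."""

    TYPICAL = "typical"
    CONTINUED_O = "continued_O"
    CONTINUED_P = "continued_P"
    NON_ENRICHED = "non_enriched"


class Decision(str, enum.Enum):
    """Interim decision on the trial population."""

    FUTILITY = "futility"
    CONTINUE_O = "continue_O"
    ENRICH_P = "enrich_P"


@dataclass(frozen=True)
class StrategySpec:
    """A recruitment strategy with its design constants.

    ``stage1_target`` is the stage-1 cohort size (half the planned total
    sample size); ``decision_period`` is the calendar lag between the
    interim data cut and the enactment of the decision.
    """

    name: Strategy
    stage1_target: int
    decision_period: float = 0.2

    def __post_init__(self) -> None:
        if self.stage1_target < 1:
            raise ValueError("stage1_target must be at least 1")
        if self.decision_period < 0:
            raise ValueError("decision_period must be non-negative")


@dataclass
class EnrollmentLog:
    """Per-patient enrollment outcome, aligned with the patient stream.

    ``cohort`` is 1 for stage-1 patients, 2 for stage-2 patients and 0 for
    patients never enrolled.  ``censoring_time`` is the calendar time at
    which follow-up is administratively curtailed (+inf when open).
    """

    enrolled: np.ndarray
    enrollment_time: np.ndarray
    cohort: np.ndarray
    censoring_time: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.enrolled)
        if not (len(self.enrollment_time) == len(self.cohort) == len(self.censoring_time) == n):
            raise ValueError("EnrollmentLog arrays must have equal length")

    @property
    def n_enrolled(self) -> int:
        return int(np.count_nonzero(self.enrolled))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self.enrolled)),
                "enrolled": self.enrolled,
                "enrollment_time": self.enrollment_time,
                "cohort": self.cohort,
                "censoring_time": self.censoring_time,
            }
        )


def apply_strategy(
    stream: PatientStream,
    spec: StrategySpec,
    interim_cut_time: float,
    decision: Decision,
    decision_time: float,
) -> EnrollmentLog:
    """Map prospective arrivals to enrolled patients under a strategy.

    The first ``spec.stage1_target`` arrivals always form the stage-1
    cohort, enrolled at their arrival times.  Later arrivals are handled
    per the strategy during the waiting window (end of stage-1 recruitment
    to ``decision_time``) and per the interim decision afterwards.

    Parameters
    ----------
    stream : PatientStream
        All prospective patients, sorted by arrival.
    spec : StrategySpec
        Strategy and design constants.
    interim_cut_time : float
        Calendar time of the interim data cut.
    decision : Decision
        The interim decision to enact at ``decision_time``.
    decision_time : float
        Calendar time the decision takes effect (cut time + decision period).
    """
    if stream.n < spec.stage1_target:
        raise ValueError(
            f"stream of {stream.n} patients is shorter than the stage-1 "
            f"target {spec.stage1_target}"
        )
    if decision_time < interim_cut_time:
        raise ValueError("decision_time must not precede interim_cut_time")

    n = stream.n
    k = spec.stage1_target
    arrival = stream.arrival_time
    positive = stream.biomarker

    enrolled = np.zeros(n, dtype=bool)
    enrollment_time = np.full(n, np.nan)
    cohort = np.zeros(n, dtype=np.int8)
    censoring = np.full(n, np.inf)

    # stage-1 cohort: the first k arrivals, in every strategy
    enrolled[:k] = True
    enrollment_time[:k] = arrival[:k]
    cohort[:k] = 1
    stage1_end = arrival[k - 1]

    rest = np.arange(k, n)
    if rest.size == 0:
        return EnrollmentLog(enrolled, enrollment_time, cohort, censoring)

    if spec.name is Strategy.NON_ENRICHED:
        # single uninterrupted phase, no adaptation
        enrolled[rest] = True
        enrollment_time[rest] = arrival[rest]
        cohort[rest] = 2
        return EnrollmentLog(enrolled, enrollment_time, cohort, censoring)

    admit_after = _admitted_by_decision(decision, positive)

    if spec.name is Strategy.TYPICAL:
        # frozen accrual: remaining arrivals shift forward by the halt length
        shift = max(decision_time - stage1_end, 0.0)
        take = rest[admit_after[rest]]
        enrolled[take] = True
        enrollment_time[take] = arrival[take] + shift
        cohort[take] = 2
    elif spec.name is Strategy.CONTINUED_O:
        in_window = arrival[rest] <= decision_time
        take = rest[in_window | admit_after[rest]]
        enrolled[take] = True
        enrollment_time[take] = arrival[take]
        cohort[take] = 2
    elif spec.name is Strategy.CONTINUED_P:
        in_window = arrival[rest] <= decision_time
        window_take = in_window & positive[rest]
        post_take = ~in_window & admit_after[rest]
        take = rest[window_take | post_take]
        enrolled[take] = True
        enrollment_time[take] = arrival[take]
        cohort[take] = 2
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown strategy {spec.name!r}")

    return EnrollmentLog(enrolled, enrollment_time, cohort, censoring)


def _admitted_by_decision(decision: Decision, positive: np.ndarray) -> np.ndarray:
    """Eligibility mask for arrivals after the decision takes effect."""
    if decision is Decision.CONTINUE_O:
        return np.ones(len(positive), dtype=bool)
    if decision is Decision.ENRICH_P:
        return positive.copy()
    if decision is Decision.FUTILITY:
        return np.zeros(len(positive), dtype=bool)
    raise ValueError(f"unknown decision {decision!r}")


def censor_negatives_on_enrichment(
    log: EnrollmentLog,
    stream: PatientStream,
    decision: Decision,
    decision_time: float,
) -> EnrollmentLog:
    """Curtail follow-up of enrolled biomarker-negative patients.

    On enrichment the negative subgroup leaves the trial: every enrolled
    negative patient is administratively censored at the decision time.
    An event observed before the decision time is unaffected (censoring
    cannot undo an observed event; the trial engine compares calendar event
    times against the censoring time).

    Raises
    ------
    ValueError
        If called with a decision other than enrichment.
    """
    if decision is not Decision.ENRICH_P:
        raise ValueError("negative-subgroup censoring applies only on enrichment")
    censoring = log.censoring_time.copy()
    hit = log.enrolled & ~stream.biomarker
    censoring[hit] = np.minimum(censoring[hit], decision_time)
    return EnrollmentLog(
        enrolled=log.enrolled.copy(),
        enrollment_time=log.enrollment_time.copy(),
        cohort=log.cohort.copy(),
        censoring_time=censoring,
    )
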