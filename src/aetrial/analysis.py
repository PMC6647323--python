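"""Stage-wise survival statistics and confirmatory testing machinery.

The final analysis of the two-stage adaptive enrichment design combines
independent stage-wise one-sided p-values with the weighted inverse-normal
combination statistic

    C(p1, p2) = w1 * Phi^{-1}(1 - p1) + w2 * Phi^{-1}(1 - p2),

rejecting when C exceeds ``Phi^{-1}(1 - alpha)`` (equivalently, when the
combined p-value ``1 - Phi(C)`` falls below alpha).  Multiplicity over the
overall population O and the biomarker-positive subgroup P is controlled by
the closure principle with the Hochberg intersection p-value

    p^{O,P} = min[2 * min(p^O, p^P), max(p^O, p^P)].

Stage-wise p-values come from the one-sided log-rank test; interim decisions
use Cox partial-likelihood hazard-ratio estimates compared against
pre-specified thresholds.  The log-rank statistic and the two-sample Cox
estimate are implemented here as vectorised primitives over risk-set count
tables (Efron handling for tied event times) so that Monte-Carlo studies
with tens of thousands of fits remain fast.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .recruitment import Decision

__all__ = [
    "StageData",
    "CombinationWeights",
    "InterimResult",
    "FinalDecision",
    "one_sided_logrank_p",
    "logrank_z",
    "estimate_hazard_ratio",
    "interim_decision",
    "combination_statistic",
    "combination_pvalue",
    "hochberg_intersection_p",
    "closed_testing_decision",
]

#: Open-interval clipping bounds keeping Phi^{-1} finite.
P_CLIP = (1e-15, 1.0 - 1e-15)

#: Cap on the hazard-ratio estimate under a monotone partial likelihood.
HR_CAP = 1e3


@dataclass
class StageData:
    """Survival records for one cohort/population slice.

    ``time`` is time-on-study from randomisation to event or censoring,
    ``event`` flags observed events, ``arm`` is True for the experimental
    arm.
    """

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        self.arm = np.asarray(self.arm, dtype=bool)
        if not (len(self.time) == len(self.event) == len(self.arm)):
            raise ValueError("StageData arrays must have equal length")
        if np.any(self.time < 0):
            raise ValueError("time-on-study must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, mask: np.ndarray) -> "StageData":
        return StageData(self.time[mask], self.event[mask], self.arm[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event.astype(int), "arm": self.arm.astype(int)}
        )


def _risk_table(data: StageData):
    """Risk-set counts at each distinct event time.

    Returns arrays over the distinct event times (ascending): deaths in the
    experimental arm ``d1``, total deaths ``d``, and at-risk counts ``n1``
    (experimental) and ``n0`` (control).
    """
    et = data.time[data.event]
    if et.size == 0:
        raise ValueError("no events in the data; test undefined")
    eg = data.arm[data.event]
    ut, inv = np.unique(et, return_inverse=True)
    d = np.bincount(inv).astype(float)
    d1 = np.bincount(inv, weights=eg.astype(float))
    t1 = np.sort(data.time[data.arm])
    t0 = np.sort(data.time[~data.arm])
    if t1.size == 0 or t0.size == 0:
        raise ValueError("both arms must be present; test undefined")
    n1 = t1.size - np.searchsorted(t1, ut, side="left")
    n0 = t0.size - np.searchsorted(t0, ut, side="left")
    return ut, d1, d, n1.astype(float), n0.astype(float)


def logrank_z(data: StageData) -> float:
    """Standardised log-rank statistic, positive when E outperforms C.

    ``Z = (E1 - O1) / sqrt(V)`` with ``O1`` the observed and ``E1`` the
    expected experimental-arm events under the null, so fewer events than
    expected in the experimental arm push Z above zero.
    """
    _, d1, d, n1, n0 = _risk_table(data)
    n = n1 + n0
    e1 = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * (n1 / n) * (n0 / n) * (n - d) / np.where(n > 1, n - 1, np.inf)
    var = float(np.sum(v))
    if var <= 0.0:
        raise ValueError("log-rank variance is zero; test undefined")
    return float((np.sum(e1) - np.sum(d1)) / np.sqrt(var))


def one_sided_logrank_p(data: StageData) -> float:
    """One-sided log-rank p-value, small when the experimental arm wins.

    ``p = 1 - Phi(Z)`` with Z oriented so positive values favour the
    experimental arm.
    """
    return float(ndtr(-logrank_z(data)))


def _efron_terms(beta: float, d1, d, n1, n0, max_d: int):
    """Efron-adjusted score and information contributions at one beta."""
    eb = np.exp(beta)
    d0 = d - d1
    score = float(np.sum(d1))
    info = 0.0
    for ell in range(max_d):
        live = d > ell
        frac = ell / d[live]
        a = (n1[live] - frac * d1[live]) * eb
        r = a + (n0[live] - frac * d0[live])
        q = a / r
        score -= float(np.sum(q))
        info += float(np.sum(q * (1.0 - q)))
    return score, info


def estimate_hazard_ratio(data: StageData, cap: float = HR_CAP) -> float:
    """Experimental-vs-control hazard ratio by Cox partial likelihood.

    Maximises the two-sample partial likelihood (Efron tie handling) by
    Newton iteration on the log hazard ratio.  Values below 1 favour the
    experimental arm.  Under a monotone likelihood (e.g. all events in one
    arm) the estimate is capped at ``cap`` (or ``1/cap``) with a warning.
    """
    _, d1, d, n1, n0 = _risk_table(data)
    max_d = int(d.max())
    bound = np.log(cap)

    beta = 0.0
    for _ in range(60):
        score, info = _efron_terms(beta, d1, d, n1, n0, max_d)
        if info <= 0.0:
            break
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        beta += step
        if abs(beta) >= bound:
            beta = float(np.clip(beta, -bound, bound))
            score, _ = _efron_terms(beta, d1, d, n1, n0, max_d)
            # monotone direction: score still pushes outward at the cap
            if score * beta > 0:
                warnings.warn(
                    "monotone partial likelihood; hazard-ratio estimate capped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                return float(np.exp(beta))
        if abs(step) < 1e-10:
            break
    return float(np.exp(beta))


def interim_decision(hr_O: float, hr_P: float,
                     eta_O: float = 1.0, eta_P: float = 1.0) -> Decision:
    """Interim decision from hazard-ratio estimates and thresholds.

    (i) stop for futility if both estimates sit above their thresholds;
    (ii) continue the overall population if ``hr_O < eta_O`` regardless of
    ``hr_P``; (iii) continue only the positive subgroup if ``hr_O >= eta_O``
    and ``hr_P < eta_P``.  An estimate exactly at its threshold counts as
    not beneficial.
    """
    for name, v in (("hr_O", hr_O), ("hr_P", hr_P), ("eta_O", eta_O), ("eta_P", eta_P)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if hr_O < eta_O:
        return Decision.CONTINUE_O
    if hr_P < eta_P:
        return Decision.ENRICH_P
    return Decision.FUTILITY


@dataclass(frozen=True)
class CombinationWeights:
    """Pre-specified inverse-normal combination weights.

    Derived from the planned stage-wise information levels (event counts)
    ``I_1, I_2`` as ``w_k = sqrt(I_k / (I_1 + I_2))``; the squares sum to 1.
    Weights are fixed at design time and never re-estimated from observed
    events.
    """

    w1: float
    w2: float

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w1**2 + self.w2**2 - 1.0) > 1e-9:
            raise ValueError("weights must satisfy w1^2 + w2^2 = 1")

    @classmethod
    def from_planned_events(cls, events_stage1: float, events_stage2: float) -> "CombinationWeights":
        if events_stage1 <= 0 or events_stage2 <= 0:
            raise ValueError("planned event counts must be positive")
        total = events_stage1 + events_stage2
        return cls(w1=np.sqrt(events_stage1 / total), w2=np.sqrt(events_stage2 / total))


def _clip_p(p: float, label: str) -> float:
    if not 0.0 < p < 1.0:
        warnings.warn(
            f"{label} = {p} clipped to the open unit interval", RuntimeWarning, stacklevel=3
        )
    return float(np.clip(p, *P_CLIP))


def combination_statistic(p1: float, p2: float, weights: CombinationWeights,
                          alpha: float = 0.025) -> tuple[float, bool]:
    """Weighted inverse-normal combination statistic and its test decision.

    Returns ``(C, reject)`` with ``C = w1 Phi^{-1}(1-p1) + w2 Phi^{-1}(1-p2)``
    and ``reject = C > Phi^{-1}(1 - alpha)``.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    p1 = _clip_p(p1, "p1")
    p2 = _clip_p(p2, "p2")
    c = weights.w1 * ndtri(1.0 - p1) + weights.w2 * ndtri(1.0 - p2)
    return float(c), bool(c > ndtri(1.0 - alpha))


def combination_pvalue(p1: float, p2: float, weights: CombinationWeights) -> float:
    """Combined p-value ``1 - Phi(C)``; below alpha exactly when C rejects."""
    c, _ = combination_statistic(p1, p2, weights)
    return float(ndtr(-c))


def hochberg_intersection_p(p_O: float, p_P: float) -> float:
    """Hochberg p-value for the two-hypothesis intersection, capped at 1."""
    lo, hi = min(p_O, p_P), max(p_O, p_P)
    return min(2.0 * lo, hi, 1.0)


@dataclass(frozen=True)
class InterimResult:
    """Interim hazard-ratio estimates and the resulting decision."""

    hr_O: float
    hr_P: float
    eta_O: float
    eta_P: float
    decision: Decision


@dataclass(frozen=True)
class FinalDecision:
    """Outcome of the closed testing procedure at the final analysis."""

    rejected_O: bool
    rejected_P: bool
    alpha: float
    details: dict = field(default_factory=dict, compare=False)


def closed_testing_decision(
    decision: Decision,
    weights: CombinationWeights,
    alpha: float,
    p1_O: float | None = None,
    p1_P: float | None = None,
    p2_O: float | None = None,
    p2_P: float | None = None,
) -> FinalDecision:
    """Closure-principle rejection decision for the realised decision path.

    On the continue-O path the elementary hypothesis for g in {O, P} is
    rejected when both the intersection combination test
    ``C(p1^{O,P}, p2^{O,P})`` and the elementary combination test
    ``C(p1^g, p2^g)`` reject.  On the enrichment path only the positive
    subgroup can be rejected: ``C(p1^{O,P}, p2^P)`` and ``C(p1^P, p2^P)``
    must both reject (stage 2 contributes positive-subgroup data only).
    Futility rejects nothing.

    Raises
    ------
    ValueError
        If a stage p-value required by the realised path is missing.
    """
    if decision is Decision.FUTILITY:
        return FinalDecision(False, False, alpha, {"path": decision.value})

    if p1_O is None or p1_P is None:
        raise ValueError("stage-1 p-values for O and P are required")
    p1_int = hochberg_intersection_p(p1_O, p1_P)

    if decision is Decision.CONTINUE_O:
        if p2_O is None or p2_P is None:
            raise ValueError("continue-O path requires stage-2 p-values for O and P")
        p2_int = hochberg_intersection_p(p2_O, p2_P)
        c_int, rej_int = combination_statistic(p1_int, p2_int, weights, alpha)
        c_O, rej_O = combination_statistic(p1_O, p2_O, weights, alpha)
        c_P, rej_P = combination_statistic(p1_P, p2_P, weights, alpha)
        details = {
            "path": decision.value,
            "p1_int": p1_int, "p2_int": p2_int,
            "C_int": c_int, "C_O": c_O, "C_P": c_P,
        }
        return FinalDecision(rej_int and rej_O, rej_int and rej_P, alpha, details)

    if decision is Decision.ENRICH_P:
        if p2_P is None:
            raise ValueError("enrichment path requires the stage-2 p-value for P")
        c_int, rej_int = combination_statistic(p1_int, p2_P, weights, alpha)
        c_P, rej_P = combination_statistic(p1_P, p2_P, weights, alpha)
        details = {"path": decision.value, "p1_int": p1_int, "C_int": c_int, "C_P": c_P}
        return FinalDecision(False, rej_int and rej_P, alpha, details)

    raise ValueError(f"unknown decision {decision!r}")
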