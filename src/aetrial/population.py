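"""Patient-level data generation for adaptive enrichment trial simulations.

Prospective patients are characterised by a calendar arrival time on the
recruitment window ``[0, R]``, a binary biomarker status partitioning the
overall population O into biomarker-positive (P) and biomarker-negative (N)
subgroups, a randomised treatment arm (experimental E vs control C), and a
latent event time measured from randomisation.  Event times are exponential
with a constant arm-and-subgroup-specific hazard, calibrated so that the
control-arm survival probability at the end of the follow-up horizon F
matches a stated anchor (20% in the reference configuration); the
experimental hazard in subgroup g is the control hazard scaled by the
subgroup hazard ratio, so proportional hazards hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalModel",
    "AccrualPattern",
    "PatientStream",
    "hazard_from_survival",
    "experimental_survival_at_horizon",
    "sample_arrival_times",
    "generate_patient_stream",
    "SCENARIO_HAZARD_RATIOS",
]

#: Hazard ratios (positive subgroup, negative subgroup) of the five reference
#: scenarios: the treatment effect in P is fixed while the effect in N
#: degrades from equally beneficial to clearly harmful.
SCENARIO_HAZARD_RATIOS: dict[int, tuple[float, float]] = {
    1: (0.50, 0.50),
    2: (0.50, 0.90),
    3: (0.50, 1.00),
    4: (0.50, 1.11),
    5: (0.50, 1.43),
}


def hazard_from_survival(survival_prob: float, horizon: float) -> float:
    """Constant hazard rate reproducing ``S(horizon) = survival_prob``.

    Solves ``exp(-lambda * horizon) = survival_prob`` for ``lambda``.

    Parameters
    ----------
    survival_prob : float
        Survival probability at ``horizon``, strictly inside (0, 1).
    horizon : float
        Positive evaluation time.

    Returns
    -------
    float
        The exponential hazard rate ``-log(survival_prob) / horizon``.
    """
    if not 0.0 < survival_prob < 1.0:
        raise ValueError(f"survival_prob must lie in (0, 1), got {survival_prob}")
    if horizon <= 0.0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    return -math.log(survival_prob) / horizon


def experimental_survival_at_horizon(control_survival: float, hazard_ratio: float) -> float:
    """Experimental-arm survival implied by proportional hazards.

    Under a constant hazard ratio ``hr``, ``S_E(t) = S_C(t) ** hr`` at every
    time point.

    Parameters
    ----------
    control_survival : float
        Control-arm survival probability, strictly inside (0, 1).
    hazard_ratio : float
        Positive experimental-vs-control hazard ratio.
    """
    if not 0.0 < control_survival < 1.0:
        raise ValueError(f"control_survival must lie in (0, 1), got {control_survival}")
    if hazard_ratio <= 0.0:
        raise ValueError(f"hazard_ratio must be positive, got {hazard_ratio}")
    return control_survival**hazard_ratio


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential survival model for the four arm-by-subgroup cells.

    Parameters
    ----------
    follow_up : float
        Follow-up horizon F used to anchor the control hazard (time units).
    hr_positive, hr_negative : float
        Experimental-vs-control hazard ratios in the biomarker-positive and
        -negative subgroups.  Values below 1 favour the experimental arm.
    control_survival_at_F : float
        Control-arm survival probability at ``follow_up`` (default 0.2).
    """

    follow_up: float
    hr_positive: float
    hr_negative: float
    control_survival_at_F: float = 0.2

    def __post_init__(self) -> None:
        if self.hr_positive <= 0 or self.hr_negative <= 0:
            raise ValueError("hazard ratios must be positive")
        # hazard_from_survival validates the remaining fields
        hazard_from_survival(self.control_survival_at_F, self.follow_up)

    @classmethod
    def from_scenario(cls, scenario: int, follow_up: float,
                      control_survival_at_F: float = 0.2) -> "SurvivalModel":
        """Build the model for one of the five reference scenarios."""
        try:
            hr_p, hr_n = SCENARIO_HAZARD_RATIOS[scenario]
        except KeyError:
            raise ValueError(f"scenario must be one of 1-5, got {scenario}") from None
        return cls(follow_up=follow_up, hr_positive=hr_p, hr_negative=hr_n,
                   control_survival_at_F=control_survival_at_F)

    @property
    def control_hazard(self) -> float:
        return hazard_from_survival(self.control_survival_at_F, self.follow_up)

    def log_hr(self, positive: bool) -> float:
        """Log hazard ratio of the experimental arm in a subgroup."""
        return math.log(self.hr_positive if positive else self.hr_negative)

    def hazard(self, experimental: bool, positive: bool) -> float:
        """Event hazard for a patient in the given arm and subgroup."""
        lam = self.control_hazard
        if experimental:
            lam *= self.hr_positive if positive else self.hr_negative
        return lam


@dataclass(frozen=True)
class AccrualPattern:
    """Distribution of patient arrival times over the recruitment window.

    ``uniform`` spreads arrivals evenly over ``[0, R]``.  The truncated
    exponential has CDF ``F(t) = (1 - exp(-gamma t)) / (1 - exp(-gamma R))``
    on ``[0, R]``: accrual is front-loaded (convex CDF of arrivals per unit
    time decreasing) for ``gamma > 0`` and back-loaded for ``gamma < 0``.
    """

    recruitment_period: float
    kind: str = "uniform"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.recruitment_period <= 0:
            raise ValueError("recruitment_period must be positive")
        if self.kind not in ("uniform", "truncated_exponential"):
            raise ValueError(f"unknown accrual kind {self.kind!r}")
        if self.kind == "truncated_exponential":
            if self.gamma is None or self.gamma == 0.0:
                raise ValueError("truncated_exponential accrual requires gamma != 0")

    @classmethod
    def uniform(cls, recruitment_period: float) -> "AccrualPattern":
        return cls(recruitment_period=recruitment_period, kind="uniform")

    @classmethod
    def truncated_exponential(cls, recruitment_period: float, gamma: float) -> "AccrualPattern":
        return cls(recruitment_period=recruitment_period,
                   kind="truncated_exponential", gamma=gamma)

    def cdf(self, t):
        """Arrival-time CDF evaluated elementwise, clipped to [0, R]."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, self.recruitment_period)
        if self.kind == "uniform":
            return t / self.recruitment_period
        g = float(self.gamma)
        return np.expm1(-g * t) / np.expm1(-g * self.recruitment_period)

    def quantile(self, u):
        """Inverse CDF; numerically stable down to |gamma| ~ 1e-12."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0.0) | (u > 1.0)):
            raise ValueError("quantile argument must lie in [0, 1]")
        if self.kind == "uniform":
            return u * self.recruitment_period
        g = float(self.gamma)
        # t = -log(1 - u * (1 - exp(-g R))) / g, via expm1/log1p
        return -np.log1p(u * np.expm1(-g * self.recruitment_period)) / g


def sample_arrival_times(n: int, pattern: AccrualPattern,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` sorted arrival times by inverse-CDF sampling."""
    if n < 1:
        raise ValueError("n must be at least 1")
    times = pattern.quantile(rng.random(n))
    times.sort()
    return times


def _deterministic_biomarker(n: int, prevalence: float) -> np.ndarray:
    """Evenly interleaved biomarker statuses with a positive-leaning start.

    Patient ``i`` (0-based) is positive iff ``ceil((i+1) p) > ceil(i p)``,
    which puts exactly ``ceil(k p)`` positives in every length-``k`` prefix.
    At 50% prevalence this is strict alternation starting with a positive, so
    a 165-patient stage-1 cohort holds 83 positives and the remaining 165
    prospective patients hold 82.
    """
    i = np.arange(n + 1, dtype=float)
    cum = np.ceil(i * prevalence)
    return np.diff(cum) > 0


def _blocked_allocation(n_stratum: int, rng: np.random.Generator) -> np.ndarray:
    """1:1 allocation in permuted blocks of two within a stratum.

    Every consecutive pair holds exactly one experimental patient, in random
    order; an odd trailing patient is assigned by a fair coin.
    """
    n_pairs, odd = divmod(n_stratum, 2)
    arm = np.empty(n_stratum, dtype=bool)
    if n_pairs:
        first_exp = rng.random(n_pairs) < 0.5
        arm[0 : 2 * n_pairs : 2] = first_exp
        arm[1 : 2 * n_pairs : 2] = ~first_exp
    if odd:
        arm[-1] = rng.random() < 0.5
    return arm


@dataclass
class PatientStream:
    """Roster of prospective patients for one simulated trial replicate.

    Arrays are aligned and sorted by arrival time; ``biomarker`` is True for
    biomarker-positive patients, ``arm`` is True for the experimental arm.
    ``latent_event_time`` is the time from randomisation to the event; the
    calendar event time of an enrolled patient is their enrollment time plus
    this latent time.
    """

    arrival_time: np.ndarray
    biomarker: np.ndarray
    arm: np.ndarray
    latent_event_time: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.arrival_time)
        if not (len(self.biomarker) == len(self.arm) == len(self.latent_event_time) == n):
            raise ValueError("PatientStream arrays must have equal length")
        if np.any(np.diff(self.arrival_time) < 0):
            raise ValueError("arrival times must be sorted non-decreasingly")
        if np.any(self.latent_event_time <= 0):
            raise ValueError("latent event times must be positive")

    @property
    def n(self) -> int:
        return len(self.arrival_time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "arrival_time": self.arrival_time,
                "biomarker": np.where(self.biomarker, "positive", "negative"),
                "arm": np.where(self.arm, "experimental", "control"),
                "latent_event_time": self.latent_event_time,
            }
        )


def generate_patient_stream(
    n: int,
    model: SurvivalModel,
    pattern: AccrualPattern,
    rng: np.random.Generator | int | None,
    prevalence: float = 0.5,
    biomarker_mode: str = "deterministic",
    allocation: str = "blocked",
) -> PatientStream:
    """Generate one seeded replicate of prospective patients.

    Parameters
    ----------
    n : int
        Number of prospective patients (the planned total sample size).
    model : SurvivalModel
        Hazards for the four arm-by-subgroup cells.
    pattern : AccrualPattern
        Arrival-time distribution over the recruitment window.
    rng : numpy Generator, seed, or None
        Source of randomness; passing the same seed reproduces the stream.
    prevalence : float
        Fraction of the overall population that is biomarker-positive.
    biomarker_mode : {"deterministic", "bernoulli"}
        ``deterministic`` interleaves statuses so every prefix carries
        ``ceil(k * prevalence)`` positives; ``bernoulli`` draws iid statuses.
    allocation : {"blocked", "simple"}
        ``blocked`` uses permuted blocks of two within each biomarker
        stratum (exact 1:1 balance); ``simple`` is a fair coin per patient.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(rng)

    arrival = sample_arrival_times(n, pattern, rng)

    if biomarker_mode == "deterministic":
        biomarker = _deterministic_biomarker(n, prevalence)
    elif biomarker_mode == "bernoulli":
        biomarker = rng.random(n) < prevalence
    else:
        raise ValueError(f"unknown biomarker_mode {biomarker_mode!r}")

    arm = np.empty(n, dtype=bool)
    if allocation == "blocked":
        for status in (True, False):
            idx = np.flatnonzero(biomarker == status)
            arm[idx] = _blocked_allocation(len(idx), rng)
    elif allocation == "simple":
        arm[:] = rng.random(n) < 0.5
    else:
        raise ValueError(f"unknown allocation {allocation!r}")

    lam = np.where(
        arm,
        np.where(biomarker, model.hazard(True, True), model.hazard(True, False)),
        model.control_hazard,
    )
    latent = rng.exponential(1.0, size=n) / lam

    return PatientStream(arrival_time=arrival, biomarker=biomarker,
                         arm=arm, latent_event_time=latent)
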