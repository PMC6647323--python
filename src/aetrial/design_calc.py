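"""Planning calculators: targeted sample size and combination weights.

The Schoenfeld-style targeted sample size (TSS) for a 1:1 two-arm
time-to-event comparison at one-sided level alpha and power 1 - beta is

    TSS = 4 {Phi^{-1}(1-alpha) + Phi^{-1}(1-beta)}^2 / delta^2
          * 2 / (S_E(t) + S_C(t)),

with delta the log hazard ratio and S_E(t), S_C(t) the arm-wise survival
probabilities at the evaluation time.  The first factor is the required
event count; the second converts events to patients.  Note the conversion
factor here is ``2 / (S_E + S_C)``, i.e. one over the average *survival*
probability; the more common Schoenfeld conversion divides the event count
by the average *event* probability ``1 - (S_E + S_C) / 2``.  Both are
available; the former is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtri

from .analysis import CombinationWeights

__all__ = ["DesignInputs", "schoenfeld_tss", "combination_weights"]


@dataclass(frozen=True)
class DesignInputs:
    """Inputs to the targeted-sample-size formula."""

    alpha: float
    beta: float
    hazard_ratio: float
    surv_experimental: float
    surv_control: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.hazard_ratio <= 0.0:
            raise ValueError("hazard_ratio must be positive")
        if self.hazard_ratio == 1.0:
            raise ValueError("hazard_ratio of exactly 1 gives an infinite sample size")
        for name in ("surv_experimental", "surv_control"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def schoenfeld_tss(
    inputs: DesignInputs,
    event_prob_conversion: bool = False,
    even: bool = False,
) -> tuple[float, int]:
    """Targeted sample size for a 1:1 two-arm survival comparison.

    Parameters
    ----------
    inputs : DesignInputs
    event_prob_conversion : bool
        If True, convert the event-count factor to patients by dividing by
        the average event probability ``1 - (S_E + S_C)/2`` instead of
        multiplying by ``2 / (S_E + S_C)``.
    even : bool
        Round up to an even integer for exact 1:1 allocation.

    Returns
    -------
    (unrounded, rounded) : tuple of float and int
    """
    delta = math.log(inputs.hazard_ratio)
    events = 4.0 * (ndtri(1.0 - inputs.alpha) + ndtri(1.0 - inputs.beta)) ** 2 / delta**2
    s_bar = (inputs.surv_experimental + inputs.surv_control) / 2.0
    if event_prob_conversion:
        tss = events / (1.0 - s_bar)
    else:
        tss = events / s_bar
    n = math.ceil(tss)
    if even and n % 2:
        n += 1
    return tss, n


def combination_weights(planned_events_stage1: float,
                        planned_events_stage2: float) -> CombinationWeights:
    """Inverse-normal weights from planned stage-wise event counts."""
    return CombinationWeights.from_planned_events(planned_events_stage1,
                                                  planned_events_stage2)
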