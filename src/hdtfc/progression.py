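"""Constant-rate TFC progression: OLS slope from short-horizon trajectory
observations and one-cycle transition matrices over the 14 TFC states.

The functional-decline trajectory is summarized by an ordinary least squares
slope of mean TFC change on time (with intercept).  Its magnitude, clamped
to [0, 1], is the annual probability of moving down exactly one TFC state.
Movement below TFC 1 is death; a background mortality hazard competes each
cycle, applied before progression.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .parameters import TFC_MAX, TrajectoryObservation

__all__ = [
    "TRANSITION_STATES",
    "fit_tfc_slope",
    "slope_to_annual_transition_probability",
    "ProgressionModel",
    "effective_progression",
    "build_transition_matrix",
]

#: Ordered state labels of the one-cycle transition matrix: the 13 alive TFC
#: scores from 13 down to 1, then the absorbing dead state (TFC 0 included).
TRANSITION_STATES: tuple[str, ...] = tuple(
    f"TFC{k}" for k in range(TFC_MAX, 0, -1)
) + ("dead",)


def fit_tfc_slope(observations: Sequence[TrajectoryObservation]) -> float:
    """OLS slope (with intercept) of mean TFC change on time, points/year."""
    if len(observations) < 2:
        raise ValidationError("need at least two observations to fit a slope")
    t = np.array([o.time for o in observations], dtype=float)
    y = np.array([o.mean_delta for o in observations], dtype=float)
    st = ((t - t.mean()) ** 2).sum()
    if st == 0.0:
        raise ValidationError("degenerate design: all observation times identical")
    return float(((t - t.mean()) * (y - y.mean())).sum() / st)


def slope_to_annual_transition_probability(slope: float) -> float:
    """Annual one-state downward transition probability: |slope| clamped to [0, 1]."""
    if not np.isfinite(slope):
        raise ValidationError(f"slope must be finite, got {slope}")
    return float(min(1.0, max(0.0, -slope)))


@dataclass(frozen=True)
class ProgressionModel:
    """Fitted constant progression rate and its per-cycle probability."""

    slope: float
    annual_transition_probability: float

    @classmethod
    def from_observations(cls, observations: Sequence[TrajectoryObservation]
                          ) -> "ProgressionModel":
        slope = fit_tfc_slope(observations)
        return cls(slope, slope_to_annual_transition_probability(slope))


def effective_progression(p: float, cycle: int, delay_years: float,
                          rate_ratio: float) -> float:
    """Per-cycle progression probability under a treatment scenario.

    Progression is fully arrested for cycles that end before ``delay_years``
    and scaled by ``rate_ratio`` afterwards; a cycle straddling the end of
    the delay is scaled by the uncovered fraction of the year.
    """
    scaled = min(1.0, rate_ratio * p)
    if cycle + 1 <= delay_years:
        return 0.0
    if cycle >= delay_years:
        return scaled
    return scaled * (cycle + 1 - delay_years)


def build_transition_matrix(p: float, q_death: float, delay_active: bool = False,
                            rate_ratio: float = 1.0) -> np.ndarray:
    """One-cycle stochastic matrix over ``TRANSITION_STATES``.

    Background death (probability ``q_death``) is applied first; survivors
    move down one TFC state with effective probability
    ``p* = 0 if delay_active else clamp(rate_ratio * p, 0, 1)``.  Moving down
    from TFC 1 is death.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p must be in [0, 1], got {p}")
    if not (0.0 <= q_death <= 1.0):
        raise ValidationError(f"q_death must be in [0, 1], got {q_death}")
    if not (0.0 < rate_ratio <= 1.0):
        raise ValidationError(f"rate_ratio must be in (0, 1], got {rate_ratio}")
    p_eff = 0.0 if delay_active else min(1.0, max(0.0, rate_ratio * p))

    n = len(TRANSITION_STATES)
    m = np.zeros((n, n))
    dead = n - 1
    for i in range(n - 1):  # alive TFC states, ordered 13..1
        m[i, dead] = q_death
        stay = (1.0 - q_death) * (1.0 - p_eff)
        down = (1.0 - q_death) * p_eff
        m[i, i] = stay
        if i + 1 < dead:
            m[i, i + 1] = down
        else:  # from TFC 1 the downward move reaches TFC 0 = death
            m[i, dead] += down
    m[dead, dead] = 1.0
    return m
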