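"""Functional-decline onset for prefunctional cohorts.

Fits a parametric (default logistic) cumulative onset curve in age for each
CAG stratum, converts a fitted curve into an annual onset schedule whose
mass is renormalized over the modeled age window, and evaluates the
configurable prognostic-index composite score.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConfigurationError, DataError, FittingError
from .parameters import PinHdInputs

__all__ = [
    "OnsetCurve",
    "OnsetSchedule",
    "fit_onset_curve",
    "onset_schedule",
    "shift_schedule",
    "pause_schedule",
    "pin_hd_score",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class OnsetCurve:
    """Cumulative probability of functional-decline onset as a function of
    age, for one CAG stratum.  Default family is a logistic CDF with
    location ``mu`` (years) and scale ``s`` (years)."""

    cag: int
    mu: float
    s: float
    family: str = "logistic"

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise DataError("scale must be > 0")
        if self.family != "logistic":
            raise ConfigurationError(
                f"unknown onset curve family {self.family!r}; pass a custom "
                "object with a cdf(age) method instead")

    def cdf(self, age) -> np.ndarray:
        z = (np.asarray(age, dtype=float) - self.mu) / self.s
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class OnsetSchedule:
    """Per-year onset probabilities from ``start_age``; ``weights[t]`` is the
    probability that onset occurs at the start of cycle ``t`` and
    ``residual_weight`` the probability of no onset within the horizon.
    Weights plus residual always sum to 1."""

    start_age: int
    weights: np.ndarray
    residual_weight: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if (w < -_SUM_TOL).any() or self.residual_weight < -_SUM_TOL:
            raise DataError("onset weights must be non-negative")
        total = w.sum() + self.residual_weight
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"onset weights must sum to 1, got {total}")

    @property
    def horizon(self) -> int:
        return len(self.weights)


def fit_onset_curve(points: Sequence[tuple[float, float]], cag: int,
                    monotone_tol: float = 0.01) -> OnsetCurve:
    """Least-squares logistic fit to (age, cumulative probability) points."""
    if len(points) < 3:
        raise DataError("need at least 3 points to fit an onset curve")
    ages = np.array([a for a, _ in points], dtype=float)
    probs = np.array([p for _, p in points], dtype=float)
    if (np.diff(ages) <= 0).any():
        raise DataError("ages must be strictly increasing")
    if ((probs < 0) | (probs > 1)).any():
        raise DataError("cumulative probabilities must lie in [0, 1]")
    if (np.diff(probs) < -monotone_tol).any():
        raise DataError("cumulative probabilities decrease beyond tolerance")

    # initial location: age where the curve crosses 0.5 (or the midpoint)
    if probs.max() > 0.5 > probs.min():
        mu0 = float(np.interp(0.5, probs, ages))
    else:
        mu0 = float(ages.mean())
    s0 = max(1.0, (ages[-1] - ages[0]) / 8.0)

    def residuals(theta):
        mu, log_s = theta
        return 1.0 / (1.0 + np.exp(-(ages - mu) / math.exp(log_s))) - probs

    result = least_squares(residuals, x0=[mu0, math.log(s0)], method="lm",
                           max_nfev=10000)
    if not result.success:
        raise FittingError(f"onset curve fit did not converge: {result.message}")
    mu, log_s = result.x
    return OnsetCurve(cag=cag, mu=float(mu), s=float(math.exp(log_s)))


def onset_schedule(curve, start_age: int, max_age: int) -> OnsetSchedule:
    """Annual onset schedule from a cumulative curve, renormalized so that
    all onset mass falls within [start_age, max_age].

    ``curve`` is any object with a ``cdf(age)`` method.  The weight for year
    ``t`` is the CDF increment over [start_age + t, start_age + t + 1]
    divided by the total increment over the window, so the weights sum to 1
    and the residual is 0.
    """
    if start_age >= max_age:
        raise DataError("start_age must be < max_age")
    grid = np.arange(start_age, max_age + 1, dtype=float)
    cdf = np.asarray(curve.cdf(grid), dtype=float)
    denom = cdf[-1] - cdf[0]
    if denom <= 1e-12:
        raise DataError(
            f"onset curve is flat on [{start_age}, {max_age}]; cannot reweight")
    weights = np.diff(cdf) / denom
    return OnsetSchedule(start_age=start_age, weights=weights, residual_weight=0.0)


def shift_schedule(schedule: OnsetSchedule, delay_years: int) -> OnsetSchedule:
    """Translate the whole schedule later by ``delay_years``; onset mass
    pushed beyond the horizon becomes residual (no onset)."""
    d = int(round(delay_years))
    if d <= 0:
        return schedule
    n = schedule.horizon
    w = np.zeros(n)
    w[d:] = schedule.weights[: n - d]
    overflow = schedule.weights[n - d:].sum()
    return OnsetSchedule(schedule.start_age, w,
                         schedule.residual_weight + float(overflow))


def pause_schedule(schedule: OnsetSchedule, delay_years: int) -> OnsetSchedule:
    """Zero the onset hazard for the first ``delay_years`` years, then resume
    the original annual hazards on the original age grid."""
    d = int(round(delay_years))
    if d <= 0:
        return schedule
    w = schedule.weights
    survival = 1.0 - np.concatenate([[0.0], np.cumsum(w[:-1])])
    with np.errstate(divide="ignore", invalid="ignore"):
        hazard = np.where(survival > 1e-15, w / np.maximum(survival, 1e-15), 0.0)
    out = np.zeros_like(w)
    alive = 1.0
    for t in range(d, len(w)):
        out[t] = alive * hazard[t]
        alive -= out[t]
    return OnsetSchedule(schedule.start_age, out, float(max(alive, 0.0)))


_REQUIRED_COEFFS = ("motor", "cognitive", "cag_age", "cag_offset", "center", "scale")


def pin_hd_score(inputs: PinHdInputs) -> float:
    """Normalized weighted composite of motor score, cognitive score, and the
    offset CAG-by-age product.  All coefficients come from configuration."""
    c = inputs.coefficients
    missing = [k for k in _REQUIRED_COEFFS if k not in c]
    if missing:
        raise ConfigurationError(f"missing prognostic-index coefficients: {missing}")
    if c["scale"] == 0:
        raise ConfigurationError("prognostic-index scale must be nonzero")
    raw = (c["motor"] * inputs.tms
           + c["cognitive"] * inputs.sdmt
           + c["cag_age"] * (inputs.cag - c["cag_offset"]) * inputs.age)
    return (raw - c["center"]) / c["scale"]
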