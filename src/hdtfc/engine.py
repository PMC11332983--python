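"""Annual-cycle cohort propagation and lifetime outcome accumulation.

The trace tracks occupancy over a prefunctional-decline column, the 13 alive
TFC scores (13 down to 1), and two absorbing dead columns (progression past
TFC 1, i.e. TFC 0, versus background mortality).  Payoffs accrue at cycle
start with discount factor (1 + d)^-t; the final cycle-start row (at
max_age) accrues nothing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .exceptions import DataError, ValidationError
from .onset import OnsetSchedule
from .parameters import (
    STAGE_TFC_RANGE,
    TFC_MAX,
    ParameterSet,
    StagePayoffs,
    sf_stage_of,
)
from .progression import ProgressionModel, effective_progression

__all__ = [
    "LifeTable",
    "STATE_COLUMNS",
    "CohortTrace",
    "Accrued",
    "OutcomeSet",
    "run_cohort",
    "run_pfd_cohort",
    "accumulate_outcomes",
    "median_survival",
]

_MASS_TOL = 1e-12

#: Trace columns: prefunctional decline, alive TFC states 13..1, then the
#: two absorbing death columns.
STATE_COLUMNS: tuple[str, ...] = (
    ("PFD",)
    + tuple(f"TFC{k}" for k in range(TFC_MAX, 0, -1))
    + ("dead_progression", "dead_background")
)
_PFD = 0
_TFC0_COL = {k: 1 + (TFC_MAX - k) for k in range(TFC_MAX, 0, -1)}  # TFC k -> column
_DEAD_PROG = len(STATE_COLUMNS) - 2
_DEAD_BG = len(STATE_COLUMNS) - 1


@dataclass(frozen=True)
class LifeTable:
    """Annual background death probabilities q(a) on a contiguous age grid."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if len(ages) != len(qx) or len(ages) == 0:
            raise DataError("life table must have matching, non-empty age/qx columns")
        if (np.diff(ages) != 1).any():
            raise DataError("life table ages must be contiguous integers")
        bad = np.where((qx < 0) | (qx > 1))[0]
        if bad.size:
            raise DataError(
                f"life table qx outside [0, 1] at age {int(ages[bad[0]])}: "
                f"{qx[bad[0]]}")

    def q(self, age: int) -> float:
        idx = int(age) - int(self.ages[0])
        if idx < 0 or idx >= len(self.qx):
            raise DataError(f"life table does not cover age {age}")
        return float(self.qx[idx])

    def require_coverage(self, start_age: int, max_age: int) -> None:
        """Fail unless every transition age in [start_age, max_age) is covered."""
        if self.ages[0] > start_age or self.ages[-1] < max_age - 1:
            raise DataError(
                f"life table covers ages [{self.ages[0]}, {self.ages[-1]}] but "
                f"[{start_age}, {max_age - 1}] is required")


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-start occupancy over STATE_COLUMNS, plus the per-cycle fraction
    newly dying of progression (entry to TFC 0, indexed by arrival cycle)."""

    start_age: int
    occupancy: np.ndarray  # shape (T + 1, len(STATE_COLUMNS))
    entry_to_death: np.ndarray  # shape (T + 1,)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(STATE_COLUMNS):
            raise ValidationError("occupancy must be (T+1, n_states)")
        sums = occ.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValidationError("occupancy rows must sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0])

    @property
    def survival(self) -> np.ndarray:
        dead = self.occupancy[:, _DEAD_PROG] + self.occupancy[:, _DEAD_BG]
        return 1.0 - dead

    def alive_tfc(self) -> np.ndarray:
        """Occupancy over the 13 alive TFC columns (13..1)."""
        return self.occupancy[:, 1:_DEAD_PROG]

    @property
    def pfd(self) -> np.ndarray:
        return self.occupancy[:, _PFD]


def _propagate(start_col: int, p: float, params: ParameterSet,
               life_table: LifeTable, onset_cycle: Optional[int] = None,
               delay_years: float = 0.0, rate_ratio: float = 1.0) -> CohortTrace:
    """Shared stepping loop.

    ``onset_cycle`` is the cycle at which a PFD cohort enters TFC 13 (None
    for cohorts already progressing, or never for a pure-background cohort
    when set beyond the horizon).  ``delay_years``/``rate_ratio`` act on the
    progression hazard only.
    """
    T = params.horizon
    life_table.require_coverage(params.start_age, params.max_age)
    occ = np.zeros((T + 1, len(STATE_COLUMNS)))
    entry = np.zeros(T + 1)
    occ[0, start_col] = 1.0
    post_onset_age = 0  # cycles since progression began, for the DMT clock
    for t in range(T):
        if onset_cycle is not None and t == onset_cycle and occ[t, _PFD] > 0:
            occ[t, _TFC0_COL[TFC_MAX]] += occ[t, _PFD]
            occ[t, _PFD] = 0.0
        q = life_table.q(params.start_age + t)
        clock = t if onset_cycle is None else t - (onset_cycle or 0)
        p_eff = effective_progression(p, max(clock, 0), delay_years, rate_ratio)
        row = occ[t]
        alive = row[:_DEAD_PROG]
        occ[t + 1, _DEAD_BG] = row[_DEAD_BG] + alive.sum() * q
        surv = 1.0 - q
        occ[t + 1, _PFD] = surv * row[_PFD]
        tfc = row[1:_DEAD_PROG]
        stay = surv * (1.0 - p_eff) * tfc
        down = surv * p_eff * tfc
        new_tfc = stay.copy()
        new_tfc[1:] += down[:-1]
        occ[t + 1, 1:_DEAD_PROG] = new_tfc
        entry[t + 1] = down[-1]
        occ[t + 1, _DEAD_PROG] = row[_DEAD_PROG] + down[-1]
    return CohortTrace(params.start_age, occ, entry)


def run_cohort(params: ParameterSet, life_table: LifeTable) -> CohortTrace:
    """Natural-history (or treated) trace for an SF1/SF2 cohort starting with
    100% mass at ``params.start_tfc``."""
    if params.population not in ("SF1", "SF2"):
        raise ValidationError("run_cohort requires population SF1 or SF2; "
                              "use run_pfd_cohort for PFD")
    p = ProgressionModel.from_observations(params.trajectories)
    return _propagate(
        _TFC0_COL[params.start_tfc], p.annual_transition_probability, params,
        life_table, onset_cycle=None,
        delay_years=params.dmt.delay_years, rate_ratio=params.dmt.rate_ratio)


def run_pfd_cohort(params: ParameterSet, schedule: OnsetSchedule,
                   life_table: LifeTable) -> CohortTrace:
    """Pooled trace for a prefunctional-decline cohort.

    Subcohort k (weight ``schedule.weights[k]``) stays in the PFD state under
    background mortality for k cycles, then enters TFC 13 and progresses at
    the fitted rate (times any DMT rate ratio).  The residual subcohort
    never experiences onset.  The pooled trace is the weighted mixture.
    """
    if params.population != "PFD":
        raise ValidationError("run_pfd_cohort requires population PFD")
    if schedule.horizon > params.horizon:
        raise DataError(
            f"onset schedule horizon {schedule.horizon} exceeds model horizon "
            f"{params.horizon}")
    if schedule.start_age != params.start_age:
        raise DataError("schedule start_age must match params.start_age")
    p = ProgressionModel.from_observations(params.trajectories)
    rr = params.dmt.rate_ratio

    T = params.horizon
    occ = np.zeros((T + 1, len(STATE_COLUMNS)))
    entry = np.zeros(T + 1)
    pieces = [(float(w), k) for k, w in enumerate(schedule.weights) if w > 0.0]
    if schedule.residual_weight > 0.0:
        pieces.append((float(schedule.residual_weight), None))
    for w, k in pieces:
        onset = k if k is not None else T + 1  # beyond horizon: never onsets
        sub = _propagate(_PFD, p.annual_transition_probability, params,
                         life_table, onset_cycle=onset, rate_ratio=rr)
        occ += w * sub.occupancy
        entry += w * sub.entry_to_death
    return CohortTrace(params.start_age, occ, entry)


@dataclass(frozen=True)
class Accrued:
    """A quantity accumulated both with and without discounting."""

    discounted: float
    undiscounted: float

    def __sub__(self, other: "Accrued") -> "Accrued":
        return Accrued(self.discounted - other.discounted,
                       self.undiscounted - other.undiscounted)


@dataclass(frozen=True)
class OutcomeSet:
    """Lifetime totals for one cohort run.

    ``cost`` is keyed (category, stage) with categories ``direct`` and
    ``societal``; the ``SF5`` stage cell is the one-time terminal payoff
    (zero unless enabled in the payoffs).
    """

    population: str
    life_years: Accrued
    qalys: Accrued
    qalys_by_stage: Mapping[str, Accrued]
    cost: Mapping[tuple[str, str], Accrued]
    median_survival_years: float

    @property
    def total_cost(self) -> Accrued:
        d = sum(v.discounted for v in self.cost.values())
        u = sum(v.undiscounted for v in self.cost.values())
        return Accrued(d, u)

    def cost_by_category(self, category: str) -> Accrued:
        items = [v for (cat, _), v in self.cost.items() if cat == category]
        return Accrued(sum(v.discounted for v in items),
                       sum(v.undiscounted for v in items))


def median_survival(trace: CohortTrace) -> float:
    """First crossing of survival = 0.5, linearly interpolated between
    cycle-start grid points; inf if never crossed within the horizon."""
    s = trace.survival
    below = np.where(s < 0.5)[0]
    if below.size == 0:
        return float("inf")
    t = int(below[0])
    if t == 0:
        return 0.0
    return float((t - 1) + (s[t - 1] - 0.5) / (s[t - 1] - s[t]))


def accumulate_outcomes(trace: CohortTrace, payoffs: StagePayoffs,
                        discount_rate: float,
                        population: Optional[str] = None) -> OutcomeSet:
    """Lifetime life years, QALYs, and costs from a trace.

    Accrual is at cycle start with factor (1 + d)^-t, cycles 0..T-1 (no
    half-cycle correction).  TFC occupancy maps to SF-stage payoffs; the PFD
    column carries the prefunctional utility and no HD cost.  When enabled,
    the SF5 annual cost is charged once to mass newly reaching TFC 0,
    discounted at its arrival cycle.
    """
    if not (0.0 <= discount_rate < 1.0):
        raise ValidationError("discount_rate must be in [0, 1)")
    T = trace.n_cycles
    t_grid = np.arange(T)
    disc = (1.0 + discount_rate) ** (-t_grid)
    ones = np.ones(T)

    tfc_scores = list(range(TFC_MAX, 0, -1))
    stage_of_col = [sf_stage_of(k) for k in tfc_scores]
    tfc_occ = trace.alive_tfc()[:T]
    pfd_occ = trace.pfd[:T]

    stage_time_d: dict[str, float] = {s: 0.0 for s in ("PFD", "SF1", "SF2", "SF3", "SF4")}
    stage_time_u: dict[str, float] = {s: 0.0 for s in stage_time_d}
    stage_time_d["PFD"] = float((pfd_occ * disc).sum())
    stage_time_u["PFD"] = float(pfd_occ.sum())
    for col, stage in enumerate(stage_of_col):
        stage_time_d[stage] += float((tfc_occ[:, col] * disc).sum())
        stage_time_u[stage] += float((tfc_occ[:, col] * ones).sum())

    life_years = Accrued(sum(stage_time_d.values()), sum(stage_time_u.values()))

    qalys_by_stage = {
        stage: Accrued(stage_time_d[stage] * payoffs.utility[stage],
                       stage_time_u[stage] * payoffs.utility[stage])
        for stage in stage_time_d
    }
    qalys = Accrued(sum(v.discounted for v in qalys_by_stage.values()),
                    sum(v.undiscounted for v in qalys_by_stage.values()))

    cost: dict[tuple[str, str], Accrued] = {}
    for category, table in (("direct", payoffs.direct_cost),
                            ("societal", payoffs.societal_cost)):
        for stage in ("SF1", "SF2", "SF3", "SF4"):
            cost[(category, stage)] = Accrued(
                stage_time_d[stage] * table[stage],
                stage_time_u[stage] * table[stage])
        if payoffs.apply_sf5_terminal_cost:
            entry = trace.entry_to_death
            disc_all = (1.0 + discount_rate) ** (-np.arange(T + 1))
            cost[(category, "SF5")] = Accrued(
                float((entry * disc_all).sum()) * table["SF5"],
                float(entry.sum()) * table["SF5"])
        else:
            cost[(category, "SF5")] = Accrued(0.0, 0.0)

    if population is None:
        if trace.occupancy[0, _PFD] > 0:
            population = "PFD"
        else:
            start = int(np.argmax(trace.occupancy[0, 1:_DEAD_PROG]))
            population = sf_stage_of(tfc_scores[start])
    return OutcomeSet(
        population=population,
        life_years=life_years,
        qalys=qalys,
        qalys_by_stage=qalys_by_stage,
        cost=cost,
        median_survival_years=median_survival(trace),
    )
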