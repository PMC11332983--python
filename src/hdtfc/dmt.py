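"""Hypothetical disease-modifying treatment scenarios and incremental
outcomes versus natural history."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .engine import (
    Accrued,
    CohortTrace,
    LifeTable,
    OutcomeSet,
    accumulate_outcomes,
    run_cohort,
    run_pfd_cohort,
)
from .exceptions import ConfigurationError, ValidationError
from .onset import OnsetSchedule, pause_schedule, shift_schedule
from .parameters import IDENTITY_SCENARIO, DMTScenario, ParameterSet

__all__ = [
    "scenario_library",
    "IncrementalSet",
    "incremental_outcomes",
    "run_scenario_trace",
    "run_scenario",
]

_SCENARIOS: dict[str, DMTScenario] = {
    "A": DMTScenario(3, 0.75),
    "B": DMTScenario(2, 0.85),
    "C": DMTScenario(1, 0.95),
}


def scenario_library() -> dict[str, DMTScenario]:
    """Named treatment scenarios: A = (3 y, 0.75), B = (2 y, 0.85),
    C = (1 y, 0.95)."""
    return dict(_SCENARIOS)


def get_scenario(name: str) -> DMTScenario:
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; known: {sorted(_SCENARIOS)}") from None


@dataclass(frozen=True)
class IncrementalSet:
    """Treated-minus-natural-history differences, field for field."""

    population: str
    life_years: Accrued
    qalys: Accrued
    qalys_by_stage: Mapping[str, Accrued]
    cost: Mapping[tuple[str, str], Accrued]

    @property
    def total_cost(self) -> Accrued:
        return Accrued(sum(v.discounted for v in self.cost.values()),
                       sum(v.undiscounted for v in self.cost.values()))

    def cost_by_category(self, category: str) -> Accrued:
        items = [v for (cat, _), v in self.cost.items() if cat == category]
        return Accrued(sum(v.discounted for v in items),
                       sum(v.undiscounted for v in items))


def incremental_outcomes(treated: OutcomeSet, natural: OutcomeSet) -> IncrementalSet:
    """Element-wise treated - natural across all outcome fields."""
    if treated.population != natural.population:
        raise ValidationError(
            f"population mismatch: {treated.population} vs {natural.population}")
    return IncrementalSet(
        population=treated.population,
        life_years=treated.life_years - natural.life_years,
        qalys=treated.qalys - natural.qalys,
        qalys_by_stage={k: treated.qalys_by_stage[k] - natural.qalys_by_stage[k]
                        for k in treated.qalys_by_stage},
        cost={k: treated.cost[k] - natural.cost[k] for k in treated.cost},
    )


def run_scenario_trace(params: ParameterSet, life_table: LifeTable,
                       scenario: DMTScenario,
                       schedule: Optional[OnsetSchedule] = None,
                       onset_delay_mode: str = "shift") -> CohortTrace:
    """Trace under a treatment scenario.

    For SF1/SF2 the delay arrests progression for its duration, with
    background mortality still applied, and the rate ratio scales the hazard
    afterwards.  For PFD the delay moves the onset schedule later — by
    translation (``shift``, the default) or by hazard suspension
    (``pause``) — and the rate ratio applies after onset.
    """
    if params.population == "PFD":
        if schedule is None:
            raise ConfigurationError("PFD scenario runs require an onset schedule")
        if onset_delay_mode == "shift":
            delayed = shift_schedule(schedule, int(round(scenario.delay_years)))
        elif onset_delay_mode == "pause":
            delayed = pause_schedule(schedule, int(round(scenario.delay_years)))
        else:
            raise ConfigurationError(
                f"onset_delay_mode must be 'shift' or 'pause', got {onset_delay_mode!r}")
        treated = params.replace(dmt=DMTScenario(0, scenario.rate_ratio))
        return run_pfd_cohort(treated, delayed, life_table)
    return run_cohort(params.replace(dmt=scenario), life_table)


def run_scenario(params: ParameterSet, life_table: LifeTable,
                 scenario: DMTScenario,
                 schedule: Optional[OnsetSchedule] = None,
                 onset_delay_mode: str = "shift") -> IncrementalSet:
    """Incremental outcomes of a scenario versus natural history, holding
    all other inputs fixed."""
    natural_params = params.replace(dmt=IDENTITY_SCENARIO)
    if params.population == "PFD":
        natural = run_pfd_cohort(natural_params, schedule, life_table)
    else:
        natural = run_cohort(natural_params, life_table)
    treated = run_scenario_trace(params, life_table, scenario, schedule,
                                 onset_delay_mode)
    d = params.discount_rate
    return incremental_outcomes(
        accumulate_outcomes(treated, params.payoffs, d, params.population),
        accumulate_outcomes(natural, params.payoffs, d, params.population),
    )
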