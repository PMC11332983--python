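"""Probabilistic sensitivity analysis with correlated trajectory draws, and
one-way (tornado) sensitivity analysis.

PSA draws the 12-month TFC delta from its normal distribution, sets the
36-month delta proportionally (a single shared draw, implementing perfect
correlation), re-derives the progression regression per draw, and samples
utilities (beta) and costs (log-normal).  Credible ranges are empirical
2.5th/97.5th percentiles with the linear-interpolation quantile rule.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dmt import IncrementalSet, run_scenario
from .engine import LifeTable, OutcomeSet, accumulate_outcomes, run_cohort, run_pfd_cohort
from .exceptions import ConfigurationError, HdtfcError, ValidationError
from .onset import OnsetSchedule
from .parameters import (
    DMTScenario,
    DistributionSpec,
    ParameterSet,
    StagePayoffs,
    TrajectoryObservation,
    base_case_registry,
    beta_from_mean_bounds,
    lognormal_from_mean_bounds,
    normal_from_mean_bounds,
)

__all__ = [
    "PSASpec",
    "PSAResults",
    "default_distribution_registry",
    "sample_parameters",
    "run_psa",
    "credible_range",
    "TornadoRow",
    "TornadoTable",
    "run_owsa",
    "flatten_outcomes",
]

#: Fixed draw order so a given (seed, index) always yields the same draws.
_DRAW_ORDER = (
    ("tfc_delta_12mo",)
    + tuple(f"utility_{s}" for s in ("PFD", "SF1", "SF2", "SF3", "SF4"))
    + tuple(f"direct_cost_{s}" for s in ("SF1", "SF2", "SF3", "SF4", "SF5"))
    + tuple(f"societal_cost_{s}" for s in ("SF1", "SF2", "SF3", "SF4", "SF5"))
)

#: Floor for log-normal lower bounds printed as $0.
_LOGNORMAL_FLOOR = 1e-6


def default_distribution_registry(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Distribution for every varied parameter, from the packaged bounds.

    The 12-month trajectory delta takes its mean and CI from ``params`` so
    that the correlated 36-month rescaling stays anchored to the run's own
    base case.
    """
    reg = base_case_registry()
    out: dict[str, DistributionSpec] = {}
    obs12 = _observation_at(params.trajectories, 1.0)
    if obs12.ci_lower is not None and obs12.ci_upper is not None:
        out["tfc_delta_12mo"] = normal_from_mean_bounds(
            obs12.mean_delta, obs12.ci_lower, obs12.ci_upper)
    else:
        out["tfc_delta_12mo"] = DistributionSpec("point", obs12.mean_delta)
    for stage, row in reg["utilities"].items():
        out[f"utility_{stage}"] = beta_from_mean_bounds(row[0], row[1], row[2])
    for kind, key in (("direct_costs", "direct_cost"),
                      ("societal_costs", "societal_cost")):
        for stage, row in reg[kind].items():
            lo = max(row[1], _LOGNORMAL_FLOOR)
            out[f"{key}_{stage}"] = lognormal_from_mean_bounds(row[0], lo, row[2])
    return out


@dataclass(frozen=True)
class PSASpec:
    """Configuration for a probabilistic sensitivity analysis run."""

    seed: int
    n_simulations: int = 5000
    registry: Optional[Mapping[str, DistributionSpec]] = None
    truncate_normal_at_ci: bool = False

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValidationError("n_simulations must be >= 1")


def _observation_at(trajectories: Sequence[TrajectoryObservation],
                    time: float) -> TrajectoryObservation:
    for obs in trajectories:
        if obs.time == time:
            return obs
    raise ConfigurationError(f"no trajectory observation at time {time}")


def _draw(spec: DistributionSpec, rng: np.random.Generator,
          truncate: bool = False) -> float:
    if truncate and spec.family == "normal":
        from scipy.stats import truncnorm

        mean, sd = spec.params["mean"], spec.params["sd"]
        lower = spec.params.get("lower", mean - 1.96 * sd)
        upper = spec.params.get("upper", mean + 1.96 * sd)
        return float(truncnorm.rvs((lower - mean) / sd, (upper - mean) / sd,
                                   loc=mean, scale=sd, random_state=rng))
    return float(spec.sample(rng))


def sample_parameters(params: ParameterSet, spec: PSASpec,
                      simulation_index: int) -> ParameterSet:
    """One joint parameter draw, deterministic in (seed, simulation_index).

    The 12-month delta is drawn; the 36-month delta is rescaled by the same
    relative deviation so the two stay perfectly correlated, and the slope
    regression downstream is re-fit from the drawn deltas.
    """
    registry = dict(spec.registry) if spec.registry is not None else \
        default_distribution_registry(params)
    missing = [k for k in _DRAW_ORDER if k not in registry]
    if missing:
        raise ConfigurationError(f"distribution registry missing entries: {missing}")
    rng = np.random.default_rng([spec.seed, simulation_index])
    draws = {name: _draw(registry[name], rng, spec.truncate_normal_at_ci)
             for name in _DRAW_ORDER}

    base12 = _observation_at(params.trajectories, 1.0).mean_delta
    d12 = draws["tfc_delta_12mo"]
    ratio = d12 / base12 if base12 != 0 else 1.0
    new_traj = tuple(
        obs if obs.time == 0 else
        TrajectoryObservation(obs.time, obs.mean_delta * ratio)
        for obs in params.trajectories
    )

    payoffs = StagePayoffs(
        utility={"PFD": min(draws["utility_PFD"], 1.0),
                 **{s: min(draws[f"utility_{s}"], 1.0)
                    for s in ("SF1", "SF2", "SF3", "SF4")}},
        direct_cost={s: draws[f"direct_cost_{s}"]
                     for s in ("SF1", "SF2", "SF3", "SF4", "SF5")},
        societal_cost={s: draws[f"societal_cost_{s}"]
                       for s in ("SF1", "SF2", "SF3", "SF4", "SF5")},
        apply_sf5_terminal_cost=params.payoffs.apply_sf5_terminal_cost,
    )
    return params.replace(trajectories=new_traj, payoffs=payoffs)


def flatten_outcomes(outcomes) -> dict[str, float]:
    """Scalar view of an OutcomeSet or IncrementalSet for summarizing."""
    flat = {
        "life_years_discounted": outcomes.life_years.discounted,
        "life_years_undiscounted": outcomes.life_years.undiscounted,
        "qalys_discounted": outcomes.qalys.discounted,
        "qalys_undiscounted": outcomes.qalys.undiscounted,
        "total_cost_discounted": outcomes.total_cost.discounted,
        "total_cost_undiscounted": outcomes.total_cost.undiscounted,
        "direct_cost_discounted": outcomes.cost_by_category("direct").discounted,
        "societal_cost_discounted": outcomes.cost_by_category("societal").discounted,
    }
    if isinstance(outcomes, OutcomeSet):
        flat["median_survival_years"] = outcomes.median_survival_years
    return flat


@dataclass(frozen=True)
class PSAResults:
    """Per-simulation scalar outcomes plus any recorded failures."""

    records: pd.DataFrame
    failures: tuple[tuple[int, str], ...] = ()

    def credible_ranges(self) -> dict[str, tuple[float, float]]:
        return {col: credible_range(self.records[col].to_numpy())
                for col in self.records.columns if col != "simulation"}


def credible_range(samples) -> tuple[float, float]:
    """Empirical 95% credible range: 2.5th and 97.5th percentiles with the
    linear-interpolation quantile definition."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValidationError("credible_range requires at least one sample")
    lo, hi = np.percentile(arr, [2.5, 97.5], method="linear")
    return float(lo), float(hi)


def run_psa(params: ParameterSet, spec: PSASpec, life_table: LifeTable,
            scenario: Optional[DMTScenario] = None,
            schedule: Optional[OnsetSchedule] = None) -> PSAResults:
    """Full model evaluation under ``spec.n_simulations`` joint draws.

    With a scenario, each simulation records incremental outcomes versus
    natural history under the same draw; otherwise natural-history outcomes.
    Simulations that fail validation are recorded and surfaced as warnings.
    """
    rows = []
    failures: list[tuple[int, str]] = []
    for i in range(spec.n_simulations):
        try:
            ps = sample_parameters(params, spec, i)
            if scenario is not None:
                rec = flatten_outcomes(
                    run_scenario(ps, life_table, scenario, schedule))
            else:
                if ps.population == "PFD":
                    trace = run_pfd_cohort(ps, schedule, life_table)
                else:
                    trace = run_cohort(ps, life_table)
                rec = flatten_outcomes(accumulate_outcomes(
                    trace, ps.payoffs, ps.discount_rate, ps.population))
            rows.append({"simulation": i, **rec})
        except HdtfcError as exc:  # pragma: no cover - defensive
            failures.append((i, str(exc)))
    if failures:
        warnings.warn(f"{len(failures)} of {spec.n_simulations} PSA simulations "
                      "failed validation and were recorded", stacklevel=2)
    return PSAResults(records=pd.DataFrame(rows),
                      failures=tuple(failures))


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low_value: float
    high_value: float
    outcome_low: float
    outcome_high: float

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


@dataclass(frozen=True)
class TornadoTable:
    """One-way sensitivity results, ranked widest bar first."""

    outcome: str
    base_outcome: float
    rows: tuple[TornadoRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"parameter": r.parameter, "low_value": r.low_value,
              "high_value": r.high_value, "outcome_low": r.outcome_low,
              "outcome_high": r.outcome_high, "width": r.width}
             for r in self.rows])


def _scale_trajectories(params: ParameterSet, factor: float) -> ParameterSet:
    new_traj = tuple(
        obs if obs.time == 0 else
        TrajectoryObservation(obs.time, obs.mean_delta * factor)
        for obs in params.trajectories)
    return params.replace(trajectories=new_traj)


def _set_payoff(params: ParameterSet, table: str, stage: str,
                value: float) -> ParameterSet:
    payoffs = params.payoffs
    fields = {"utility": dict(payoffs.utility),
              "direct_cost": dict(payoffs.direct_cost),
              "societal_cost": dict(payoffs.societal_cost)}
    fields[table][stage] = value
    return params.replace(payoffs=StagePayoffs(
        utility=fields["utility"], direct_cost=fields["direct_cost"],
        societal_cost=fields["societal_cost"],
        apply_sf5_terminal_cost=payoffs.apply_sf5_terminal_cost))


def _owsa_variations(params: ParameterSet, scenario: Optional[DMTScenario]):
    """(name, base_value, apply(params, scenario, value)) triples."""
    variations = []

    def traj(ps, sc, v, base=1.0):
        return _scale_trajectories(ps, v), sc

    variations.append(("tfc_progression_rate", 1.0, traj))

    util_stages = ["PFD", "SF1", "SF2", "SF3", "SF4"] if params.population == "PFD" \
        else ["SF1", "SF2", "SF3", "SF4"]
    for stage in util_stages:
        def apply_u(ps, sc, v, stage=stage):
            return _set_payoff(ps, "utility", stage, min(v, 1.0)), sc
        variations.append((f"utility_{stage}", params.payoffs.utility[stage], apply_u))
    for table in ("direct_cost", "societal_cost"):
        costs = getattr(params.payoffs, table)
        for stage in ("SF1", "SF2", "SF3", "SF4", "SF5"):
            def apply_c(ps, sc, v, table=table, stage=stage):
                return _set_payoff(ps, table, stage, v), sc
            variations.append((f"{table}_{stage}", costs[stage], apply_c))

    def apply_d(ps, sc, v):
        return ps.replace(discount_rate=v), sc

    variations.append(("discount_rate", params.discount_rate, apply_d))

    if scenario is not None:
        def apply_rr(ps, sc, v):
            return ps, replace(sc, rate_ratio=min(max(v, 1e-9), 1.0))

        def apply_delay(ps, sc, v):
            return ps, replace(sc, delay_years=max(v, 0.0))

        variations.append(("dmt_rate_ratio", scenario.rate_ratio, apply_rr))
        variations.append(("dmt_delay_years", scenario.delay_years, apply_delay))
    return variations


def run_owsa(params: ParameterSet, life_table: LifeTable, fraction: float = 0.25,
             scenario: Optional[DMTScenario] = None,
             schedule: Optional[OnsetSchedule] = None,
             outcome: Optional[str] = None) -> TornadoTable:
    """Vary each parameter to base*(1 -/+ fraction), re-run the model, and
    rank parameters by the width of the outcome swing.

    Default outcome is discounted total cost for natural history and
    discounted incremental QALYs when a scenario is given.  Utilities and
    the rate ratio are capped at 1 after scaling.
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must be in (0, 1)")
    if outcome is None:
        outcome = "qalys_discounted" if scenario is not None else \
            "total_cost_discounted"

    def evaluate(ps: ParameterSet, sc: Optional[DMTScenario]) -> float:
        if sc is not None:
            res = run_scenario(ps, life_table, sc, schedule)
        else:
            if ps.population == "PFD":
                trace = run_pfd_cohort(ps, schedule, life_table)
            else:
                trace = run_cohort(ps, life_table)
            res = accumulate_outcomes(trace, ps.payoffs, ps.discount_rate,
                                      ps.population)
        return flatten_outcomes(res)[outcome]

    base_outcome = evaluate(params, scenario)
    rows = []
    for name, base, apply in _owsa_variations(params, scenario):
        lo_v, hi_v = base * (1.0 - fraction), base * (1.0 + fraction)
        ps_lo, sc_lo = apply(params, scenario, lo_v)
        ps_hi, sc_hi = apply(params, scenario, hi_v)
        rows.append(TornadoRow(name, lo_v, hi_v,
                               evaluate(ps_lo, sc_lo), evaluate(ps_hi, sc_hi)))
    rows.sort(key=lambda r: r.width, reverse=True)
    return TornadoTable(outcome=outcome, base_outcome=base_outcome,
                        rows=tuple(rows))
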