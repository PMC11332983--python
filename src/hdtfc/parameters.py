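"""Model inputs: domain types, the packaged base-case registry, and
method-of-moments constructors for sampling distributions.

All monetary values are annual 2023 USD; utilities are per-year weights on
[0, 1]; trajectory deltas are TFC points relative to baseline.
"""
from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "TFC_MAX",
    "STAGES",
    "STAGE_TFC_RANGE",
    "sf_stage_of",
    "TrajectoryObservation",
    "StagePayoffs",
    "DMTScenario",
    "PinHdInputs",
    "ParameterSet",
    "DistributionSpec",
    "normal_from_mean_bounds",
    "beta_from_mean_bounds",
    "lognormal_from_mean_bounds",
    "base_case_registry",
    "load_parameters",
]

TFC_MAX = 13

#: Shoulson–Fahn stages and their inclusive TFC ranges; the five ranges
#: partition {0, ..., 13}.  Stage SF5 (TFC 0) is treated as death.
STAGES = ("SF1", "SF2", "SF3", "SF4", "SF5")
STAGE_TFC_RANGE: dict[str, tuple[int, int]] = {
    "SF1": (11, 13),
    "SF2": (7, 10),
    "SF3": (3, 6),
    "SF4": (1, 2),
    "SF5": (0, 0),
}

#: 95% central interval width in standard deviations (2 x 1.96).
_Z95_WIDTH = 3.92


def sf_stage_of(tfc: int) -> str:
    """Map a TFC score (0-13) to its Shoulson-Fahn stage label."""
    if not (0 <= int(tfc) <= TFC_MAX) or int(tfc) != tfc:
        raise ValidationError(f"TFC score must be an integer in [0, 13], got {tfc!r}")
    for stage, (lo, hi) in STAGE_TFC_RANGE.items():
        if lo <= tfc <= hi:
            return stage
    raise AssertionError("unreachable: stage ranges partition 0-13")


@dataclass(frozen=True)
class TrajectoryObservation:
    """Mean TFC change from baseline observed ``time`` years after entry."""

    time: float
    mean_delta: float
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.time}")
        if self.time == 0 and self.mean_delta != 0:
            raise ValidationError("delta at time 0 must be 0")
        if self.ci_lower is not None and self.ci_upper is not None:
            if not (self.ci_lower <= self.mean_delta <= self.ci_upper):
                raise ValidationError(
                    f"CI [{self.ci_lower}, {self.ci_upper}] must bracket mean "
                    f"{self.mean_delta}"
                )


@dataclass(frozen=True)
class StagePayoffs:
    """Annual utility and cost payoffs by Shoulson-Fahn stage.

    ``utility`` has keys SF1-SF4 plus ``PFD`` (prefunctional decline carries
    the general-population utility; SF5 is death and accrues no person-time).
    ``direct_cost`` / ``societal_cost`` have keys SF1-SF5.  The SF5 entry is
    only ever charged as a one-time terminal payoff, and only when
    ``apply_sf5_terminal_cost`` is set (off by default: the published
    base-case totals are only consistent with per-occupancy accrual and no
    terminal charge).
    """

    utility: Mapping[str, float]
    direct_cost: Mapping[str, float]
    societal_cost: Mapping[str, float]
    apply_sf5_terminal_cost: bool = False

    def __post_init__(self) -> None:
        for key in ("PFD", "SF1", "SF2", "SF3", "SF4"):
            if key not in self.utility:
                raise ConfigurationError(f"missing utility for {key}")
            u = self.utility[key]
            if not (0.0 <= u <= 1.0):
                raise ValidationError(f"utility[{key}]={u} outside [0, 1]")
        for name, table in (("direct_cost", self.direct_cost),
                            ("societal_cost", self.societal_cost)):
            for stage in STAGES:
                if stage not in table:
                    raise ConfigurationError(f"missing {name} for {stage}")
                if table[stage] < 0:
                    raise ValidationError(f"{name}[{stage}] must be >= 0")


@dataclass(frozen=True)
class DMTScenario:
    """Hypothetical disease-modifying treatment: progression is arrested for
    ``delay_years`` and multiplied by ``rate_ratio`` thereafter.

    ``delay_years`` is fractional-friendly so one-way sensitivity analysis
    can scale it; the named scenarios use whole years.
    """

    delay_years: float
    rate_ratio: float

    def __post_init__(self) -> None:
        if self.delay_years < 0:
            raise ValidationError("delay_years must be >= 0")
        if not (0.0 < self.rate_ratio <= 1.0):
            raise ValidationError("rate_ratio must be in (0, 1]")

    @property
    def is_identity(self) -> bool:
        return self.delay_years == 0 and self.rate_ratio == 1.0


IDENTITY_SCENARIO = DMTScenario(0, 1.0)


@dataclass(frozen=True)
class PinHdInputs:
    """Inputs to the prognostic-index composite score.

    The coefficient mapping must supply ``motor``, ``cognitive``,
    ``cag_age``, ``cag_offset``, ``center`` and ``scale``; the weights are
    configuration, not packaged constants.
    """

    tms: float
    sdmt: float
    cag: int
    age: float
    coefficients: Mapping[str, float] = field(default_factory=dict)


_POPULATIONS = ("PFD", "SF1", "SF2")
_DEFAULT_START_TFC = {"PFD": 13, "SF1": 12, "SF2": 9}


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated input set for a single model run."""

    population: str
    payoffs: StagePayoffs
    trajectories: tuple[TrajectoryObservation, ...]
    start_age: int = 40
    max_age: int = 100
    discount_rate: float = 0.03
    start_tfc: Optional[int] = None
    cag_repeats: Optional[int] = None
    dmt: DMTScenario = IDENTITY_SCENARIO
    pin_hd: Optional[PinHdInputs] = None

    def __post_init__(self) -> None:
        if self.population not in _POPULATIONS:
            raise ValidationError(
                f"population must be one of {_POPULATIONS}, got {self.population!r}")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValidationError("discount_rate must be in [0, 1)")
        if self.start_age >= self.max_age:
            raise ValidationError("start_age must be < max_age")
        if self.start_tfc is None:
            object.__setattr__(self, "start_tfc", _DEFAULT_START_TFC[self.population])
        if self.population == "PFD":
            if self.start_tfc != TFC_MAX:
                raise ValidationError("PFD population must start at TFC 13")
            if self.cag_repeats is None:
                object.__setattr__(self, "cag_repeats", 40)
        else:
            lo, hi = STAGE_TFC_RANGE[self.population]
            if not (lo <= self.start_tfc <= hi):
                raise ValidationError(
                    f"{self.population} start_tfc must lie in [{lo}, {hi}], "
                    f"got {self.start_tfc}")
        if len(self.trajectories) < 2:
            raise ValidationError("need at least two trajectory observations")

    @property
    def horizon(self) -> int:
        """Number of annual cycles from start_age to max_age."""
        return self.max_age - self.start_age

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Sampling distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution pinned to a base-case value.

    ``family`` is one of ``point``, ``normal``, ``beta``, ``lognormal``.
    Constructed via the ``*_from_mean_bounds`` helpers, which convert the
    printed 95% interval width to a standard deviation and match moments so
    the analytic mean equals the base case.
    """

    family: str
    base_value: float
    params: Mapping[str, float] = field(default_factory=dict)

    def mean(self) -> float:
        if self.family == "point":
            return self.base_value
        if self.family == "normal":
            return self.params["mean"]
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return a / (a + b)
        if self.family == "lognormal":
            mu, sigma = self.params["mu"], self.params["sigma"]
            return math.exp(mu + sigma * sigma / 2.0)
        raise ValidationError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "point":
            if size is None:
                return self.base_value
            return np.full(size, self.base_value)
        if self.family == "normal":
            return rng.normal(self.params["mean"], self.params["sd"], size)
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size)
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size)
        raise ValidationError(f"unknown family {self.family!r}")


def _interval_sd(lower: float, upper: float) -> float:
    if lower > upper:
        raise ValidationError(f"lower bound {lower} exceeds upper bound {upper}")
    return (upper - lower) / _Z95_WIDTH


def normal_from_mean_bounds(mean: float, lower: float, upper: float) -> DistributionSpec:
    """Normal spec with the printed mean and sd = (upper - lower) / 3.92.

    The printed mean is kept as the location even when the interval is
    asymmetric about it.
    """
    sd = _interval_sd(lower, upper)
    if sd == 0.0:
        return DistributionSpec("point", mean)
    return DistributionSpec(
        "normal", mean, {"mean": mean, "sd": sd, "lower": lower, "upper": upper})


def beta_from_mean_bounds(mean: float, lower: float, upper: float) -> DistributionSpec:
    """Beta spec by method of moments from the mean and 95% interval width."""
    if not (0.0 < mean < 1.0):
        raise ValidationError(f"beta mean must lie in (0, 1), got {mean}")
    sd = _interval_sd(lower, upper)
    if sd == 0.0:
        return DistributionSpec("point", mean)
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValidationError(
            f"implied variance {var:.6g} >= mean(1-mean) = {mean * (1 - mean):.6g}; "
            "no valid beta distribution")
    k = mean * (1.0 - mean) / var - 1.0
    return DistributionSpec(
        "beta", mean, {"alpha": mean * k, "beta": (1.0 - mean) * k})


def lognormal_from_mean_bounds(mean: float, lower: float, upper: float) -> DistributionSpec:
    """Log-normal spec matching the arithmetic mean and interval-derived sd."""
    if mean <= 0.0:
        raise ValidationError(f"log-normal mean must be > 0, got {mean}")
    sd = _interval_sd(lower, upper)
    if sd == 0.0:
        return DistributionSpec("point", mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return DistributionSpec("lognormal", mean, {"mu": mu, "sigma": math.sqrt(sigma2)})


# ---------------------------------------------------------------------------
# Packaged base-case registry
# ---------------------------------------------------------------------------

# Every entry is (base, lower, upper, family); family "point" means the
# value is not varied probabilistically.  Log-normal lower bounds of 0 are
# floored at 1e-6 when the distribution is constructed.
_BASE_CASE: dict[str, Any] = {
    "general": {
        "start_age": 40,
        "max_age": 100,
        "discount_rate": 0.03,
        "owsa_fraction": 0.25,
        "psa_simulations": 5000,
    },
    "pfd": {
        "cag_repeats": 40,
        "start_tfc": 13,
        "tms": 2,
        "sdmt": 50,
    },
    "trajectories": {
        # (time_years, mean_delta, ci_lower, ci_upper); 36-month deltas are
        # varied only through their correlation with the 12-month draw.
        "SF1": [
            (0.0, 0.0, None, None),
            (1.0, -0.910, -1.360, -0.620),
            (3.0, -1.989, None, None),
        ],
        "SF2": [
            (0.0, 0.0, None, None),
            (1.0, -0.440, -0.780, -0.130),
            (3.0, -1.974, None, None),
        ],
    },
    "start_tfc_baseline": {"SF1": 12.2, "SF2": 8.7},
    "utilities": {
        "PFD": (0.86, 0.84, 0.87, "beta"),
        "SF1": (0.78, 0.72, 0.85, "beta"),
        "SF2": (0.66, 0.59, 0.73, "beta"),
        "SF3": (0.54, 0.48, 0.61, "beta"),
        "SF4": (0.22, 0.11, 0.32, "beta"),
    },
    "direct_costs": {
        "SF1": (13183.0, 5723.0, 20644.0, "lognormal"),
        "SF2": (16549.0, 3786.0, 29311.0, "lognormal"),
        "SF3": (20189.0, 5404.0, 34974.0, "lognormal"),
        "SF4": (48031.0, 18983.0, 77080.0, "lognormal"),
        "SF5": (25217.0, 0.0, 55668.0, "lognormal"),
    },
    "societal_costs": {
        "SF1": (30691.0, 11333.0, 50048.0, "lognormal"),
        "SF2": (41676.0, 15390.0, 67962.0, "lognormal"),
        "SF3": (110142.0, 38727.0, 185849.0, "lognormal"),
        "SF4": (58561.0, 1724.0, 115398.0, "lognormal"),
        "SF5": (36409.0, 1072.0, 71746.0, "lognormal"),
    },
}


def base_case_registry() -> dict[str, Any]:
    """A deep copy of the packaged base-case parameter registry, including
    the 95% bounds and distribution family of every varied parameter."""
    return json.loads(json.dumps(_BASE_CASE))


def _default_payoffs() -> StagePayoffs:
    reg = _BASE_CASE
    return StagePayoffs(
        utility={k: v[0] for k, v in reg["utilities"].items()},
        direct_cost={k: v[0] for k, v in reg["direct_costs"].items()},
        societal_cost={k: v[0] for k, v in reg["societal_costs"].items()},
    )


def _default_trajectories(population: str) -> tuple[TrajectoryObservation, ...]:
    key = "SF1" if population == "PFD" else population
    return tuple(TrajectoryObservation(*row) for row in _BASE_CASE["trajectories"][key])


def _as_mapping(config) -> Mapping[str, Any]:
    if config is None:
        return {}
    if isinstance(config, Mapping):
        return config
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith(".json"):
            return json.loads(text)
        import yaml

        return yaml.safe_load(text) or {}
    raise ConfigurationError(f"unsupported config type {type(config)!r}")


def load_parameters(config=None, *, population: Optional[str] = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a configuration document.

    ``config`` may be ``None``, a mapping, or a path to a YAML/JSON file.
    Unspecified fields take the packaged base-case values.  ``population``
    may be given either in the document or as a keyword; the keyword wins.
    """
    doc = dict(_as_mapping(config))
    pop = population or doc.pop("population", None)
    if pop is None:
        raise ConfigurationError("missing required field 'population'")
    if pop not in _POPULATIONS:
        raise ValidationError(f"population must be one of {_POPULATIONS}, got {pop!r}")

    general = _BASE_CASE["general"]
    payoffs = _default_payoffs()
    if any(k in doc for k in ("utilities", "direct_costs", "societal_costs",
                              "apply_sf5_terminal_cost")):
        payoffs = StagePayoffs(
            utility={**dict(payoffs.utility), **doc.get("utilities", {})},
            direct_cost={**dict(payoffs.direct_cost), **doc.get("direct_costs", {})},
            societal_cost={**dict(payoffs.societal_cost),
                           **doc.get("societal_costs", {})},
            apply_sf5_terminal_cost=doc.get("apply_sf5_terminal_cost", False),
        )

    if "trajectories" in doc:
        trajectories = tuple(
            TrajectoryObservation(
                time=row["time_years"],
                mean_delta=row["mean_delta"],
                ci_lower=row.get("ci_lower"),
                ci_upper=row.get("ci_upper"),
            )
            for row in doc["trajectories"]
        )
    else:
        trajectories = _default_trajectories(pop)

    dmt = IDENTITY_SCENARIO
    if "dmt" in doc and doc["dmt"] is not None:
        d = doc["dmt"]
        dmt = DMTScenario(d.get("delay_years", 0), d.get("rate_ratio", 1.0))

    pin_hd = None
    if "pin_hd" in doc and doc["pin_hd"] is not None:
        p = doc["pin_hd"]
        pin_hd = PinHdInputs(
            tms=p.get("tms", _BASE_CASE["pfd"]["tms"]),
            sdmt=p.get("sdmt", _BASE_CASE["pfd"]["sdmt"]),
            cag=p.get("cag", _BASE_CASE["pfd"]["cag_repeats"]),
            age=p.get("age", general["start_age"]),
            coefficients=p.get("coefficients", {}),
        )

    known = {"start_age", "max_age", "discount_rate", "start_tfc", "cag_repeats"}
    unknown = set(doc) - known - {
        "utilities", "direct_costs", "societal_costs", "apply_sf5_terminal_cost",
        "trajectories", "dmt", "pin_hd"}
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")

    return ParameterSet(
        population=pop,
        payoffs=payoffs,
        trajectories=trajectories,
        start_age=int(doc.get("start_age", general["start_age"])),
        max_age=int(doc.get("max_age", general["max_age"])),
        discount_rate=float(doc.get("discount_rate", general["discount_rate"])),
        start_tfc=doc.get("start_tfc"),
        cag_repeats=doc.get("cag_repeats"),
        dmt=dmt,
        pin_hd=pin_hd,
    )
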