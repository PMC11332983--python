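"""Readers and writers for the standard text formats, packaged fixtures,
and run manifests.

All CSVs are plain text with ``#`` comment lines.  Formats:

* life table: columns ``age,qx``
* trajectories: columns ``time_years,mean_delta,ci_lower,ci_upper``
* onset curves: columns ``cag,age,cumulative_probability``
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .engine import STATE_COLUMNS, CohortTrace, LifeTable, OutcomeSet
from .exceptions import DataError
from .onset import OnsetCurve, fit_onset_curve
from .parameters import ParameterSet, TrajectoryObservation

__all__ = [
    "read_life_table",
    "write_life_table",
    "default_life_table",
    "read_trajectories",
    "read_onset_points",
    "default_onset_points",
    "fit_packaged_curves",
    "write_trace_csv",
    "outcomes_to_dict",
    "RunManifest",
]


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_life_table(path) -> LifeTable:
    """Load a life table CSV with columns ``age,qx`` (comments allowed)."""
    df = _read_csv(path)
    if not {"age", "qx"}.issubset(df.columns):
        raise DataError(f"life table {path} must have columns age,qx")
    df = df.sort_values("age")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def write_life_table(table: LifeTable, path) -> None:
    pd.DataFrame({"age": table.ages, "qx": table.qx}).to_csv(path, index=False)


def default_life_table() -> LifeTable:
    """The vendored US all-population background-mortality fixture."""
    with resources.as_file(
            resources.files("hdtfc.data") / "life_table_us_total.csv") as p:
        return read_life_table(p)


def read_trajectories(path) -> tuple[TrajectoryObservation, ...]:
    df = _read_csv(path)
    required = {"time_years", "mean_delta"}
    if not required.issubset(df.columns):
        raise DataError(f"trajectory file {path} must have columns "
                        "time_years,mean_delta[,ci_lower,ci_upper]")
    out = []
    for _, row in df.iterrows():
        ci_lo = row.get("ci_lower")
        ci_hi = row.get("ci_upper")
        out.append(TrajectoryObservation(
            time=float(row["time_years"]), mean_delta=float(row["mean_delta"]),
            ci_lower=None if pd.isna(ci_lo) else float(ci_lo),
            ci_upper=None if pd.isna(ci_hi) else float(ci_hi)))
    return tuple(out)


def read_onset_points(path) -> dict[int, list[tuple[float, float]]]:
    """Cumulative onset points grouped by CAG stratum."""
    df = _read_csv(path)
    required = {"cag", "age", "cumulative_probability"}
    if not required.issubset(df.columns):
        raise DataError(f"onset file {path} must have columns "
                        "cag,age,cumulative_probability")
    out: dict[int, list[tuple[float, float]]] = {}
    for cag, grp in df.groupby("cag"):
        grp = grp.sort_values("age")
        out[int(cag)] = list(zip(grp["age"].astype(float),
                                 grp["cumulative_probability"].astype(float)))
    return out


def default_onset_points() -> dict[int, list[tuple[float, float]]]:
    """The packaged onset-curve fixture (a clearly labeled stand-in, not
    source cohort data)."""
    with resources.as_file(
            resources.files("hdtfc.data") / "onset_curves.csv") as p:
        return read_onset_points(p)


def fit_packaged_curves() -> dict[int, OnsetCurve]:
    """Fitted cumulative onset curve per CAG stratum in the packaged fixture."""
    return {cag: fit_onset_curve(points, cag)
            for cag, points in default_onset_points().items()}


def write_trace_csv(trace: CohortTrace, path) -> None:
    """Tidy per-cycle occupancy: columns cycle, age, state, occupancy."""
    T = trace.occupancy.shape[0]
    records = []
    for t in range(T):
        for j, state in enumerate(STATE_COLUMNS):
            records.append({"cycle": t, "age": trace.start_age + t,
                            "state": state, "occupancy": trace.occupancy[t, j]})
    pd.DataFrame(records).to_csv(path, index=False)


def outcomes_to_dict(outcomes) -> dict:
    """JSON-ready nested dict of an OutcomeSet or IncrementalSet."""
    doc = {
        "population": outcomes.population,
        "life_years": dataclasses.asdict(outcomes.life_years),
        "qalys": dataclasses.asdict(outcomes.qalys),
        "qalys_by_stage": {k: dataclasses.asdict(v)
                           for k, v in outcomes.qalys_by_stage.items()},
        "total_cost": dataclasses.asdict(outcomes.total_cost),
        "cost": {f"{cat}/{stage}": dataclasses.asdict(v)
                 for (cat, stage), v in outcomes.cost.items()},
        "standard_care_cost": dataclasses.asdict(outcomes.cost_by_category("direct")),
        "societal_cost": dataclasses.asdict(outcomes.cost_by_category("societal")),
    }
    if isinstance(outcomes, OutcomeSet):
        doc["median_survival_years"] = outcomes.median_survival_years
    return doc


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted alongside every result file."""

    population: str
    seed: Optional[int]
    software_version: str
    timestamp: str
    parameter_digest: str
    input_digests: dict

    @classmethod
    def create(cls, params: ParameterSet, seed: Optional[int] = None,
               input_files: Optional[dict] = None) -> "RunManifest":
        digest = hashlib.sha256(
            json.dumps(_params_doc(params), sort_keys=True).encode()).hexdigest()
        files = {}
        for name, path in (input_files or {}).items():
            files[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        return cls(
            population=params.population,
            seed=seed,
            software_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            parameter_digest=digest,
            input_digests=files,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _params_doc(params: ParameterSet) -> dict:
    doc = dataclasses.asdict(params)
    doc["payoffs"] = {
        "utility": dict(params.payoffs.utility),
        "direct_cost": dict(params.payoffs.direct_cost),
        "societal_cost": dict(params.payoffs.societal_cost),
        "apply_sf5_terminal_cost": params.payoffs.apply_sf5_terminal_cost,
    }
    return doc
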