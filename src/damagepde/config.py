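"""Scenario configs as TOML or JSON files.

Sections map onto the domain types: ``[grid]``, ``[rates]``, ``[feedback]``,
``[partition]``, ``[dediff]``, ``[boundary]``, ``[initial]``, ``[run]`` and
``[calibration]``.  Every key has a documented default; unknown keys are
rejected with the offending path so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Any

from .experiments import Scenario
from .model_core import DeathModel, DediffRule, FeedbackParams, ModelParams, PartitionFractions

_SECTIONS = {
    "name",
    "grid",
    "rates",
    "feedback",
    "partition",
    "dediff",
    "boundary",
    "initial",
    "run",
    "calibration",
}


def _take(section: dict[str, Any], path: str, known: set[str]) -> None:
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in [{path}]")


def load_scenario(path: str | Path) -> Scenario:
    """Parse a scenario config file (.toml or .json)."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    elif path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use .toml or .json)")
    return scenario_from_dict(data, default_name=path.stem)


def scenario_from_dict(data: dict[str, Any], default_name: str = "scenario") -> Scenario:
    _take(data, "<root>", _SECTIONS)

    grid = dict(data.get("grid", {}))
    _take(grid, "grid", {"domain_length", "num_cells"})

    rates = dict(data.get("rates", {}))
    _take(rates, "rates", {"v_P", "v_W", "lam_P_hat", "lam_R_hat", "p1_hat", "p2_hat", "death", "delta", "delta_P"})
    death_kind = rates.get("death", "linear")
    death = DeathModel(death_kind, rates.get("delta", 0.6 if death_kind == "linear" else 0.5))

    fb_sec = dict(data.get("feedback", {}))
    _take(fb_sec, "feedback", {"k1", "k2", "k3", "k4", "m1", "m2", "m3", "m4", "p2_complement"})
    feedback = FeedbackParams(
        p1_hat=rates.get("p1_hat", 0.5),
        p2_hat=rates.get("p2_hat", 1.0 - rates.get("p1_hat", 0.5)),
        lam_P_hat=rates.get("lam_P_hat", 1.0),
        lam_R_hat=rates.get("lam_R_hat", 0.0),
        **fb_sec,
    )

    part = dict(data.get("partition", {}))
    _take(part, "partition", {"alpha1", "beta1", "gamma1"})
    fractions = PartitionFractions.from_first(
        part.get("alpha1", 0.5), part.get("beta1", 0.5), part.get("gamma1", 1.0 / 3.0)
    )

    ded = dict(data.get("dediff", {}))
    _take(ded, "dediff", {"variant", "x_c", "rho", "rho_min", "rho_max", "loss_form"})
    dediff = DediffRule(**{"variant": "constant", **ded})

    boundary = dict(data.get("boundary", {}))
    _take(boundary, "boundary", {"inflow"})

    run = dict(data.get("run", {}))
    _take(run, "run", {"t_end", "steady_tol", "t_max", "dt", "courant", "snapshot_times", "no_partition", "remap_method"})

    params = ModelParams(
        v_P=rates.get("v_P", 0.05),
        v_W=rates.get("v_W", 0.05),
        fractions=fractions,
        feedback=feedback,
        death=death,
        dediff=dediff,
        inflow=boundary.get("inflow", 0.0),
        courant=run.get("courant", 0.25),
        delta_P=rates.get("delta_P", 0.0),
        remap_method=run.get("remap_method", "scatter"),
    )

    initial = dict(data.get("initial", {"kind": "indicator", "height": 10.0, "interval": (0.2, 0.4)}))
    _take(initial, "initial", {"kind", "height", "interval", "amplitude", "center", "width"})
    if "interval" in initial:
        initial["interval"] = tuple(initial["interval"])

    calibration = data.get("calibration")
    if calibration is not None:
        calibration = dict(calibration)
        _take(calibration, "calibration", {"target_ratio", "target_W", "bracket", "rel_tol", "ratio_only"})
        if "bracket" in calibration:
            calibration["bracket"] = tuple(calibration["bracket"])

    return Scenario(
        name=data.get("name", default_name),
        params=params,
        domain_length=grid.get("domain_length", 2.0),
        num_cells=grid.get("num_cells", 400),
        initial=initial,
        t_end=run.get("t_end"),
        steady_tol=run.get("steady_tol", 1e-6),
        t_max=run.get("t_max", 400.0),
        dt=run.get("dt"),
        snapshot_times=tuple(run.get("snapshot_times", ())),
        calibration=calibration,
        no_partition=run.get("no_partition", False),
    )
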