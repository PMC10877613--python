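"""Config-file schema and tabular writers.

Networks, dose schedules and circuit parameter sets round-trip through a
small YAML/JSON schema; trajectories are written as CSV (``time_s`` then
one nM column per species in builder order) and metrics as JSON.  Unknown
keys in config mappings are rejected so typos fail loudly before any
simulation runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .crn import (
    ConfigurationError,
    DoseEvent,
    DoseSchedule,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    Trajectory,
)
from .circuit import CircuitParams

__all__ = [
    "network_to_dict", "network_from_dict",
    "schedule_to_dict", "schedule_from_dict",
    "circuit_params_from_dict", "circuit_params_to_dict",
    "load_config", "save_config",
    "trajectory_to_csv", "metrics_to_json",
]


def _check_keys(d: Mapping[str, Any], allowed: set[str], what: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown keys in {what}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


def network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "species": [
            {"name": s.name, "initial_concentration": s.initial_concentration,
             "strandedness": s.strandedness, "role": s.role}
            for s in network.species
        ],
        "reactions": [
            {"label": r.label, "reactants": list(r.reactants),
             "products": list(r.products), "k_forward": r.k_forward,
             "k_backward": r.k_backward,
             **({"mode_rates": {m: list(v) for m, v in r.mode_rates.items()}}
                if r.mode_rates else {})}
            for r in network.reactions
        ],
    }


def network_from_dict(d: Mapping[str, Any]) -> ReactionNetwork:
    _check_keys(d, {"species", "reactions"}, "network")
    species = []
    for s in d["species"]:
        _check_keys(s, {"name", "initial_concentration", "strandedness",
                        "role"}, "species")
        species.append(SpeciesSpec(**s))
    reactions = []
    for r in d["reactions"]:
        _check_keys(r, {"label", "reactants", "products", "k_forward",
                        "k_backward", "mode_rates"}, "reaction")
        mode_rates = r.get("mode_rates")
        if mode_rates is not None:
            mode_rates = {m: tuple(v) for m, v in mode_rates.items()}
        reactions.append(Reaction(
            reactants=tuple(r["reactants"]), products=tuple(r["products"]),
            k_forward=r["k_forward"], k_backward=r.get("k_backward", 0.0),
            label=r.get("label", ""), mode_rates=mode_rates,
        ))
    return ReactionNetwork(species, reactions)


def schedule_to_dict(schedule: DoseSchedule) -> dict:
    return {
        "horizon": schedule.horizon,
        "events": [
            {"time": e.time, "species": e.species, "amount": e.amount}
            for e in schedule.events
        ],
    }


def schedule_from_dict(d: Mapping[str, Any]) -> DoseSchedule:
    _check_keys(d, {"horizon", "events"}, "schedule")
    events = []
    for e in d["events"]:
        _check_keys(e, {"time", "species", "amount"}, "dose event")
        events.append(DoseEvent(**e))
    return DoseSchedule(events=events, horizon=d["horizon"])


_PARAM_KEYS = {"k_forward", "k_backward", "k_d1", "k_d2", "init",
               "dose_amount"}


def circuit_params_to_dict(params: CircuitParams) -> dict:
    return {
        "k_forward": params.k_forward, "k_backward": params.k_backward,
        "k_d1": params.k_d1, "k_d2": params.k_d2,
        "init": dict(params.init), "dose_amount": params.dose_amount,
    }


def circuit_params_from_dict(d: Mapping[str, Any]) -> CircuitParams:
    _check_keys(d, _PARAM_KEYS, "circuit params")
    return CircuitParams(**d)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ConfigurationError(
        f"unsupported config extension {path.suffix!r} (use .yaml/.json)"
    )


def save_config(data: Mapping[str, Any], path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(dict(data), sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        raise ConfigurationError(
            f"unsupported config extension {path.suffix!r} (use .yaml/.json)"
        )


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """CSV columns: time_s, then one nM column per species (builder order)."""
    traj.to_frame().to_csv(path, index=False)


def metrics_to_json(data: Mapping[str, Any], path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting."""
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
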