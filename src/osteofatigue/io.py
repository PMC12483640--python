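"""Configuration handling and result serialization.

Units are fixed across all interfaces and recorded once per run manifest:
time in days, speed in m/s, stress in MPa, strain rate in 1/s.  Floats are
written with 10 significant digits so re-runs are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .model import BoneState, LoadingCondition
from .params import ModelParameters, preset
from .simulation import (
    SimulationResult,
    race_loading,
    rest_loading,
    training_loading,
)

__all__ = [
    "FLOAT_FMT",
    "load_config",
    "validate_keys",
    "params_from_config",
    "loading_from_config",
    "state_from_config",
    "write_trace",
    "write_manifest",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

UNITS = {"time": "day", "speed": "m/s", "stress": "MPa", "strain_rate": "1/s"}


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML (or JSON) configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: top level must be a mapping")
    return dict(data)


def validate_keys(config: Mapping[str, Any], allowed: set[str], context: str) -> None:
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(
            f"unknown {context} keys: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def params_from_config(config: Mapping[str, Any]) -> ModelParameters:
    """Resolve ``preset`` plus flat ``overrides`` into a parameter set."""
    base = preset(config.get("preset", "fitted"))
    overrides = config.get("overrides") or {}
    if not isinstance(overrides, Mapping):
        raise ValueError("'overrides' must be a mapping of parameter: value")
    unknown = set(overrides) - set(ModelParameters.field_names())
    if unknown:
        raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
    return base.replace(**{k: float(v) for k, v in overrides.items()})


_NAMED_CONDITIONS = {
    "rest": rest_loading,
    "training": training_loading,
    "race": race_loading,
}


def loading_from_config(spec: Any, params: ModelParameters) -> LoadingCondition:
    """A loading condition from a name ("rest"/"training"/"race") or mapping."""
    if isinstance(spec, str):
        try:
            maker = _NAMED_CONDITIONS[spec]
        except KeyError:
            raise ValueError(
                f"unknown named condition {spec!r}; use {sorted(_NAMED_CONDITIONS)}"
            ) from None
        return maker(params) if spec == "rest" else maker()
    if isinstance(spec, Mapping):
        validate_keys(spec, {"sigma", "strain_rate", "vn"}, "loading condition")
        return LoadingCondition(
            sigma=float(spec["sigma"]),
            strain_rate=float(spec["strain_rate"]),
            vn=float(spec.get("vn", 0.0)),
        )
    raise ValueError(f"cannot interpret loading condition {spec!r}")


def state_from_config(spec: Mapping[str, Any]) -> BoneState:
    validate_keys(spec, {"fBM", "D"}, "initial state")
    return BoneState(fBM=float(spec["fBM"]), D=float(spec.get("D", 0.0)))


def write_trace(result: SimulationResult, path: str | Path) -> None:
    """Tidy per-day trace CSV: day, fBM, D, Sv, E, psi, AOBL, AOCL, Df, Dr."""
    result.trace.to_csv(path, index=False, float_format=FLOAT_FMT)


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: Mapping[str, Any],
    seed: int | None = None,
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Write the fully resolved run manifest next to a command's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "command": command,
        "seed": seed,
        "units": UNITS,
        "config": dict(config),
        "config_hash": _config_hash(config),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
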