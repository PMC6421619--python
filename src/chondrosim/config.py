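"""Run configuration: a JSON dialect for fully specifying a simulation.

The config file is a single flat JSON object; every key maps to a
:class:`~chondrosim.scenarios.ScenarioSpec` field, with two run-level extras
(``out_dir``, ``log_level``) and one nested object, ``param_overrides``,
whose keys must be dimensionless parameter names. Unknown keys are errors —
a misspelled parameter must never silently fall back to its default. Every
default that is filled in is logged at INFO.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from chondrosim.params import DimensionlessParams, ValidationError
from chondrosim.scenarios import ScenarioSpec

__all__ = ["RunConfig", "load_config", "save_config"]

logger = logging.getLogger("chondrosim")

_SCENARIO_KEYS = {
    "name": str,
    "gf_config": str,
    "seeding_width": float,
    "duration_months": float,
    "n_nodes": int,
    "eps": float,
    "rtol": float,
    "atol": float,
    "output_cadence_months": float,
}
_RUN_KEYS = {"out_dir": str, "log_level": str}


@dataclass(frozen=True)
class RunConfig:
    """A scenario plus where and how verbosely to write its results."""

    spec: ScenarioSpec
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValidationError(
                f"log_level must be DEBUG/INFO/WARNING/ERROR, got {self.log_level!r}")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {k: getattr(self.spec, k) for k in _SCENARIO_KEYS}
        d["param_overrides"] = dict(self.spec.param_overrides)
        d["out_dir"] = self.out_dir
        d["log_level"] = self.log_level
        return d


def _coerce(key: str, value: Any, typ: type) -> Any:
    if typ is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValidationError(f"config key {key!r}: expected a number, got {value!r}")
        return float(value)
    if typ is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ValidationError(f"config key {key!r}: expected an integer, got {value!r}")
        return value
    if not isinstance(value, str):
        raise ValidationError(f"config key {key!r}: expected a string, got {value!r}")
    return value


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON run configuration.

    Missing keys take the documented defaults (each filled default is
    logged); unknown keys, type mismatches and invariant violations raise
    :class:`~chondrosim.params.ValidationError` naming the key.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as err:
            raise ValidationError(f"config {path}: not valid JSON ({err})") from err
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path}: top level must be a JSON object")

    known = set(_SCENARIO_KEYS) | set(_RUN_KEYS) | {"param_overrides"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"config {path}: unknown key(s) {sorted(unknown)}")

    overrides = raw.get("param_overrides", {})
    if not isinstance(overrides, dict):
        raise ValidationError("config key 'param_overrides': expected an object")
    valid_params = set(DimensionlessParams.__dataclass_fields__) - {"skip_validation"}
    for k, v in overrides.items():
        if k not in valid_params:
            raise ValidationError(
                f"config key 'param_overrides.{k}': not a dimensionless parameter")
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ValidationError(
                f"config key 'param_overrides.{k}': expected a number, got {v!r}")
    # overrides must respect the model invariants (ranges, orderings)
    ScenarioSpec(param_overrides={k: float(v) for k, v in overrides.items()}
                 ).resolved_params()

    spec_kwargs: dict[str, Any] = {}
    for key, typ in _SCENARIO_KEYS.items():
        if key in raw:
            spec_kwargs[key] = _coerce(key, raw[key], typ)
        else:
            default = getattr(ScenarioSpec, "__dataclass_fields__")[key].default
            logger.info("config %s: using default %s = %r", path.name, key, default)
    spec = ScenarioSpec(param_overrides={k: float(v) for k, v in overrides.items()},
                        **spec_kwargs)

    run_kwargs: dict[str, Any] = {}
    for key, typ in _RUN_KEYS.items():
        if key in raw:
            run_kwargs[key] = _coerce(key, raw[key], typ)
        else:
            default = getattr(RunConfig, "__dataclass_fields__")[key].default
            logger.info("config %s: using default %s = %r", path.name, key, default)
    return RunConfig(spec=spec, **run_kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config that :func:`load_config` round-trips to ``cfg``."""
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
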