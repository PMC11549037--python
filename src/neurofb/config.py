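"""Declarative run configuration for the command-line interface.

One YAML (or JSON) file controls everything a run needs: the band scheme,
the threshold multiplier, epoch/window lengths, session-plan constants and
simulator parameters.  Unknown or ill-typed keys raise a
:class:`ConfigError` naming the offending key, so a typo in a home-deployed
config fails loudly instead of silently changing the training protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .spectral import BandDefinition, BandScheme, default_scheme

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class SimulatorConfig:
    profile: str = "pain"  # "pain" or "painfree"
    responsiveness: float = 0.0
    artifact_rate: float = 1.0
    pink_noise_scale: float = 20.0
    pink_noise_exponent: float = 1.0
    channel_asymmetry: float = 1.0


@dataclass
class RunConfig:
    fs: float = 250.0
    decision_epoch: float = 1.0
    baseline_epoch: float = 2.0
    threshold_multiplier: float = 1.0
    impedance_limit_kohm: float = 50.0
    resting_duration: float = 120.0
    round_duration: float = 150.0
    break_duration: float = 30.0
    n_rounds: int = 5
    bands: BandScheme = field(default_factory=default_scheme)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)


_NUMERIC_KEYS = {
    "fs",
    "decision_epoch",
    "baseline_epoch",
    "threshold_multiplier",
    "impedance_limit_kohm",
    "resting_duration",
    "round_duration",
    "break_duration",
    "n_rounds",
}


def _parse_bands(spec_list) -> BandScheme:
    if not isinstance(spec_list, list):
        raise ConfigError("key 'bands' must be a list of band mappings")
    bands = []
    for i, b in enumerate(spec_list):
        if not isinstance(b, dict):
            raise ConfigError(f"key 'bands[{i}]' must be a mapping")
        extra = set(b) - {"name", "f_low", "f_high", "direction"}
        if extra:
            raise ConfigError(
                f"key 'bands[{i}].{sorted(extra)[0]}' is not a recognised field"
            )
        try:
            bands.append(BandDefinition(**b))
        except (TypeError, ValueError) as err:
            raise ConfigError(f"key 'bands[{i}]': {err}") from err
    try:
        return BandScheme(bands=tuple(bands))
    except ValueError as err:
        raise ConfigError(f"key 'bands': {err}") from err


def _parse_simulator(d) -> SimulatorConfig:
    if not isinstance(d, dict):
        raise ConfigError("key 'simulator' must be a mapping")
    valid = {f.name for f in fields(SimulatorConfig)}
    for k, v in d.items():
        if k not in valid:
            raise ConfigError(f"key 'simulator.{k}' is not a recognised field")
        if k == "profile":
            if v not in ("pain", "painfree"):
                raise ConfigError(
                    "key 'simulator.profile' must be 'pain' or 'painfree'"
                )
        elif not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"key 'simulator.{k}' must be a number, got {v!r}")
    return SimulatorConfig(**d)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a run configuration; None → all defaults."""
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    cfg = RunConfig()
    for key, value in raw.items():
        if key in _NUMERIC_KEYS:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"key {key!r} must be a number, got {value!r}")
            if value <= 0:
                raise ConfigError(f"key {key!r} must be positive, got {value!r}")
            setattr(cfg, key, type(getattr(cfg, key))(value))
        elif key == "bands":
            cfg.bands = _parse_bands(value)
        elif key == "simulator":
            cfg.simulator = _parse_simulator(value)
        else:
            raise ConfigError(f"key {key!r} is not a recognised configuration key")
    return cfg
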