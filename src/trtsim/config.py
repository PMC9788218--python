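"""Flat key/value configuration with the published model defaults.

A config file is a flat YAML mapping (``key: value`` lines); every key is
optional and defaults to the published parameter value.  Derived fields
follow the same rules as the domain types: the decay rate is always
ln 2 / half_life_h, and v/Vm default from V0, N0 and Nm unless set
explicitly.  Unknown keys are rejected so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .dosimetry import DoseConversion
from .errors import ConfigError, TrtSimError
from .pk_delivery import DeliveryRates
from .tumor_response import TumorParams

__all__ = ["ModelConfig", "load_config", "save_config"]

_RATE_KEYS = ("a12", "a13", "a14", "a21", "a31", "half_life_h")
_CONV_KEYS = ("gy_per_h_per_mbq", "tumor_mass_g")
_TUMOR_KEYS = ("lam", "b", "c", "t0", "N0", "Nm", "V0", "v", "Vm")
_OUTPUT_KEYS = ("delimiter",)
_ALL_KEYS = _RATE_KEYS + _CONV_KEYS + _TUMOR_KEYS + _OUTPUT_KEYS


@dataclass(frozen=True)
class ModelConfig:
    """Aggregated model parameters plus output options."""

    rates: DeliveryRates = field(default_factory=DeliveryRates)
    conv: DoseConversion = field(default_factory=DoseConversion)
    tumor: TumorParams = field(default_factory=TumorParams)
    delimiter: str = "\t"

    def to_dict(self) -> dict:
        out = {}
        for key in _RATE_KEYS:
            out[key] = getattr(self.rates, key)
        for key in _CONV_KEYS:
            out[key] = getattr(self.conv, key)
        for key in _TUMOR_KEYS:
            out[key] = getattr(self.tumor, key)
        out["delimiter"] = self.delimiter
        return out

    def digest(self) -> str:
        """Short hash of the full parameter set, for run logging."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _build(raw: dict) -> ModelConfig:
    unknown = set(raw) - set(_ALL_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key, value in raw.items():
        if key in _OUTPUT_KEYS:
            if not isinstance(value, str):
                raise ConfigError(f"config key {key!r} must be a string")
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"config key {key!r} must be numeric, got {value!r}")
    try:
        rates = DeliveryRates(**{k: raw[k] for k in _RATE_KEYS if k in raw})
        conv = DoseConversion(**{k: raw[k] for k in _CONV_KEYS if k in raw})
        tumor = TumorParams(**{k: raw[k] for k in _TUMOR_KEYS if k in raw})
    except TrtSimError as exc:
        raise ConfigError(str(exc)) from exc
    return ModelConfig(rates=rates, conv=conv, tumor=tumor,
                       delimiter=raw.get("delimiter", "\t"))


def load_config(path: str | Path | None) -> ModelConfig:
    """Load a flat YAML config; ``None`` or an empty file gives all defaults."""
    if path is None:
        return ModelConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key/value mapping")
    return _build(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Serialize a config so that ``load_config`` round-trips it losslessly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
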