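"""Run configuration: defaults plus optional YAML overrides."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "constants": {
        "k1k2": "lueker2000",  # or "dickson_millero"
        "boron": "uppstrom",  # or "lee"
    },
    "seawater": {
        "default_salinity": 35.5,
        "default_pH_sw": 8.07,  # mid-range of the observed 8.03-8.10
    },
    "boron": {
        "d11B_sw": 39.61,  # ‰, modern mean seawater
        "alpha_B": 1.0272,
    },
    "thermometry": {
        "chronology_r2": 0.5,
    },
    "rate_model": {
        "parameterisation": "arrhenius",
        "fixed_T": 21.7,  # °C, annual average for scenario 3
        "aquaria": {"slope": 0.51, "intercept": 4.28},
    },
}


def _deep_update(base: dict, other: dict) -> dict:
    for key, val in other.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Default configuration, deep-updated from a YAML file when given."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(cfg, overrides)
    return cfg
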