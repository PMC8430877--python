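"""Shared defaults and YAML configuration handling.

Every physical constant and tunable used across the package is surfaced
here so a single YAML file can override them end to end.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from ppas.sampler_model import SamplerParams
from ppas.synthetic import ScenarioConfig, scenario_from_dict
from ppas.units import GasConditions

DEFAULTS: dict = {
    "gas_conditions": {"temperature": 298.15, "pressure": 101325.0},
    "sampler": {
        "A_s": 2.25e-4,
        "delta": 5.5e-4,
        "K_SA": 10.0,
        "k_O": 2.53e-3 / 2.25e-4,
        "k_reac": 100.0,
        "C_cap": 1.8,
        "R_s": 2.53e-3,
        "stoich": 2.0,
    },
    "calibration": {"slope": 10.0, "intercept": 0.0},
    "guidelines": [
        {"label": "OSHA_PEL", "threshold_ppbv": 500.0},
        {"label": "AEGL-1", "threshold_ppbv": 500.0,
         "min_duration": 10.0, "max_duration": 480.0},
    ],
    "scenario": {
        "product_type": "liquid",
        "amount": 200.0,
        "plateau_ppbv": 1160.0,
        "rise_rate": 1.0,
        "lag_time_h": 1.5,
        "seed": 0,
    },
    "generator": {"noise_cv": 0.05, "n_replicates": 3,
                  "blank_extract_g_per_L": 0.1, "V_E": 0.01},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with the YAML file at ``path`` (if given)."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path, "r", encoding="utf-8") as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"{path}: top level of config must be a mapping")
    return _deep_merge(DEFAULTS, override)


def dump_defaults(path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(DEFAULTS, fh, sort_keys=False)


def config_hash(cfg: dict) -> str:
    """Short deterministic digest of an effective configuration."""
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def sampler_params_from_config(cfg: dict) -> SamplerParams:
    return SamplerParams(**cfg["sampler"])


def gas_conditions_from_config(cfg: dict) -> GasConditions:
    return GasConditions(**cfg["gas_conditions"])


def scenario_from_config(cfg: dict) -> ScenarioConfig:
    return scenario_from_dict(cfg["scenario"])
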