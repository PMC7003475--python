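"""Run configuration: YAML schema, defaults, and resolution.

Every run artifact embeds the fully resolved configuration (defaults
included) so that re-running from an emitted config reproduces results
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["ConfigError", "DEFAULTS", "load_config", "resolve", "config_hash"]


class ConfigError(ValueError):
    """Configuration schema violation, naming the offending key."""


DEFAULTS: dict = {
    "seed": 0,
    "network": {
        "path": None,            # JSON network file; if null, synthesize
        "n_generations": 2,
        "root_diameter": 0.35,
        "root_length": 3.0,
        "gamma": 2.27,
    },
    "stenosis": None,            # {segment_id, center_fraction, stenosed_length, area_reduction, shape}
    "states": {
        "resting": {"systolic": 115.0, "diastolic": 74.0,
                    "cardiac_output": 5.19, "heart_rate": 65.0,
                    "coronary_resistance_factor": 1.0},
        "hyperaemic": {"systolic": 115.0, "diastolic": 70.0,
                       "cardiac_output": 7.6, "heart_rate": 90.0,
                       "coronary_resistance_factor": 0.22},
    },
    "tier1": {
        "coronary_flow_fraction": 0.04,
        "coronary_left_fraction": 0.7,
        "tolerance": 0.02,
    },
    "solver": {
        "target_dx": 0.1,
        "dt": 1.0e-3,
        "periodic_tolerance": 1.0e-3,
        "max_cycles": 10,
        "picard_tol": 1.0e-8,
        "output_dt": 1.0e-3,
    },
    "probes": None,              # {proximal_segment, proximal_fraction, distal_segment, distal_fraction}
    "cohort": {
        "n_cases": 12,
        "severity_range": [0.2, 0.8],
        "tree_generations": 2,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def resolve(overrides: dict | None = None) -> dict:
    """Merge user overrides onto the defaults, rejecting unknown keys."""
    return _merge(DEFAULTS, overrides or {})


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file and resolve it against the defaults."""
    if path is None:
        return resolve()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping")
    return resolve(doc)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a resolved configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
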