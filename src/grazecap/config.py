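"""Run configuration: one structured YAML file with full defaulting.

Every pipeline parameter lives here; a partial config is deep-merged over
the defaults, so a fully-defaulted config round-trips through YAML
unchanged. All randomness in a run flows from the single ``seed``.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "dump_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "synthetic": {
        "extent": [0.0, 0.0, 160.0, 160.0],
        "cell_size": 5.0,
        "n_parcels": 27,
        # multiplies the latent mean density of every species (scenario dial)
        "wildlife_scale": 1.0,
        "ndvi": {"n_dates": 4, "mean": 0.22, "sd": 0.06, "cloud_prob": 0.5},
    },
    "survey": {
        "n_lines": 250,
        "seasons": ["2015", "2016"],
        "length_km": 10.0,
        "halfwidth_km": 0.5,
        "detection_prob": 1.0,
        "seasonal_cv": 0.15,
    },
    "density": {"halfwidth_km": 0.5, "merge_rule": "mean"},
    "kriging": {
        "model": "spherical",
        "neighborhood": 16,
        "lag_width_km": 10.0,
        "max_lag_km": 80.0,
    },
    "habitat": {"beta": 0.5, "threshold_percentile": 10.0, "max_iter": 5000},
    "yield": {"intercept": -47.021, "slope": 440.21, "unit": "g/m^2", "clamp_negative": True},
    "capacity": {
        "edible_ratio": 0.85,
        "utilization": 0.65,
        "intake_kg_per_day": 4.0,
        "grazing_days": 365.0,
    },
    "conversions": {
        "wildlife": {"kiang": 6.0, "gazelle": 0.3},
        "livestock": {"cattle": 4.5, "sheep": 1.0, "horse": 6.0},
    },
    "livestock": {
        "total_sheep_units": 338159.0,
        "mix": {"cattle": 0.73, "sheep": 0.24, "horse": 0.03},
    },
}


def merge_config(base: dict, override: dict) -> dict:
    """Recursive dict merge: override wins, nested dicts merge key-wise."""
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults <- YAML file <- explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = merge_config(cfg, loaded)
    if overrides:
        cfg = merge_config(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path
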