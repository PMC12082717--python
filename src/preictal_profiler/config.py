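"""Run configuration: one YAML with every tunable, defaulting to the
method's canonical values (0.5-75 Hz band-pass, 6 s / 3 s windows, 2 h
interictal ending 6 h before onset, 99th percentile threshold, >= 15 min
intervals, 20% test split, 75th selection quantile, top-3 features)."""
from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS: dict = {
    "filter": {"low_hz": 0.5, "high_hz": 75.0, "transition_hz": 0.25},
    "window_s": 6.0,
    "hop_s": 3.0,
    "hfd": {"k_max": 8},
    "dfa": {"min_scale": 16, "n_scales": 10},
    "bands": {
        "delta": [0.4, 4.0], "theta": [4.0, 8.0], "alpha": [8.0, 13.0],
        "beta": [13.0, 30.0], "gamma": [30.0, 48.0],
    },
    "interictal": {"duration_h": 2.0, "gap_h": 6.0},
    "detect": {"min_duration_min": 15.0, "percentile": 99.0, "ridge": 1e-6},
    "select": {"test_fraction": 0.2, "quantile": 0.75, "seed": 0},
    "logreg": {"C": 1.0, "max_iter": 1000},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, overlaid by an optional YAML file, then by ``overrides``."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        try:
            payload = yaml.safe_load(Path(path).read_text()) or {}
        except OSError as exc:
            raise ConfigError(f"{path}: cannot read config ({exc})") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
        cfg = _merge(cfg, payload)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg
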