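"""Layered run configuration: defaults <- config file <- CLI flags.

All keys are schema-checked; unknown keys are rejected with the dotted key
path, so a typo never silently falls back to a default.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

from .errors import ConfigError

DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "n_athletes_per_team": 4,     # 4v4 small-sided game
        "duration_s": 120.0,
        "coupling_kappa": 2.0,
        "dropout_rate": 0.02,
        "passes_per_min": 6.0,
        "perturbations_per_min": 0.5,
    },
    "preprocess": {
        "alpha": 0.98,                # complementary-filter gyro trust
        "snr_floor_db": 15.0,         # recalibration trigger
        "cutoff_hz": {"imu": 12.0, "gps": 2.0, "lps": 2.0, "physio": 0.5,
                      "insole": 12.0},
    },
    "align": {
        "degree": 3,                  # B-spline degree
        "out_rate_hz": 20.0,
    },
    "fuse": {
        "lambda": 0.65,               # temporal weight smoothing
        "out_rate_hz": 20.0,
        "K": 5,                       # wavelet decomposition level
        "alpha_feat": 0.15,           # feature reduction ratio
    },
    "indicators": {
        "window_s": 10.0,
        "overlap": 0.5,
        "accel_threshold_mps2": 2.0,
        "sync_window_s": 0.5,
        "zone_nx": 6,
        "zone_ny": 4,
    },
}

_RANGES = {
    "fuse.lambda": (0.0, 1.0),
    "fuse.alpha_feat": (1e-9, 1.0),
    "preprocess.alpha": (0.0, 1.0),
    "indicators.overlap": (0.0, 0.999),
    "simulate.dropout_rate": (0.0, 0.999),
}
_POSITIVE = {"align.out_rate_hz", "fuse.out_rate_hz", "fuse.K", "align.degree",
             "indicators.window_s", "preprocess.snr_floor_db",
             "simulate.duration_s", "simulate.n_athletes_per_team",
             "indicators.zone_nx", "indicators.zone_ny"}


def _merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            raise ConfigError(f"unknown config key {path!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {path!r} must be a mapping")
            out[key] = _merge(base[key], val, prefix=path + ".")
        else:
            out[key] = val
    return out


def validate(cfg: dict) -> None:
    for path, (lo, hi) in _RANGES.items():
        val = _get(cfg, path)
        if not isinstance(val, (int, float)) or not lo <= val <= hi:
            raise ConfigError(f"config {path} = {val!r} outside [{lo}, {hi}]")
    for path in _POSITIVE:
        val = _get(cfg, path)
        if not isinstance(val, (int, float)) or val <= 0:
            raise ConfigError(f"config {path} = {val!r} must be > 0")


def _get(cfg: dict, dotted: str):
    node = cfg
    for part in dotted.split("."):
        node = node[part]
    return node


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Resolve the effective config: defaults <- file <- overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, json.load(fh))
    if overrides:
        cfg = _merge(cfg, overrides)
    validate(cfg)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
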