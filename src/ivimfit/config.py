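"""Run configuration: a single YAML document with a schema validator.

Every CLI run is driven by (and archived with) one config file so that a
re-run from the saved config reproduces deterministic outputs bit-for-bit
and stochastic ones statistically under the saved seeds.  Randomized stages
(phantom generation, simulation) demand an explicit seed — a missing seed is
an error, never a silent default.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .fitters import METHOD_TAGS, BayesSettings, NLLSSettings
from .model import PROTOCOL_B_VALUES, FitBounds
from .simulate import DEFAULT_SNR_LEVELS

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "validate_config",
    "bounds_from_config",
    "nlls_from_config",
    "bayes_from_config",
]


def default_config() -> dict:
    return {
        "bounds": {
            "f_range": [0.0, 0.5],
            "Dstar_range": [1.5e-3, 500e-3],
            "D_range": [0.0, 2.5e-3],
            "high_b_cutoff": 200.0,
        },
        "methods": list(METHOD_TAGS),
        "nlls": {
            "ftol": 1e-10,
            "xtol": 1e-12,
            "max_iter": 1000,
            "f_init": 0.1,
            "Dstar_init": 20e-3,
        },
        "bayes": {
            "engine": "grid",
            "n_walkers": 24,
            "n_burn": 400,
            "n_keep": 200,
            "seed": 0,
            "grid_shape": [40, 48, 40],
        },
        "simulation": {
            "n_combinations": 7875,
            "snr_levels": list(DEFAULT_SNR_LEVELS),
            "b_values": [float(b) for b in PROTOCOL_B_VALUES],
            "seed": None,
        },
        "phantom": {
            "shape": [48, 48, 22],
            "snr": 46.6,
            "seed": None,
        },
        "log_level": "INFO",
    }


_SCHEMA_KEYS = {"bounds", "methods", "nlls", "bayes", "simulation", "phantom", "log_level"}


def validate_config(cfg: dict, require_seed_for=()) -> dict:
    """Merge onto defaults and check types/ranges; returns the merged config."""
    merged = default_config()
    for key, val in (cfg or {}).items():
        if key not in _SCHEMA_KEYS:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    for tag in merged["methods"]:
        if tag not in METHOD_TAGS:
            raise ValueError(f"unknown method {tag!r}; choose from {METHOD_TAGS}")
    b = merged["bounds"]
    for rng in ("f_range", "Dstar_range", "D_range"):
        lo, hi = b[rng]
        if not lo < hi:
            raise ValueError(f"bounds.{rng} must satisfy lo < hi")
    for stage in require_seed_for:
        if merged[stage].get("seed") is None:
            raise ValueError(f"{stage}.seed is required (randomized stages need explicit seeds)")
    return merged


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(cfg)


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def bounds_from_config(cfg: dict) -> FitBounds:
    b = cfg["bounds"]
    return FitBounds(
        f_range=tuple(b["f_range"]),
        Dstar_range=tuple(b["Dstar_range"]),
        D_range=tuple(b["D_range"]),
        high_b_cutoff=float(b["high_b_cutoff"]),
    )


def nlls_from_config(cfg: dict) -> NLLSSettings:
    n = cfg["nlls"]
    return NLLSSettings(
        ftol=float(n["ftol"]),
        xtol=float(n["xtol"]),
        max_iter=int(n["max_iter"]),
        f_init=float(n["f_init"]),
        Dstar_init=float(n["Dstar_init"]),
    )


def bayes_from_config(cfg: dict) -> BayesSettings:
    b = cfg["bayes"]
    return BayesSettings(
        engine=b["engine"],
        n_walkers=int(b["n_walkers"]),
        n_burn=int(b["n_burn"]),
        n_keep=int(b["n_keep"]),
        seed=int(b["seed"]),
        grid_shape=tuple(b["grid_shape"]),
    )
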