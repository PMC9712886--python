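"""Pipeline configuration: defaults, YAML loading, schema validation.

A single mapping drives every stage.  Defaults reproduce the reference
analysis settings: q grid -4:0.1:4, 64x64 ROIs, box sizes {2,...,32}
for box counting and {4,...,16} for MF-DMA, 5-fold cross-validation.
Validation happens before any stage runs and errors name the offending
key.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ConfigError", "default_config", "load_config", "validate_config", "build_qgrid"]


class ConfigError(ValueError):
    """A configuration value failed schema validation; names the key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key '{key}': {message}")


_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "outputs",
    "estimator": "boxcount",  # boxcount | mfdma
    "qgrid": {"min": -4.0, "max": 4.0, "step": 0.1},
    "scales": [2, 4, 8, 16, 32],
    "preprocess": {
        "enabled": True,
        "patch_size": 15,
        "omega": 0.8,
        "t0": 0.1,
        "airlight_frac": 0.001,
        "windows": [1, 3, 5],
    },
    "mfdma": {"theta1": 0.0, "theta2": 0.0, "scales": [4, 6, 8, 12, 16]},
    "glcm": {"levels": 8, "symmetric": False},
    "roi": {"size": 64, "min_dist": 64.0, "min_tissue_frac": 0.75, "bg_threshold": 0.0},
    "simulate": {
        "n_per_class": 200,
        "background": "cascade",
        "weights": [0.3, 0.25, 0.25, 0.2],
        "density": 0.7,
        "texture_contrast": 0.2,
        "psf_sigma": 1.5,
        "blob": {"amplitude": 5.0, "sigma": 1.5, "count": 1},
    },
    "classify": {"model": "svm_poly2", "k": 5, "params": {}},
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            raise ConfigError(path, "unknown key")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(path, f"expected a mapping, got {type(value).__name__}")
            out[key] = _merge(base[key], value, prefix=path + ".")
        else:
            out[key] = value
    return out


def build_qgrid(cfg: dict) -> np.ndarray:
    from .boxcount import default_qgrid

    g = cfg["qgrid"]
    return default_qgrid(float(g["min"]), float(g["max"]), float(g["step"]))


def validate_config(cfg: dict) -> dict:
    """Check every field against the schema; raise ConfigError on the first violation."""
    g = cfg["qgrid"]
    if not (g["min"] < g["max"]) or g["step"] <= 0:
        raise ConfigError("qgrid", "requires min < max and step > 0 (strictly increasing grid)")
    if cfg["estimator"] not in ("boxcount", "mfdma"):
        raise ConfigError("estimator", f"must be boxcount or mfdma, got {cfg['estimator']!r}")
    scales = cfg["scales"]
    if len(scales) < 3 or any(b <= a for a, b in zip(scales, scales[1:])):
        raise ConfigError("scales", "need >= 3 strictly increasing box sizes")
    if any(s < 1 or s & (s - 1) for s in scales):
        raise ConfigError("scales", "box sizes must be powers of two")
    p = cfg["preprocess"]
    if p["patch_size"] < 1 or p["patch_size"] % 2 == 0:
        raise ConfigError("preprocess.patch_size", "must be an odd integer >= 1")
    if not 0 <= p["omega"] <= 1:
        raise ConfigError("preprocess.omega", "must lie in [0, 1]")
    if not 0 < p["t0"] <= 1:
        raise ConfigError("preprocess.t0", "must lie in (0, 1]")
    if len(p["windows"]) < 2 or any(w % 2 == 0 or w < 1 for w in p["windows"]):
        raise ConfigError("preprocess.windows", "need >= 2 odd window sizes")
    m = cfg["mfdma"]
    for th in ("theta1", "theta2"):
        if not 0 <= m[th] <= 1:
            raise ConfigError(f"mfdma.{th}", "must lie in [0, 1]")
    ms = m["scales"]
    if len(ms) < 3 or any(b <= a for a, b in zip(ms, ms[1:])) or ms[0] < 4:
        raise ConfigError("mfdma.scales", "need >= 3 strictly increasing scales, all >= 4")
    if cfg["glcm"]["levels"] < 2:
        raise ConfigError("glcm.levels", "must be >= 2")
    r = cfg["roi"]
    if r["size"] < 2 or r["size"] % 2:
        raise ConfigError("roi.size", "must be an even positive integer")
    s = cfg["simulate"]
    if s["n_per_class"] < 1:
        raise ConfigError("simulate.n_per_class", "must be >= 1")
    if s["background"] not in ("cascade", "fbm"):
        raise ConfigError("simulate.background", "must be cascade or fbm")
    w = s["weights"]
    if len(w) != 4 or abs(sum(w) - 1.0) > 1e-9 or any(x <= 0 for x in w):
        raise ConfigError("simulate.weights", "need 4 positive weights summing to 1")
    c = cfg["classify"]
    if c["model"] not in ("svm_poly2", "knn", "dtree"):
        raise ConfigError("classify.model", "must be one of svm_poly2, knn, dtree")
    if c["k"] < 2:
        raise ConfigError("classify.k", "must be >= 2")
    return cfg


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and explicit overrides."""
    cfg = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("<root>", "config file must contain a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return validate_config(cfg)
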