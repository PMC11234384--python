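"""Pipeline configuration: defaults, YAML round-trip, seed fan-out, hashing.

A configuration is a nested mapping with a fixed schema of blocks (scene,
coloc, pla, calcium, stats) plus a global seed.  Every stochastic stage
receives an explicit seed derived from the global one by a counter-based
scheme, so any stage can be rerun in isolation and end-to-end runs are
byte-reproducible.

The default puncta density (200 reference / 200 partner puncta per cell)
is a plausible placeholder — real per-cell densities vary widely and are
not part of the generator's contract; change it freely in the config.
"""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path

import yaml

from .core import derive_seed

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "make_plots": False,
    "scene": {
        "width_px": 256,
        "height_px": 256,
        "pixel_size_nm": 77.7,
        "psf_sigma_nm": 80.0,
        "gaussian_sd": 2.0,
        "poisson_scaling": 1.0,
        "mito_area_fraction": 0.25,
    },
    "coloc": {
        "n_cells": 3,
        "n_ref": 200,
        "n_partner": 200,
        "f_coloc": 0.3,
        "f_mito": 0.25,
        "offset_sigma_nm": 50.0,
        "min_spacing_nm": 300.0,
        "threshold_nm": 233.0,
        "n_iter": 100,
        "dilation_px": 1,
        "direction": "ref_to_partner",  # or "partner_to_ref"
        "detect_from_images": True,
        "amplitude": 200.0,
    },
    "pla": {
        "conditions": [
            {"name": "control", "spots_per_cell_mean": 20.0, "n_fields": 6, "n_cells": 10},
            {"name": "knockdown", "spots_per_cell_mean": 10.0, "n_fields": 6, "n_cells": 10},
        ],
        "design": "oneway_tukey",
        "threshold_k": 6.0,
        "min_area_px": 2,
        "max_area_px": 100,
    },
    "calcium": {
        "conditions": [
            {"name": "control", "cyto_peak_frac": 0.45, "mito_peak_frac": 0.5, "n_cells": 10},
            {"name": "knockdown", "cyto_peak_frac": 0.22, "mito_peak_frac": 0.22, "n_cells": 10},
        ],
        "baseline_frac": 0.2,
        "noise_sd_frac": 0.01,
        "n_frames": 600,
        "stim_frame": 60,
        "fmax_frame": 480,
        "design": "two_group_unpaired",
    },
}

# counter-based seed streams, one per pipeline stage
STREAM_SCENE, STREAM_PUNCTA, STREAM_RENDER, STREAM_RAND, STREAM_PLA, STREAM_CA = range(6)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and/or an override mapping into the defaults."""
    cfg = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable hash of the canonical YAML form (embedded in every report)."""
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def stage_seed(cfg: dict, stream: int, index: int = 0) -> int:
    return derive_seed(cfg["seed"], stream, index)
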