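"""YAML-backed configuration for grids, fixed parameters and fit bounds."""

from __future__ import annotations

import copy

import yaml

from .csf_model import DetectionNoise
from .v1_core import FixedParams

__all__ = ["default_config", "load_config", "fixed_params_from_config",
           "noise_from_config"]


def default_config() -> dict:
    """Full default configuration as a plain nested dict."""
    return {
        "fixed_params": {
            "n_s": 6, "n": 2.0, "A": 2.0, "sigma_SF": 1.0, "m": 1.0,
            "T": 1.0, "I_c": 1.0, "v_e": 14.0 / 3.0, "v_i": -2.0 / 3.0,
            "tau": 10.0,
        },
        "grids": {
            "orientation_spacing_deg": 2.0,
            "sf_min": 0.5, "sf_max": 64.0, "sf_octave_step": 0.25,
            "ck_prune_limit": 1000.0,
        },
        "detection": {"r0_floor": 1.0, "n_pool": 50},
        "staircase": {
            "tilt_steps": [[2.0, 5.0], [5.0, 2.0]],
            "tilt_start_offset_deg": 10.0,
            "csf_base_contrast": 0.1,
            "csf_down_boost": 3.0, "csf_boost_trials": 4,
        },
        "fitting": {
            "lapse": 0.01,
            "tilt_bounds": {"I_inh": [0.0, 5.0], "sigma_theta": [2.0, 60.0],
                            "threshold_sigma": [0.2, 60.0]},
            "csf_bounds": {"c_min": [1e-4, 1.0], "a": [0.1, 5.0],
                           "b": [0.2, 32.0]},
            "high_sf_margin": 2.0,
        },
    }


def load_config(path: str | None = None) -> dict:
    """Defaults, shallow-merged section-wise with an optional YAML file."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    merged = copy.deepcopy(cfg)
    for section, values in user.items():
        if isinstance(values, dict) and section in merged:
            merged[section].update(values)
        else:
            merged[section] = values
    return merged


def fixed_params_from_config(cfg: dict) -> FixedParams:
    fp = cfg["fixed_params"]
    return FixedParams(n_s=fp["n_s"], n=fp["n"], A=fp["A"], m=fp["m"],
                       T=fp["T"], I_c=fp["I_c"], v_e=fp["v_e"],
                       v_i=fp["v_i"], sigma_sf_firstlayer=fp["sigma_SF"],
                       tau=fp["tau"])


def noise_from_config(cfg: dict) -> DetectionNoise:
    det = cfg["detection"]
    return DetectionNoise(r0=det["r0_floor"], n_pool=det["n_pool"])
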