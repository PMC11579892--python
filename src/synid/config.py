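"""YAML run configuration: defaults, schema validation, merging."""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigurationError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "filters": {
        "bandpass_hz": [20.0, 400.0],
        "notch_hz": 50.0,
        "notch_q": 30.0,
        "lowpass_hz": 4.0,
    },
    "onset": {"gain_h": 9.0, "window_ms": 150.0},
    "rates": {"raw_hz": 1000.0, "control_hz": 100.0},
    "decoder": {
        "n_syn": 4,
        "t_acc_s": 0.6,
        "gmm_components": 3,
        "nmf_restarts": 10,
        "nmf_max_iter": 1000,
        "nmf_tol": 1.0e-6,
        "signal_level": "envelope",
    },
    "arm": {
        "l_upper_m": 0.30,
        "l_forearm_m": 0.33,
        "masses_kg": [2.0, 1.5],
        "centers_m": [0.15, 0.17],
    },
    "assist": {
        "gains": [0.01, 0.03, 0.01],
        "gain_multiplier": 1000.0,
        "admittance": 1.0,
    },
    "manipulability": {"measure": "inv_cond"},
    "generator": {
        "n_train_per_direction": 10,
        "n_test_per_direction": 20,
        "snr": 20.0,
        "direction_jitter_deg": 10.0,
        "lapse_rate": 0.08,
        "tuning_exponent": 1.0,
        "baseline_level": 0.02,
        "bell_peak_frac": 0.5,
        "bell_width_frac": 0.45,
        "electromechanical_delay_s": 0.1,
        "movement_duration_s": 1.0,
        "radius_m": 0.25,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigurationError(f"{here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML file; unknown keys rejected."""
    if path is None:
        return _merge(DEFAULT_CONFIG, {})
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    try:
        user = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigurationError(f"invalid YAML in {p}: {e}") from None
    if not isinstance(user, dict):
        raise ConfigurationError("config root must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def pipeline_config_from(config: dict):
    """Build a PipelineConfig from a validated configuration mapping."""
    from .signal_processing import FilterConfig
    from .synergy_model import NmfOptions
    from .pipeline import PipelineConfig

    dec = config["decoder"]
    return PipelineConfig(
        n_syn=int(dec["n_syn"]),
        t_acc_s=float(dec["t_acc_s"]),
        control_fs=float(config["rates"]["control_hz"]),
        gain_h=float(config["onset"]["gain_h"]),
        onset_window_ms=float(config["onset"]["window_ms"]),
        signal_level=dec["signal_level"],
        filter_config=FilterConfig(
            bandpass_hz=tuple(config["filters"]["bandpass_hz"]),
            notch_hz=float(config["filters"]["notch_hz"]),
            notch_q=float(config["filters"]["notch_q"]),
            lowpass_hz=float(config["filters"]["lowpass_hz"]),
        ),
        nmf=NmfOptions(
            max_iter=int(dec["nmf_max_iter"]),
            tol=float(dec["nmf_tol"]),
            restarts=int(dec["nmf_restarts"]),
            seed=int(config["seed"]),
        ),
        gmm_seed=int(config["seed"]),
        gmm_components=int(dec["gmm_components"]),
    )


def generator_config_from(config: dict, seed: int | None = None):
    from .evaluation import TargetLayout
    from .synthetic_data import GeneratorConfig
    import numpy as np

    g = config["generator"]
    return GeneratorConfig(
        seed=int(config["seed"] if seed is None else seed),
        n_train_per_direction=int(g["n_train_per_direction"]),
        n_test_per_direction=int(g["n_test_per_direction"]),
        snr=None if g["snr"] in (None, "inf") else float(g["snr"]),
        direction_jitter_deg=float(g["direction_jitter_deg"]),
        lapse_rate=float(g["lapse_rate"]),
        tuning_exponent=float(g["tuning_exponent"]),
        baseline_level=float(g["baseline_level"]),
        bell_peak_frac=float(g["bell_peak_frac"]),
        bell_width_frac=float(g["bell_width_frac"]),
        electromechanical_delay_s=float(g["electromechanical_delay_s"]),
        movement_duration_s=float(g["movement_duration_s"]),
        layout=TargetLayout(home=np.zeros(3), radius_m=float(g["radius_m"])),
        fs_raw=float(config["rates"]["raw_hz"]),
        control_fs=float(config["rates"]["control_hz"]),
    )
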