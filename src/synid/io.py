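"""Plain-text artifact I/O: trial files, session manifests, model files.

Trial files are UTF-8 CSV with header ``time_s,<muscle_1>,...,<muscle_6>``
plus optional ``x_m,y_m,z_m`` trajectory columns.  A session manifest is a
JSON file with the sampling rate, muscle names, per-muscle MVC values and
the list of trial files with their direction labels and session mode.
Decoder models round-trip through JSON with 17-significant-digit floats
(bit-exact for the stored decimal representation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .direction_decoder import DecoderModel, DirectionGmm, DirectionLabel
from .errors import DataError, DependencyError
from .signal_processing import EmgTrial
from .synergy_model import SynergyModel


@dataclass
class LoadedTrial:
    emg: EmgTrial
    trajectory: Optional[np.ndarray]   # (n, 3) or None
    file: str
    split: Optional[str] = None


def load_manifest(manifest_path: str | Path) -> List[LoadedTrial]:
    """Load a session manifest and all its trial files."""
    path = Path(manifest_path)
    if not path.exists():
        raise DependencyError(f"manifest not found: {path}")
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise DependencyError(f"manifest is not valid JSON: {e}") from None
    for key in ("fs_raw", "muscle_names", "trials"):
        if key not in manifest:
            raise DependencyError(f"manifest missing required key {key!r}")
    muscles = manifest["muscle_names"]
    mvc_map = manifest.get("mvc")
    mvc = np.array([mvc_map[m] for m in muscles]) if mvc_map else None
    trials = []
    for entry in manifest["trials"]:
        f = path.parent / entry["file"]
        if not f.exists():
            raise DependencyError(f"trial file not found: {f}")
        df = pd.read_csv(f)
        missing = [m for m in muscles if m not in df.columns]
        if missing:
            raise DataError(f"{f.name}: missing muscle columns {missing}")
        samples = df[muscles].to_numpy().T
        traj = None
        if {"x_m", "y_m", "z_m"} <= set(df.columns):
            traj = df[["x_m", "y_m", "z_m"]].to_numpy()
        emg = EmgTrial(
            samples=samples,
            fs_raw=float(manifest["fs_raw"]),
            muscle_names=muscles,
            direction=entry.get("direction"),
            mvc=mvc,
            mode=entry.get("mode", "transparent"),
        )
        trials.append(LoadedTrial(emg=emg, trajectory=traj, file=entry["file"],
                                  split=entry.get("split")))
    return trials


def _fmt(x) -> float:
    return float(np.format_float_scientific(x, precision=16))


def save_decoder(model: DecoderModel, path: str | Path, config_hash: str | None = None) -> None:
    obj = {
        "synergy": {
            "W": model.synergy.W.tolist(),
            "n_syn": model.synergy.n_syn,
            "muscle_names": list(model.synergy.muscle_names),
            "extraction_meta": {
                k: v for k, v in model.synergy.extraction_meta.items()
                if k != "rmse_history"
            },
        },
        "gmms": {
            name: {
                "weights": g.weights.tolist(),
                "means": g.means.tolist(),
                "covariances": g.covariances.tolist(),
            }
            for name, g in model.gmms.items()
        },
        "t_acc_s": model.t_acc_s,
        "control_fs": model.control_fs,
    }
    if config_hash is not None:
        obj["config_hash"] = config_hash
    Path(path).write_text(json.dumps(obj, indent=1))


def load_decoder(path: str | Path) -> DecoderModel:
    p = Path(path)
    if not p.exists():
        raise DependencyError(f"decoder model not found: {p}")
    obj = json.loads(p.read_text())
    syn = obj["synergy"]
    model = DecoderModel(
        synergy=SynergyModel(
            W=np.array(syn["W"]),
            n_syn=int(syn["n_syn"]),
            muscle_names=tuple(syn["muscle_names"]),
            extraction_meta=syn.get("extraction_meta", {}),
        ),
        gmms={
            name: DirectionGmm(
                weights=np.array(g["weights"]),
                means=np.array(g["means"]),
                covariances=np.array(g["covariances"]),
            )
            for name, g in obj["gmms"].items()
        },
        t_acc_s=float(obj["t_acc_s"]),
        control_fs=float(obj["control_fs"]),
    )
    model.config_hash = obj.get("config_hash")
    return model


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, DirectionLabel):
            return o.name
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
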