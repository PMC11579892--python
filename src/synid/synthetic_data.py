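"""Seeded synthetic center-out sessions with synergy-driven EMG envelopes.

Each trial emulates the statistical structure the decoder assumes: four
fixed muscle synergies whose activation amplitudes are cosine-tuned to the
movement direction (two flexor-dominant synergies preferring northward
targets, two extensor-dominant preferring southward ones), a bell-shaped
temporal profile peaking near mid-movement, additive non-negative noise,
and a minimum-jerk hand trajectory that starts one electromechanical delay
after the EMG onset.

The temporal profile is a Gaussian bell truncated at the EMG onset: real
envelope onsets are abrupt (motor-unit recruitment) even when the overall
activation profile is bell-shaped, and the truncation reproduces that
fast rise.  Signals are synthesized at envelope level (post-filtering);
a raw-EMG mode (envelope-modulated wide-band noise) exists to exercise
the filtering chain itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .direction_decoder import DIRECTIONS, DirectionLabel
from .errors import ConfigurationError
from .evaluation import TargetLayout
from .signal_processing import DEFAULT_MUSCLES, EmgTrial

# Default synergy basis: columns = synergies, rows = muscles in
# DEFAULT_MUSCLES order (Biceps, Triceps, AntDelt, MedDelt, PostDelt, Trap).
# Synergies 1-2 are flexor-dominant (preferred angles in the northern half),
# 3-4 extensor-dominant (southern half); columns are unit-normalized.
_W_TRUE_RAW = np.array(
    [
        #  s1    s2    s3    s4
        [0.80, 0.50, 0.00, 0.05],   # Biceps (flexor)
        [0.00, 0.05, 0.70, 0.40],   # Triceps (extensor)
        [0.50, 0.80, 0.05, 0.00],   # Anterior Deltoid (flexor)
        [0.20, 0.00, 0.30, 0.40],   # Medial Deltoid
        [0.05, 0.00, 0.60, 0.80],   # Posterior Deltoid (extensor)
        [0.10, 0.30, 0.10, 0.10],   # Upper Trapezius
    ]
)
DEFAULT_W_TRUE = _W_TRUE_RAW / np.linalg.norm(_W_TRUE_RAW, axis=0)


def default_layout() -> TargetLayout:
    return TargetLayout(home=np.zeros(3), radius_m=0.25)


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic sessions.

    ``snr`` is the ratio between the peak noiseless envelope amplitude and
    the noise standard deviation; ``None`` means noise-free.  Preferred
    angles place one synergy per diagonal so that every one of the eight
    directions activates a distinct subset of synergies (the four diagonal
    directions recruit exactly one synergy, the cardinals a 45-degree blend
    of two), which makes the synergy basis identifiable from the data.
    """

    seed: int = 0
    n_train_per_direction: int = 10
    n_test_per_direction: int = 20
    W_true: np.ndarray = field(default_factory=lambda: DEFAULT_W_TRUE.copy())
    synergy_preferred_angles: tuple = (45.0, 135.0, 225.0, 315.0)
    tuning_exponent: float = 1.0
    snr: Optional[float] = 20.0
    direction_jitter_deg: float = 10.0
    lapse_rate: float = 0.08
    baseline_level: float = 0.02
    amplitude: float = 1.0
    bell_peak_frac: float = 0.5
    bell_width_frac: float = 0.45
    electromechanical_delay_s: float = 0.1
    movement_duration_s: float = 1.0
    pre_onset_s: float = 1.5
    post_s: float = 1.0
    layout: TargetLayout = field(default_factory=default_layout)
    fs_raw: float = 1000.0
    control_fs: float = 100.0
    signal_level: str = "envelope"   # "envelope" | "raw"

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, float)
        if np.any(self.W_true < 0):
            raise ConfigurationError("W_true must be non-negative")
        if self.snr is not None and self.snr <= 0:
            raise ConfigurationError("snr must be positive (or None for noise-free)")
        if not 0 < self.bell_peak_frac < 1:
            raise ConfigurationError("bell_peak_frac must lie in (0, 1)")
        if self.tuning_exponent < 0:
            raise ConfigurationError("tuning_exponent must be >= 0")

    @property
    def n_muscles(self) -> int:
        return self.W_true.shape[0]

    @property
    def n_syn(self) -> int:
        return self.W_true.shape[1]


@dataclass
class SyntheticTrial:
    """One generated trial plus its ground truth."""

    emg: EmgTrial
    true_onset_index: int            # sample index at fs_raw
    trajectory: np.ndarray           # (n_samples, 3) at fs_raw, global frame
    direction: DirectionLabel


def tuning_amplitudes(
    direction: DirectionLabel | float, cfg: GeneratorConfig
) -> np.ndarray:
    """Per-synergy activation amplitude for a movement angle (cosine tuning).

    Accepts a direction label or a raw angle in degrees (the latter is used
    for jittered per-trial effective directions).
    """
    angle = direction.angle_deg if isinstance(direction, DirectionLabel) else float(direction)
    th = np.deg2rad(angle)
    phis = np.deg2rad(np.asarray(cfg.synergy_preferred_angles, float))
    base = np.maximum(0.0, np.cos(th - phis))
    if cfg.tuning_exponent == 0:
        return cfg.amplitude * np.ones_like(base)
    return cfg.amplitude * base ** cfg.tuning_exponent


def activation_profile(cfg: GeneratorConfig, n_samples: int, onset: int) -> np.ndarray:
    """Truncated-Gaussian bell over the trial, zero before the EMG onset."""
    t = np.arange(n_samples) / cfg.fs_raw
    t_on = onset / cfg.fs_raw
    t_pk = t_on + cfg.bell_peak_frac * cfg.movement_duration_s
    w = cfg.bell_width_frac * cfg.movement_duration_s
    bell = np.exp(-0.5 * ((t - t_pk) / w) ** 2)
    bell[t < t_on] = 0.0
    return bell


def minimum_jerk(x0: np.ndarray, x1: np.ndarray, n: int) -> np.ndarray:
    """Minimum-jerk point-to-point path sampled at n points (inclusive ends)."""
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return x0 + np.outer(s, np.asarray(x1, float) - np.asarray(x0, float))


def peak_noiseless_envelope(cfg: GeneratorConfig) -> float:
    """Largest noiseless envelope value across muscles and directions."""
    peaks = [np.max(cfg.W_true @ tuning_amplitudes(d, cfg)) for d in DIRECTIONS]
    return float(max(peaks))


def mvc_values(cfg: GeneratorConfig) -> np.ndarray:
    """Synthetic per-muscle MVC amplitudes: 1.2x the largest noiseless
    envelope each muscle reaches across directions (reaching is submaximal)."""
    per_muscle = np.max(
        np.stack([cfg.W_true @ tuning_amplitudes(d, cfg) for d in DIRECTIONS]),
        axis=0,
    )
    return 1.2 * np.maximum(per_muscle, 1e-6 * cfg.amplitude)


def generate_trial(
    direction: DirectionLabel,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    mode: str = "transparent",
) -> SyntheticTrial:
    """Generate one direction-tuned trial (envelopes + hand trajectory)."""
    fs = cfg.fs_raw
    n = int(round((cfg.pre_onset_s + cfg.movement_duration_s + cfg.post_s) * fs))
    onset = int(round(cfg.pre_onset_s * fs))

    bell = activation_profile(cfg, n, onset)
    # Trial-to-trial motor variability: the muscle pattern is tuned to a
    # jittered effective angle (the hand still reaches the instructed
    # target under visual guidance); occasional lapse trials use an
    # unrelated angle entirely, emulating attention/posture slips.
    if rng.uniform() < cfg.lapse_rate:
        eff_angle = rng.uniform(0.0, 360.0)
    else:
        eff_angle = direction.angle_deg + rng.normal(0.0, cfg.direction_jitter_deg)
    amps = tuning_amplitudes(eff_angle, cfg)
    C = np.outer(amps, bell)                      # (n_syn, n)
    clean = cfg.W_true @ C + cfg.baseline_level * cfg.amplitude

    if cfg.snr is not None and np.isfinite(cfg.snr):
        sigma = peak_noiseless_envelope(cfg) / cfg.snr
        noise = rng.normal(0.0, sigma, size=clean.shape)
        env = np.clip(clean + noise, 0.0, None)
    else:
        env = clean

    if cfg.signal_level == "raw":
        carrier = rng.normal(0.0, 1.0, size=env.shape)
        samples = env * carrier                    # envelope-modulated wide-band noise
    elif cfg.signal_level == "envelope":
        samples = env
    else:
        raise ConfigurationError(f"unknown signal_level {cfg.signal_level!r}")

    # trajectory: hold at home, then minimum jerk to the target, then hold
    kin_onset = onset + int(round(cfg.electromechanical_delay_s * fs))
    n_move = int(round(cfg.movement_duration_s * fs))
    home = cfg.layout.home
    target = cfg.layout.target(direction)
    traj = np.tile(home, (n, 1)).astype(float)
    seg_end = min(kin_onset + n_move, n)
    path = minimum_jerk(home, target, n_move)
    traj[kin_onset:seg_end] = path[: seg_end - kin_onset]
    traj[seg_end:] = target

    emg = EmgTrial(
        samples=samples,
        fs_raw=fs,
        muscle_names=DEFAULT_MUSCLES[: cfg.n_muscles],
        direction=direction.name,
        mvc=mvc_values(cfg),
        mode=mode,
    )
    return SyntheticTrial(
        emg=emg, true_onset_index=onset, trajectory=traj, direction=direction
    )


@dataclass
class SyntheticSession:
    """In-memory session: training (transparent) and test trials."""

    cfg: GeneratorConfig
    train_trials: List[SyntheticTrial]
    test_trials: List[SyntheticTrial]


def generate_session(cfg: GeneratorConfig, test_mode: str = "transparent") -> SyntheticSession:
    """Generate a full seeded session: trials for every direction in
    randomized order, reproducible from ``cfg.seed`` alone."""
    rng = np.random.default_rng(cfg.seed)

    def make(n_per_dir: int, mode: str) -> List[SyntheticTrial]:
        dirs = [d for d in DIRECTIONS for _ in range(n_per_dir)]
        order = rng.permutation(len(dirs))
        return [generate_trial(dirs[i], cfg, rng, mode=mode) for i in order]

    return SyntheticSession(
        cfg=cfg,
        train_trials=make(cfg.n_train_per_direction, "transparent"),
        test_trials=make(cfg.n_test_per_direction, test_mode),
    )


def write_session(session: SyntheticSession, out_dir: str | Path) -> Path:
    """Write a session to disk in the plain-text trial format.

    One CSV per trial (``time_s,<muscles...>,x_m,y_m,z_m``), a JSON manifest
    listing the trials, and a ``truth.json`` sidecar with the generator's
    ground truth (true onsets, W_true, seed) for test oracles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = session.cfg
    manifest = {
        "fs_raw": cfg.fs_raw,
        "muscle_names": list(DEFAULT_MUSCLES[: cfg.n_muscles]),
        "mvc": {m: float(v) for m, v in zip(DEFAULT_MUSCLES, mvc_values(cfg))},
        "trials": [],
    }
    truth = {
        "seed": cfg.seed,
        "W_true": cfg.W_true.tolist(),
        "onsets": {},
    }
    header = "time_s," + ",".join(manifest["muscle_names"]) + ",x_m,y_m,z_m"
    for split, trials in (("train", session.train_trials), ("test", session.test_trials)):
        for i, tr in enumerate(trials):
            name = f"{split}_{i:03d}_{tr.direction.name}.csv"
            t = np.arange(tr.emg.n_samples) / cfg.fs_raw
            table = np.column_stack([t, tr.emg.samples.T, tr.trajectory])
            np.savetxt(out / name, table, delimiter=",", header=header,
                       comments="", fmt="%.9g")
            manifest["trials"].append(
                {"file": name, "direction": tr.direction.name,
                 "mode": tr.emg.mode, "split": split}
            )
            truth["onsets"][name] = int(tr.true_onset_index)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out / "manifest.json"


# ---------------------------------------------------------------------------
# Simple fixtures for the onset-detection operating-point suites
# ---------------------------------------------------------------------------

def baseline_trial(
    rng: np.random.Generator,
    duration_s: float = 5.0,
    fs: float = 100.0,
    n_channels: int = 6,
    sigma: float = 1.0,
) -> np.ndarray:
    """Pure-baseline multi-channel envelope noise around a tonic level.

    The tonic offset (3 sigma) keeps the non-negativity clip from distorting
    the noise distribution, so the trial probes the detector's false-positive
    rate on near-Gaussian baseline rather than on clipping artifacts.
    """
    n = int(round(duration_s * fs))
    x = 3.0 * sigma + rng.normal(0.0, sigma, size=(n_channels, n))
    return np.clip(x, 0.0, None)


def step_trial(
    rng: np.random.Generator,
    step_at_s: float = 2.0,
    duration_s: float = 4.0,
    fs: float = 100.0,
    n_channels: int = 6,
    sigma: float = 1.0,
    snr: float = 20.0,
) -> tuple[np.ndarray, int]:
    """Baseline noise plus a sustained activation step.

    ``snr`` scales the step of the *summed* envelope relative to the summed
    baseline's noise standard deviation (sqrt(n_channels) * sigma) -- the
    quantity the onset detector actually observes.
    Returns (values, true step index).
    """
    x = baseline_trial(rng, duration_s, fs, n_channels, sigma)
    k = int(round(step_at_s * fs))
    x[:, k:] += snr * np.sqrt(n_channels) * sigma / n_channels
    return x, k
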