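"""Session-level glue: train a decoder, decode trials, evaluate a session.

This is the layer the command-line interface and the reproduction script
sit on.  It chains the per-trial operations — envelope extraction (when
signals are raw), decimation to the control rate, onset detection, synergy
extraction, mixture training, online decoding — and aggregates results into
session metrics and time-resolved accuracy curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import assistance as asst
from .direction_decoder import (
    DIRECTIONS,
    DecoderModel,
    DirectionLabel,
    PosteriorTrace,
    decode_trial,
    train_gmms,
)
from .errors import DataError, TrainingError, TrialExcludedError
from .evaluation import (
    SessionMetrics,
    TargetLayout,
    TrialResult,
    accuracy_vs_time,
    iemg,
    kinematic_benchmark,
    movement_end,
    repeatability_errors,
    session_metrics,
)
from .signal_processing import (
    EmgTrial,
    EnvelopeSeries,
    FilterConfig,
    OnsetEvent,
    compute_envelope,
    decimate_envelope,
    detect_onset,
)
from .synergy_model import ActivationSeries, NmfOptions, extract_synergies
from .synthetic_data import SyntheticSession, SyntheticTrial


@dataclass
class PipelineConfig:
    """Knobs of the processing chain (defaults mirror the online system)."""

    n_syn: int = 4
    t_acc_s: float = 0.6
    control_fs: float = 100.0
    gain_h: float = 9.0
    onset_window_ms: float = 150.0
    signal_level: str = "envelope"    # "envelope" (already filtered) | "raw"
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    nmf: NmfOptions = field(default_factory=NmfOptions)
    gmm_seed: int = 0
    gmm_components: int = 3


def control_envelope(trial: EmgTrial, cfg: PipelineConfig) -> EnvelopeSeries:
    """Trial -> envelope at the control rate (filters applied if raw)."""
    if cfg.signal_level == "raw":
        env = compute_envelope(trial, cfg.filter_config)
    else:
        env = EnvelopeSeries(values=np.clip(trial.samples, 0.0, None), fs=trial.fs_raw)
    return decimate_envelope(env, cfg.control_fs)


@dataclass
class DecodeOutcome:
    """Decoding result (or exclusion) for one trial."""

    direction: Optional[DirectionLabel]
    envelope: EnvelopeSeries
    onset: Optional[OnsetEvent]
    trace: Optional[PosteriorTrace]
    exclusion_reason: Optional[str] = None

    @property
    def excluded(self) -> bool:
        return self.trace is None


def train_decoder(
    trials: Sequence[EmgTrial],
    cfg: PipelineConfig | None = None,
) -> tuple[DecoderModel, dict]:
    """Train synergies + per-direction mixtures from labeled trials.

    Each trial's envelope segment from the detected onset to the end of the
    accumulation window (t_acc * control_fs samples) is concatenated along
    time; synergies are extracted from the concatenation and the resulting
    activation coefficients, labeled per trial, train the mixtures.  Trials
    whose onset is not detected in time are skipped and reported.
    """
    cfg = cfg or PipelineConfig()
    n_seg = int(round(cfg.t_acc_s * cfg.control_fs))
    segments, labels, skipped = [], [], []
    for i, trial in enumerate(trials):
        if trial.direction is None:
            raise TrainingError(f"training trial {i} has no direction label")
        env = control_envelope(trial, cfg)
        onset = detect_onset(env, gain_h=cfg.gain_h, window_ms=cfg.onset_window_ms)
        if onset is None or onset.index + 1 + n_seg > env.n_samples:
            skipped.append(i)
            continue
        seg = env.values[:, onset.index + 1 : onset.index + 1 + n_seg]
        segments.append(seg)
        labels.extend([trial.direction] * n_seg)
    if not segments:
        raise TrainingError("no training trial had a usable onset")
    E = np.concatenate(segments, axis=1)
    training_env = EnvelopeSeries(values=E, fs=cfg.control_fs)
    synergy, H = extract_synergies(training_env, n_syn=cfg.n_syn, options=cfg.nmf)
    H_labeled = ActivationSeries(H=H.H, fs=cfg.control_fs, labels=np.array(labels))
    gmms = train_gmms(
        H_labeled, n_components=cfg.gmm_components, seed=cfg.gmm_seed
    )
    model = DecoderModel(
        synergy=synergy, gmms=gmms, t_acc_s=cfg.t_acc_s, control_fs=cfg.control_fs
    )
    report = {
        "n_trials": len(trials),
        "n_skipped": len(skipped),
        "skipped_indices": skipped,
        "nmf_rmse": synergy.extraction_meta["final_rmse"],
    }
    return model, report


def decode_trials(
    trials: Sequence[EmgTrial],
    model: DecoderModel,
    cfg: PipelineConfig | None = None,
) -> List[DecodeOutcome]:
    """Run onset detection + online decoding on every trial."""
    cfg = cfg or PipelineConfig()
    outcomes = []
    for trial in trials:
        env = control_envelope(trial, cfg)
        direction = (
            DirectionLabel.from_name(trial.direction) if trial.direction else None
        )
        onset = detect_onset(env, gain_h=cfg.gain_h, window_ms=cfg.onset_window_ms)
        if onset is None:
            outcomes.append(DecodeOutcome(direction, env, None, None,
                                          "onset not detected"))
            continue
        try:
            trace = decode_trial(env, onset, model)
        except TrialExcludedError as e:
            outcomes.append(DecodeOutcome(direction, env, onset, None, e.reason))
            continue
        outcomes.append(DecodeOutcome(direction, env, onset, trace))
    return outcomes


def outcomes_to_results(outcomes: Sequence[DecodeOutcome]) -> List[TrialResult]:
    results = []
    for o in outcomes:
        if o.direction is None:
            raise DataError("cannot evaluate an unlabeled trial")
        if o.excluded:
            results.append(
                TrialResult(true_direction=o.direction, excluded=True,
                            exclusion_reason=o.exclusion_reason)
            )
        else:
            results.append(
                TrialResult(
                    true_direction=o.direction,
                    estimated_direction=o.trace.final_estimate,
                    estimate_trace=o.trace.estimates,
                )
            )
    return results


def evaluate_outcomes(
    outcomes: Sequence[DecodeOutcome],
    from_s: float = 0.05,
    control_fs: float = 100.0,
) -> SessionMetrics:
    """Session metrics plus the modified-accuracy-vs-time curve."""
    results = outcomes_to_results(outcomes)
    metrics = session_metrics(results)
    kept = [r for r in results if not r.excluded]
    metrics.accuracy_vs_time = accuracy_vs_time(
        [r.estimate_trace for r in kept],
        [r.true_direction for r in kept],
        control_fs=control_fs,
        from_s=from_s,
    )
    return metrics


def benchmark_estimate_traces(
    trials: Sequence[SyntheticTrial],
    outcomes: Sequence[DecodeOutcome],
    cfg: PipelineConfig | None = None,
    layout: TargetLayout | None = None,
    min_disp_m: float = 0.01,
) -> tuple[list, list]:
    """Kinematics-benchmark estimate traces aligned with the decoder's.

    For every non-excluded trial, the hand trajectory (home frame, xy) is
    decimated to the control rate, classified per sample by the nearest
    target angle, and the estimates over the decoder's accumulation window
    (the ``n_iter`` control steps after the detected EMG onset) are
    returned together with the true directions.
    """
    cfg = cfg or PipelineConfig()
    layout = layout or TargetLayout()
    k = int(round(trials[0].emg.fs_raw / cfg.control_fs))
    traces, truths = [], []
    for trial, out in zip(trials, outcomes):
        if out.excluded:
            continue
        traj_c = trial.trajectory[::k] - layout.home
        est = kinematic_benchmark(traj_c[:, :2], min_disp_m=min_disp_m)
        i0 = out.onset.index
        n_iter = out.trace.n_iterations
        seg = est[i0 + 1 : i0 + 1 + n_iter]
        if seg.size < n_iter:
            seg = np.pad(seg, (0, n_iter - seg.size), mode="edge")
        traces.append(seg)
        truths.append(out.direction)
    return traces, truths


def assisted_final_positions(
    trials: Sequence[SyntheticTrial],
    outcomes: Sequence[DecodeOutcome],
    arm: asst.ArmModel | None = None,
    gains: Sequence[float] = (0.01, 0.03, 0.01),
    gain_multiplier: float = 1000.0,
    admittance: float = 1.0,
    layout: TargetLayout | None = None,
) -> List[Optional[np.ndarray]]:
    """Closed-loop assisted-reach simulation for every decoded trial.

    The intent velocity is the time derivative of the trial's generated
    (transparent) trajectory; the virtual-stiffness force pulls toward the
    target of the decoder's running estimate (frozen after the accumulation
    time).  Returns the final hand position per trial (None if excluded).
    """
    arm = arm or asst.ArmModel()
    layout = layout or TargetLayout()
    finals: List[Optional[np.ndarray]] = []
    for trial, out in zip(trials, outcomes):
        if out.excluded:
            finals.append(None)
            continue
        fs = trial.emg.fs_raw
        k = int(round(fs / out.envelope.fs))
        traj_c = trial.trajectory[::k]
        v_intent = np.gradient(traj_c, 1.0 / out.envelope.fs, axis=0)
        i0 = out.onset.index
        est = out.trace.estimates

        def target_at(step: int, i0=i0, est=est) -> np.ndarray:
            j = step - (i0 + 1)
            if j < 0:
                j = 0
            j = min(j, len(est) - 1)
            return layout.target(DIRECTIONS[int(est[j])])

        xs = asst.simulate_assisted_reach(
            v_intent=v_intent[i0:],
            x_target=lambda s, i0=i0: target_at(s + i0),
            gains=np.asarray(gains),
            admittance=admittance,
            arm=arm,
            dt=1.0 / out.envelope.fs,
            x0=traj_c[i0],
            gain_multiplier=gain_multiplier,
        )
        finals.append(xs[-1])
    return finals


def repeatability_summary(
    trials: Sequence[SyntheticTrial],
    finals: Sequence[Optional[np.ndarray]],
    layout: TargetLayout | None = None,
) -> dict:
    """Per-trial polar errors of assisted end points against the transparent
    centroids (the generator's transparent reaches end on the target, so the
    centroid for each direction is the target itself)."""
    layout = layout or TargetLayout()
    drho, dtheta = [], []
    for trial, fp in zip(trials, finals):
        if fp is None:
            continue
        centroid = layout.target(trial.direction) - layout.home
        dr, dt = repeatability_errors(fp[:2] - layout.home[:2], centroid[:2])
        drho.append(dr)
        dtheta.append(dt)
    return {
        "delta_rho_m": np.array(drho),
        "delta_theta_deg": np.array(dtheta),
        "median_delta_rho_m": float(np.median(drho)) if drho else float("nan"),
        "median_delta_theta_deg": float(np.median(dtheta)) if dtheta else float("nan"),
    }


def iemg_summary(
    trials: Sequence[SyntheticTrial],
    outcomes: Sequence[DecodeOutcome],
) -> np.ndarray:
    """Per-muscle mean iEMG over non-excluded trials (onset to movement end).

    Movement end uses the non-causal rule on the hand displacement from
    home: first decay to 20% of the peak after the peak.
    """
    vals = []
    for trial, out in zip(trials, outcomes):
        if out.excluded:
            continue
        fs = trial.emg.fs_raw
        k = int(round(fs / out.envelope.fs))
        disp = np.linalg.norm(trial.trajectory[::k] - trial.trajectory[0], axis=1)
        try:
            end = movement_end(disp)
        except DataError:
            continue
        i0 = out.onset.index
        stop = max(end.index, i0 + 2)
        seg = out.envelope.values[:, i0:stop]
        vals.append(iemg(seg, trial.emg.mvc))
    if not vals:
        raise DataError("no trials usable for iEMG")
    return np.mean(vals, axis=0)


def run_synthetic_study(
    session: SyntheticSession,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Train on the transparent trials, decode the test trials, evaluate.

    Returns the trained model, per-trial outcomes, session metrics and the
    paired kinematics-benchmark curve — the full study shape on one
    synthetic session.
    """
    cfg = cfg or PipelineConfig()
    model, train_report = train_decoder([t.emg for t in session.train_trials], cfg)
    outcomes = decode_trials([t.emg for t in session.test_trials], model, cfg)
    metrics = evaluate_outcomes(outcomes, control_fs=cfg.control_fs)
    bench_traces, bench_truth = benchmark_estimate_traces(
        session.test_trials, outcomes, cfg, layout=session.cfg.layout
    )
    bench_curve = accuracy_vs_time(
        bench_traces, bench_truth, control_fs=cfg.control_fs, from_s=0.05
    )
    return {
        "model": model,
        "train_report": train_report,
        "outcomes": outcomes,
        "metrics": metrics,
        "benchmark_curve": bench_curve,
    }
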