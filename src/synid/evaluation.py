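"""Performance indicators for center-out intention decoding.

Covers the whole evaluation battery: confusion matrix and accuracy,
the four-level error taxonomy based on circular distance between targets,
modified accuracy (correct + adjacent-direction errors), polar
repeatability errors between assisted and unassisted end points, MVC- and
time-normalized EMG integrals (effort proxy), movement-end segmentation,
time-resolved accuracy curves, a kinematics-based benchmark classifier, and
the trial-count-adjusted chance level of a multi-class classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .direction_decoder import (
    DIRECTION_NAMES,
    DIRECTIONS,
    DirectionLabel,
    N_DIRECTIONS,
    PosteriorTrace,
)
from .errors import DataError
from .signal_processing import EnvelopeSeries

ERROR_TYPES = ("correct", "type1", "type2", "type3", "type4")


def classify_error(true_d: DirectionLabel, est_d: DirectionLabel) -> str:
    """Error category from the circular index distance between directions.

    Adjacent targets (45 deg apart) give ``type1``, perpendicular ones
    ``type2``, near-opposite ``type3`` and opposite ``type4``; distance 0 is
    ``correct``.
    """
    d = abs(true_d.index - est_d.index)
    d = min(d, N_DIRECTIONS - d)
    return ERROR_TYPES[d]


@dataclass
class TargetLayout:
    """Eight targets equally spaced on a horizontal circle around home."""

    home: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius_m: float = 0.25

    def __post_init__(self) -> None:
        self.home = np.asarray(self.home, float)
        if self.radius_m <= 0:
            raise DataError("radius must be positive")

    def target(self, direction: DirectionLabel) -> np.ndarray:
        a = np.deg2rad(direction.angle_deg)
        return self.home + self.radius_m * np.array([np.cos(a), np.sin(a), 0.0])

    @property
    def targets(self) -> np.ndarray:
        return np.array([self.target(d) for d in DIRECTIONS])


@dataclass
class TrialResult:
    """Outcome of one decoded trial, ready for aggregation."""

    true_direction: DirectionLabel
    estimated_direction: Optional[DirectionLabel] = None
    estimate_trace: Optional[np.ndarray] = None
    final_hand_position: Optional[np.ndarray] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    @property
    def error_type(self) -> Optional[str]:
        if self.excluded or self.estimated_direction is None:
            return None
        return classify_error(self.true_direction, self.estimated_direction)


@dataclass
class SessionMetrics:
    """Aggregated indicators for one session."""

    confusion: np.ndarray                  # 8x8 counts, rows = true direction
    accuracy_pct: float
    type1_pct: float
    type2_pct: float
    type3_pct: float
    type4_pct: float
    modified_accuracy_pct: float
    n_trials: int
    n_excluded: int
    chance_level_pct: Optional[float] = None
    iemg: Optional[dict] = None
    delta_rho_m: Optional[np.ndarray] = None
    delta_theta_deg: Optional[np.ndarray] = None
    manipulability: Optional[np.ndarray] = None
    accuracy_vs_time: Optional[dict] = None


def session_metrics(results: Sequence[TrialResult]) -> SessionMetrics:
    """Confusion matrix and error-type percentages over non-excluded trials.

    Percentages are computed over the non-excluded trials only, so accuracy
    plus the four error-type rates sums to exactly 100%.  Modified accuracy
    is accuracy plus the adjacent-direction (type 1) rate.
    """
    kept = [r for r in results if not r.excluded]
    n_excluded = len(results) - len(kept)
    if not kept:
        raise DataError("no non-excluded trials to aggregate")
    confusion = np.zeros((N_DIRECTIONS, N_DIRECTIONS), dtype=int)
    counts = dict.fromkeys(ERROR_TYPES, 0)
    for r in kept:
        confusion[r.true_direction.index, r.estimated_direction.index] += 1
        counts[r.error_type] += 1
    n = len(kept)
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    return SessionMetrics(
        confusion=confusion,
        accuracy_pct=pct["correct"],
        type1_pct=pct["type1"],
        type2_pct=pct["type2"],
        type3_pct=pct["type3"],
        type4_pct=pct["type4"],
        modified_accuracy_pct=pct["correct"] + pct["type1"],
        n_trials=n,
        n_excluded=n_excluded,
        chance_level_pct=adjusted_chance_level(n, N_DIRECTIONS),
    )


def to_polar(p: np.ndarray) -> tuple[float, float]:
    """Planar point -> (rho [m], theta [deg] counter-clockwise from +x, in [0, 360)).

    At the origin the angle is undefined and returned as NaN.
    """
    p = np.asarray(p, float)
    if not np.all(np.isfinite(p)):
        raise DataError("non-finite point")
    rho = float(np.hypot(p[0], p[1]))
    if rho == 0.0:
        return 0.0, float("nan")
    theta = float(np.degrees(np.arctan2(p[1], p[0]))) % 360.0
    return rho, theta


def wrap_angle_deg(a: float) -> float:
    """Wrap an angle difference into [-180, 180)."""
    return (a + 180.0) % 360.0 - 180.0


def repeatability_errors(
    final_assist: np.ndarray, centroid_transparent: np.ndarray
) -> tuple[float, float]:
    """Polar discrepancies between an assisted end point and the transparent
    centroid for the same target: |delta rho| in m and wrapped |delta theta|
    in deg (<= 180)."""
    r1, t1 = to_polar(final_assist)
    r0, t0 = to_polar(centroid_transparent)
    if np.isnan(t1) or np.isnan(t0):
        raise DataError("angle undefined at zero radius; trial must be excluded")
    return abs(r1 - r0), abs(wrap_angle_deg(t1 - t0))


def iemg(env_segment: EnvelopeSeries | np.ndarray, mvc: np.ndarray) -> np.ndarray:
    """Per-muscle integral of the MVC-normalized envelope over normalized time.

    The segment (onset to movement end) is mapped to [0, 1] in time and the
    envelope expressed in % MVC, so a constant envelope at MVC level
    integrates to exactly 100.
    """
    values = env_segment.values if isinstance(env_segment, EnvelopeSeries) else np.asarray(env_segment, float)
    mvc = np.asarray(mvc, float)
    if mvc.shape != (values.shape[0],) or np.any(mvc <= 0):
        raise DataError("mvc must hold one positive value per muscle")
    t = values.shape[1]
    if t < 2:
        raise DataError("segment too short to integrate")
    norm = values / mvc[:, None] * 100.0
    return np.trapezoid(norm, dx=1.0 / (t - 1), axis=1)


@dataclass
class MovementEnd:
    index: int
    complete: bool    # False when the series never decays to the cutoff


def movement_end(displacement: np.ndarray, cutoff_frac: float = 0.2) -> MovementEnd:
    """Non-causal movement-end rule: first sample after the peak where the
    displacement coordinate decays to ``cutoff_frac`` of its peak value."""
    x = np.asarray(displacement, float)
    peak_idx = int(np.argmax(x))
    peak = x[peak_idx]
    if peak <= 0:
        raise DataError("displacement peak must be positive")
    after = np.nonzero(x[peak_idx:] <= cutoff_frac * peak)[0]
    if after.size == 0:
        return MovementEnd(index=x.size - 1, complete=False)
    return MovementEnd(index=peak_idx + int(after[0]), complete=True)


def kinematic_benchmark(
    trajectory: np.ndarray, min_disp_m: float = 0.01
) -> np.ndarray:
    """Kinematics-only direction classifier, per sample.

    For each planar hand position (home frame) the polar angle is assigned
    to the nearest of the eight target angles (45-deg spacing, wrapped
    distance; exact ties go to the lower direction index).  Samples closer
    to home than ``min_disp_m`` inherit the previous estimate, starting
    from E (index 0).
    """
    traj = np.asarray(trajectory, float)
    angles = np.array([d.angle_deg for d in DIRECTIONS])
    out = np.empty(traj.shape[0], dtype=int)
    prev = 0
    for i, p in enumerate(traj):
        rho, theta = to_polar(p)
        if rho < min_disp_m or np.isnan(theta):
            out[i] = prev
        else:
            diffs = np.abs([wrap_angle_deg(theta - a) for a in angles])
            out[i] = int(np.argmin(diffs))      # first min = lowest index
        prev = out[i]
    return out


def adjusted_chance_level(
    n_trials: int, n_classes: int = 8, confidence: float = 0.95
) -> float:
    """Chance level adjusted for the number of trials, in percent.

    Upper bound of the two-sided binomial confidence interval around random
    guessing: the smallest integer count ``k`` whose binomial CDF
    (n = n_trials, p = 1/n_classes) reaches ``1 - (1 - confidence)/2``,
    reported as ``100 k / n``.  A classifier must exceed this rate to be
    distinguishable from chance at the given confidence.
    """
    if n_trials < 1 or n_classes < 2:
        raise DataError("need n_trials >= 1 and n_classes >= 2")
    p = 1.0 / n_classes
    q = 1.0 - (1.0 - confidence) / 2.0
    k = int(binom.ppf(q, n_trials, p))
    # ppf returns the smallest k with CDF >= q; guard floating boundary
    while binom.cdf(k, n_trials, p) < q:
        k += 1
    while k > 0 and binom.cdf(k - 1, n_trials, p) >= q:
        k -= 1
    return 100.0 * k / n_trials


def accuracy_vs_time(
    estimate_traces: Sequence[np.ndarray],
    true_directions: Sequence[DirectionLabel],
    control_fs: float,
    from_s: float = 0.05,
    modified: bool = True,
) -> dict:
    """Time-resolved (modified) accuracy curve across trials.

    ``estimate_traces[i][k]`` is trial i's running direction-index estimate
    at control iteration k+1 after onset.  The curve is evaluated at every
    control step from ``from_s`` after onset to the end of the traces.
    Modified accuracy counts correct estimates plus adjacent-direction
    (type 1) estimates.
    """
    if not estimate_traces:
        raise DataError("no traces")
    n_iter = min(len(t) for t in estimate_traces)
    k0 = max(int(np.ceil(from_s * control_fs)), 1)
    times, values = [], []
    for k in range(k0, n_iter + 1):
        ok = 0
        for trace, true_d in zip(estimate_traces, true_directions):
            d = abs(int(trace[k - 1]) - true_d.index)
            d = min(d, N_DIRECTIONS - d)
            if d == 0 or (modified and d == 1):
                ok += 1
        times.append(k / control_fs)
        values.append(100.0 * ok / len(estimate_traces))
    return {"time_s": np.array(times), "accuracy_pct": np.array(values)}
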