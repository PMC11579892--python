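"""Surface-EMG conditioning and activation-onset detection.

Raw multi-channel EMG is converted to *linear envelopes* by a causal filter
chain (band-pass, power-line notch, full-wave rectification, low-pass) run
at the acquisition rate, then decimated to the control-loop rate for the
online decoder.  Movement onset is detected on the sum of all muscle
envelopes with an adaptive threshold: mean plus a tunable multiple of the
standard deviation of the summed envelope in a trailing moving window.

All filters are single-pass (causal) so that offline results match what a
real-time controller would have computed sample by sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .errors import ConfigurationError, DataError

DEFAULT_MUSCLES = (
    "BicepsBrachii",
    "TricepsBrachii",
    "AnteriorDeltoid",
    "MedialDeltoid",
    "PosteriorDeltoid",
    "UpperTrapezius",
)


@dataclass
class EmgTrial:
    """One recorded reaching trial: raw samples plus acquisition metadata.

    ``samples`` is [channels x time] in acquisition units.  ``mvc`` holds
    per-muscle maximum-voluntary-contraction amplitudes in the same units;
    it is used only for effort normalization, never by the decoder, which
    consumes non-normalized envelopes.
    """

    samples: np.ndarray
    fs_raw: float = 1000.0
    muscle_names: Sequence[str] = DEFAULT_MUSCLES
    direction: Optional[str] = None
    mvc: Optional[np.ndarray] = None
    mode: str = "transparent"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D [channels x time] array")
        if self.fs_raw <= 0:
            raise ConfigurationError("fs_raw must be positive")
        if len(self.muscle_names) != self.samples.shape[0]:
            raise DataError("muscle_names length must match channel count")
        if self.mvc is not None:
            self.mvc = np.asarray(self.mvc, dtype=float)
            if self.mvc.shape != (self.samples.shape[0],):
                raise DataError("mvc must have one value per muscle")
            if np.any(self.mvc <= 0):
                raise DataError("mvc values must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EnvelopeSeries:
    """Non-negative multi-muscle linear-envelope matrix [channels x time]."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("envelope values must be 2-D [channels x time]")
        if np.any(self.values < 0):
            raise DataError("envelope values must be non-negative")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class OnsetEvent:
    """Detected activation onset with the traces that justify it."""

    index: int
    time_s: float
    threshold_trace: np.ndarray
    sum_trace: np.ndarray


@dataclass
class FilterConfig:
    """Causal envelope-extraction chain settings.

    The band-pass is a 4th-order Butterworth (two poles per band edge), the
    notch a 2nd-order IIR resonator, and the smoothing stage a 2nd-order
    Butterworth low-pass whose cut-off sets the envelope bandwidth.
    """

    bandpass_hz: tuple = (20.0, 400.0)
    notch_hz: float = 50.0
    notch_q: float = 30.0
    lowpass_hz: float = 4.0


def compute_envelope(trial: EmgTrial, config: FilterConfig | None = None) -> EnvelopeSeries:
    """Convert raw EMG to linear envelopes with the causal filter chain.

    Band-pass 20-400 Hz, notch at the power-line frequency, full-wave
    rectification, low-pass at 4 Hz, in that order; every stage is applied
    single-pass so the output at sample ``n`` depends only on inputs up to
    ``n``.  Tiny negative overshoot of the final low-pass is clamped to 0.
    """
    config = config or FilterConfig()
    fs = trial.fs_raw
    nyq = fs / 2.0
    lo, hi = config.bandpass_hz
    if not (0 < lo < hi):
        raise ConfigurationError("band-pass edges must satisfy 0 < low < high")
    if hi >= nyq or config.notch_hz >= nyq or config.lowpass_hz >= nyq:
        raise ConfigurationError("filter edge at or above the Nyquist frequency")
    if not np.all(np.isfinite(trial.samples)):
        raise DataError("raw samples contain non-finite values")

    sos_bp = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    b_notch, a_notch = signal.iirnotch(config.notch_hz, config.notch_q, fs=fs)
    sos_lp = signal.butter(2, config.lowpass_hz, btype="lowpass", fs=fs, output="sos")

    x = signal.sosfilt(sos_bp, trial.samples, axis=1)
    x = signal.lfilter(b_notch, a_notch, x, axis=1)
    x = np.abs(x)
    x = signal.sosfilt(sos_lp, x, axis=1)
    np.clip(x, 0.0, None, out=x)
    return EnvelopeSeries(values=x, fs=fs)


def notch_attenuation(config: FilterConfig, fs: float, freq_hz: float) -> float:
    """Magnitude response of the designed notch at ``freq_hz`` (audit helper)."""
    b, a = signal.iirnotch(config.notch_hz, config.notch_q, fs=fs)
    _, h = signal.freqz(b, a, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]))


def decimate_envelope(env: EnvelopeSeries, target_fs: float) -> EnvelopeSeries:
    """Down-sample an envelope to the control rate by keeping every k-th sample.

    The envelope is already band-limited far below the control rate by the
    final low-pass, so plain sample picking introduces no aliasing and keeps
    the operation exactly causal.
    """
    if target_fs <= 0:
        raise ConfigurationError("target_fs must be positive")
    ratio = env.fs / target_fs
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ConfigurationError(
            f"envelope rate {env.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    return EnvelopeSeries(values=env.values[:, ::k].copy(), fs=target_fs)


def detect_onset(
    env: EnvelopeSeries,
    gain_h: float = 9.0,
    window_ms: float = 150.0,
) -> Optional[OnsetEvent]:
    """Detect the first multi-muscle activation onset, or ``None``.

    The summed envelope ``s`` is compared at every sample ``n`` with a
    threshold ``T(n) = mean + gain_h * std`` of ``s`` over the moving window
    ending at sample ``n - 1`` (the window trails the tested sample, so a
    rising signal cannot inflate its own threshold).  The first sample with
    ``s[n] > T(n)`` strictly is returned; one onset per trial (the task is
    a single reach), hence no further scanning after a detection.
    """
    if gain_h <= 0:
        raise ConfigurationError("gain_h must be positive")
    w = int(round(window_ms * 1e-3 * env.fs))
    if w < 2:
        raise ConfigurationError("window too short at this sampling rate")
    s = env.values.sum(axis=0)
    n = s.size
    if n <= w:
        raise DataError("trial shorter than one onset-detection window")

    windows = sliding_window_view(s, w)          # windows[i] = s[i : i + w]
    mu = windows.mean(axis=1)
    sd = windows.std(axis=1)
    thr = np.full(n, np.nan)
    # Threshold for sample n uses the window ending at n - 1, i.e. s[n-w : n].
    thr[w:] = mu[: n - w] + gain_h * sd[: n - w]
    exceed = np.zeros(n, dtype=bool)
    exceed[w:] = s[w:] > thr[w:]
    hits = np.nonzero(exceed)[0]
    if hits.size == 0:
        return None
    idx = int(hits[0])
    return OnsetEvent(
        index=idx,
        time_s=idx / env.fs,
        threshold_trace=thr,
        sum_trace=s,
    )
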