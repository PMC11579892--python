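"""Movement-direction decoding from synergy activation coefficients.

One Gaussian mixture (three full-covariance components, k-means
initialized, EM fitted) is trained per reaching direction on the activation
coefficients observed while moving toward that direction.  Online, each new
activation vector is scored under all eight mixtures; the densities are
normalized to a probability vector over directions (uniform prior) and
combined across control iterations by a recursive Bayesian product
("evidence accumulation").  The running direction estimate is the argmax of
the cumulative probability vector; once the accumulation time has elapsed
the estimate is frozen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .errors import DataError, TrainingError, TrialExcludedError
from .signal_processing import EnvelopeSeries, OnsetEvent
from .synergy_model import ActivationSeries, SynergyModel, estimate_activations

log = logging.getLogger(__name__)

DIRECTION_NAMES = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")
N_DIRECTIONS = 8


@dataclass(frozen=True)
class DirectionLabel:
    """One of the eight center-out targets.

    ``angle_deg`` is measured counter-clockwise from +x (East) in the home
    frame; ``index`` orders the labels E, NE, N, NW, W, SW, S, SE, i.e. by
    increasing angle in 45-degree steps.
    """

    name: str
    angle_deg: float
    index: int

    @staticmethod
    def from_name(name: str) -> "DirectionLabel":
        try:
            i = DIRECTION_NAMES.index(name)
        except ValueError:
            raise DataError(f"unknown direction label {name!r}") from None
        return DIRECTIONS[i]

    @staticmethod
    def from_index(i: int) -> "DirectionLabel":
        return DIRECTIONS[int(i) % N_DIRECTIONS]


DIRECTIONS: tuple = tuple(
    DirectionLabel(name=n, angle_deg=45.0 * i, index=i)
    for i, n in enumerate(DIRECTION_NAMES)
)


@dataclass
class DirectionGmm:
    """Gaussian mixture density over activation coefficients for one direction."""

    weights: np.ndarray        # (n_components,)
    means: np.ndarray          # (n_components, n_syn)
    covariances: np.ndarray    # (n_components, n_syn, n_syn)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.covariances = np.asarray(self.covariances, float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise DataError("mixture weights must sum to 1")

    def log_pdf(self, x: np.ndarray) -> float:
        """Log mixture density at one point, evaluated in the log domain."""
        x = np.asarray(x, float)
        comps = np.empty(len(self.weights))
        d = x.size
        for j in range(len(self.weights)):
            cov = self.covariances[j]
            chol = np.linalg.cholesky(cov)
            diff = x - self.means[j]
            y = solve_triangular(chol, diff, lower=True)
            maha = float(y @ y)
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
            comps[j] = (
                np.log(self.weights[j] + 1e-300)
                - 0.5 * (d * np.log(2 * np.pi) + logdet + maha)
            )
        return float(logsumexp(comps))


@dataclass
class DecoderModel:
    """Trained intention decoder: synergy basis + per-direction mixtures."""

    synergy: SynergyModel
    gmms: Dict[str, DirectionGmm]
    t_acc_s: float = 0.6
    control_fs: float = 100.0

    def __post_init__(self) -> None:
        if set(self.gmms) != set(DIRECTION_NAMES):
            raise DataError("decoder needs exactly one mixture per direction")
        if self.t_acc_s <= 0:
            raise DataError("t_acc_s must be positive")

    @property
    def n_iterations(self) -> int:
        return int(round(self.t_acc_s * self.control_fs))


@dataclass
class PosteriorTrace:
    """Per-iteration decoding record for one trial.

    ``likelihoods[k]`` is the normalized per-direction probability of the
    k-th activation sample, ``cumulative[k]`` the accumulated (and
    renormalized) probability after that sample, ``estimates[k]`` the index
    of the running argmax estimate.
    """

    likelihoods: np.ndarray    # (n_iter, 8)
    cumulative: np.ndarray     # (n_iter, 8)
    estimates: np.ndarray      # (n_iter,) int direction indices
    final_estimate: DirectionLabel
    n_iterations: int
    activations: Optional[np.ndarray] = None   # (n_iter, n_syn), for audit


def train_gmms(
    H_labeled: ActivationSeries,
    n_components: int = 3,
    seed: int = 0,
    reg: Optional[float] = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> Dict[str, DirectionGmm]:
    """Fit one Gaussian mixture per direction on labeled activation samples.

    Means are initialized by seeded k-means and refined by EM.  Covariances
    are regularized by adding ``reg`` to the diagonal (default: 1e-6 times
    the mean per-feature variance of that direction's data), which keeps
    them positive-definite when activation features contain exact zeros.
    """
    if H_labeled.labels is None:
        raise TrainingError("activation series must carry direction labels")
    X_all = H_labeled.H.T
    n_syn = X_all.shape[1]
    out: Dict[str, DirectionGmm] = {}
    for d in DIRECTION_NAMES:
        X = X_all[H_labeled.labels == d]
        if X.shape[0] < n_components * n_syn:
            raise TrainingError(
                f"direction {d}: {X.shape[0]} samples < {n_components * n_syn} required"
            )
        reg_d = reg if reg is not None else max(1e-6 * float(X.var(axis=0).mean()), 1e-12)
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="full",
            reg_covar=reg_d,
            init_params="kmeans",
            random_state=seed,
            max_iter=max_iter,
            tol=tol,
        ).fit(X)
        out[d] = DirectionGmm(
            weights=gm.weights_.copy(),
            means=gm.means_.copy(),
            covariances=gm.covariances_.copy(),
        )
    return out


def direction_likelihoods(c_k: np.ndarray, model: DecoderModel) -> np.ndarray:
    """Normalized per-direction probability of one activation sample.

    Each direction's mixture density is evaluated at ``c_k`` in the log
    domain and the eight values are normalized to sum to 1 (uniform prior
    over directions).  If every density underflows to zero the function
    returns the uniform vector and logs a warning.
    """
    logs = np.array([model.gmms[d].log_pdf(c_k) for d in DIRECTION_NAMES])
    if np.all(np.isneginf(logs)):
        log.warning("all direction densities underflowed; returning uniform vector")
        return np.full(N_DIRECTIONS, 1.0 / N_DIRECTIONS)
    p = np.exp(logs - logsumexp(logs))
    return p / p.sum()


def accumulate(prev: np.ndarray, likelihoods: np.ndarray) -> np.ndarray:
    """Recursive Bayesian evidence-accumulation update.

    Element-wise product of the previous cumulative vector and the new
    likelihood vector, renormalized to sum to 1.  If the product vanishes
    entirely the previous vector is kept unchanged (degenerate evidence).
    """
    p = np.asarray(prev, float) * np.asarray(likelihoods, float)
    s = p.sum()
    if s <= 0:
        log.warning("accumulated probability vector vanished; keeping previous")
        return np.array(prev, float, copy=True)
    return p / s


def estimate_direction(P_cum: np.ndarray) -> DirectionLabel:
    """Argmax of the cumulative probability vector (ties: lowest index)."""
    return DIRECTIONS[int(np.argmax(P_cum))]


def decode_trial(
    env: EnvelopeSeries,
    onset: OnsetEvent,
    model: DecoderModel,
    keep_activations: bool = False,
) -> PosteriorTrace:
    """Run the full online decoding loop for one trial.

    For every control iteration in ``(t_on, t_on + t_acc]``: estimate
    activations by non-negative least squares, convert to direction
    probabilities, accumulate, and record the running argmax.  The trial is
    excluded if the envelope does not extend one full accumulation window
    beyond the detected onset.
    """
    if abs(env.fs - model.control_fs) > 1e-9:
        raise DataError(
            f"envelope rate {env.fs} Hz != decoder control rate {model.control_fs} Hz"
        )
    n_iter = model.n_iterations
    start = onset.index + 1
    if start + n_iter > env.n_samples:
        raise TrialExcludedError(
            "envelope ends before the accumulation time elapses after onset"
        )

    lik = np.empty((n_iter, N_DIRECTIONS))
    cum = np.empty((n_iter, N_DIRECTIONS))
    est = np.empty(n_iter, dtype=int)
    acts = np.empty((n_iter, model.synergy.n_syn)) if keep_activations else None

    P = np.full(N_DIRECTIONS, 1.0 / N_DIRECTIONS)    # uniform prior at onset
    for k in range(n_iter):
        e_k = env.values[:, start + k]
        c_k = estimate_activations(e_k, model.synergy)
        p_k = direction_likelihoods(c_k, model)
        P = accumulate(P, p_k)
        lik[k] = p_k
        cum[k] = P
        est[k] = int(np.argmax(P))
        if acts is not None:
            acts[k] = c_k

    return PosteriorTrace(
        likelihoods=lik,
        cumulative=cum,
        estimates=est,
        final_estimate=DIRECTIONS[int(est[-1])],
        n_iterations=n_iter,
        activations=acts,
    )
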