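"""Muscle-synergy extraction and online activation estimation.

Offline, the envelope matrix ``E`` [muscles x time] is factorized as
``E ~ W H`` with both factors non-negative: ``W`` [muscles x n_syn] holds
the synergies (fixed co-activation patterns across muscles) and ``H``
[n_syn x time] their time-varying activation coefficients.  The
factorization uses multiplicative updates for the Frobenius objective,
which guarantee a non-increasing root-mean-squared residual at every
iteration; the iteration history is kept so that guarantee can be audited.

Online, given a single envelope sample ``e_k`` and a frozen ``W``, the
activation vector is the non-negative least-squares solution
``argmin_{c >= 0} ||e_k - W c||``, computed with the Lawson-Hanson active
set method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import ConfigurationError, DataError
from .signal_processing import DEFAULT_MUSCLES, EnvelopeSeries

_EPS = 1e-12


@dataclass
class SynergyModel:
    """Extracted synergy basis ``W`` plus extraction metadata.

    Columns of ``W`` are unit Euclidean norm (the scale indeterminacy of the
    factorization is folded into ``H``) so activation coefficients are
    comparable between training and online estimation.
    """

    W: np.ndarray
    n_syn: int
    muscle_names: Sequence[str] = DEFAULT_MUSCLES
    extraction_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[1] != self.n_syn:
            raise DataError("W must be [muscles x n_syn]")
        if np.any(self.W < 0):
            raise DataError("W must be non-negative")
        if np.any(self.W.sum(axis=0) == 0):
            raise DataError("W has an all-zero synergy column")

    @property
    def n_muscles(self) -> int:
        return self.W.shape[0]


@dataclass
class ActivationSeries:
    """Non-negative activation coefficients [n_syn x time], sample-aligned
    with the envelopes they were estimated from; ``labels`` optionally tags
    every sample with the direction of the trial it came from."""

    H: np.ndarray
    fs: float
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.ndim != 2:
            raise DataError("H must be 2-D [n_syn x time]")
        if np.any(self.H < 0):
            raise DataError("H must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.H.shape[1],):
                raise DataError("labels must have one entry per sample")


@dataclass
class NmfOptions:
    max_iter: int = 1000
    tol: float = 1e-6          # relative RMSE change stopping criterion
    restarts: int = 10
    seed: int = 0


def _rmse(E: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    R = E - W @ H
    return float(np.sqrt(np.mean(R * R)))


def _nmf_single(E: np.ndarray, n_syn: int, opts: NmfOptions, seed: int):
    """One multiplicative-update run from a random non-negative init."""
    rng = np.random.default_rng(seed)
    m, t = E.shape
    scale = np.sqrt(E.mean() / n_syn) if E.mean() > 0 else 1.0
    W = rng.uniform(0.0, 1.0, size=(m, n_syn)) * 2 * scale
    H = rng.uniform(0.0, 1.0, size=(n_syn, t)) * 2 * scale
    history = [_rmse(E, W, H)]
    for _ in range(opts.max_iter):
        H *= (W.T @ E) / (W.T @ W @ H + _EPS)
        W *= (E @ H.T) / (W @ (H @ H.T) + _EPS)
        r = _rmse(E, W, H)
        history.append(r)
        prev = history[-2]
        if prev > 0 and (prev - r) / prev < opts.tol:
            break
    return W, H, history


def extract_synergies(
    training_env: EnvelopeSeries,
    n_syn: int = 4,
    options: NmfOptions | None = None,
) -> tuple[SynergyModel, ActivationSeries]:
    """Factorize training envelopes into ``n_syn`` muscle synergies.

    Runs ``options.restarts`` seeded random initializations and keeps the
    run with the lowest final RMSE.  After extraction every column of ``W``
    is rescaled to unit norm with the inverse scale folded into ``H``.
    """
    options = options or NmfOptions()
    E = training_env.values
    m, t = E.shape
    if n_syn < 1 or n_syn > m:
        raise ConfigurationError("n_syn must be between 1 and the number of muscles")
    if t < n_syn:
        raise DataError("training matrix has fewer samples than synergies")
    if not np.any(E > 0):
        raise DataError("training envelope matrix is all zero")

    best = None
    for r in range(options.restarts):
        W, H, history = _nmf_single(E, n_syn, options, seed=options.seed + r)
        if best is None or history[-1] < best[2][-1]:
            best = (W, H, history, r)
    W, H, history, best_restart = best

    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]

    meta = {
        "iterations": len(history) - 1,
        "final_rmse": history[-1],
        "rmse_history": history,
        "restarts": options.restarts,
        "best_restart": best_restart,
        "seed": options.seed,
    }
    model = SynergyModel(W=W, n_syn=n_syn, muscle_names=DEFAULT_MUSCLES[:m]
                         if m <= len(DEFAULT_MUSCLES) else tuple(f"m{i}" for i in range(m)),
                         extraction_meta=meta)
    return model, ActivationSeries(H=H, fs=training_env.fs)


def estimate_activations(e_k: np.ndarray, model: SynergyModel) -> np.ndarray:
    """Non-negative least-squares activation estimate for one envelope sample.

    Returns ``argmin_{c >= 0} ||e_k - W c||_2`` (Lawson-Hanson), which is
    deterministic for fixed inputs.
    """
    e_k = np.asarray(e_k, dtype=float)
    if e_k.shape != (model.n_muscles,):
        raise DataError(
            f"expected envelope sample of length {model.n_muscles}, got {e_k.shape}"
        )
    if not np.all(np.isfinite(e_k)):
        raise DataError("envelope sample contains non-finite values")
    c, _ = nnls(model.W, e_k)
    return c


def match_synergies(W_est: np.ndarray, W_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy column matching by cosine similarity.

    Returns ``(perm, cosines)`` where ``perm[j]`` is the estimated column
    matched to true column ``j``.  Used to undo the permutation
    indeterminacy of the factorization before comparing synergy bases.
    """
    W_est = np.asarray(W_est, float)
    W_true = np.asarray(W_true, float)
    ne = np.linalg.norm(W_est, axis=0)
    nt = np.linalg.norm(W_true, axis=0)
    C = (W_true.T @ W_est) / (np.outer(nt, ne) + _EPS)
    k = W_true.shape[1]
    perm = np.full(k, -1)
    cosines = np.zeros(k)
    used = set()
    # repeatedly take the globally best remaining (true, est) pair
    order = np.dstack(np.unravel_index(np.argsort(-C, axis=None), C.shape))[0]
    for i, j in order:
        if perm[i] == -1 and j not in used:
            perm[i] = j
            cosines[i] = C[i, j]
            used.add(int(j))
    return perm, cosines
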