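"""JTT substitution model: rate matrix, transition probabilities, ML distances.

The continuous-time Markov model is built from the published JTT
exchangeabilities ``S`` and equilibrium frequencies ``pi`` as
``Q[i,j] = S[i,j] * pi[j]`` (off-diagonal), with the diagonal set so rows sum
to zero and the whole matrix scaled so that one unit of time corresponds to
one expected substitution per site: ``-sum_i pi_i Q_ii = 1``. Distances are
therefore in substitutions/site.

``P(t) = expm(Q t)`` is computed from a one-off symmetric eigendecomposition
(``D^{1/2} Q D^{-1/2}`` is symmetric for a reversible model), which makes
repeated evaluations cheap enough for grid oracles and simulation.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

from .jtt_data import AA_ORDER, JTT_FREQUENCIES, JTT_LOWER_TRIANGLE

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Saturation clamp for pairwise distances, substitutions/site.
D_MAX = 10.0
_T_MIN = 1e-6


class SaturationWarning(UserWarning):
    """Emitted when a pairwise distance hits the saturation clamp."""


def exchangeability_matrix() -> np.ndarray:
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = JTT_LOWER_TRIANGLE[k]
            k += 1
    return S


def equilibrium_frequencies() -> np.ndarray:
    pi = np.asarray(JTT_FREQUENCIES, dtype=float)
    return pi / pi.sum()


@lru_cache(maxsize=1)
def _model() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(pi, eigenvalues, left transform, right transform) of the scaled Q."""
    pi = equilibrium_frequencies()
    S = exchangeability_matrix()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    Q /= rate
    # reversible model: D^{1/2} Q D^{-1/2} is symmetric -> stable eigh
    sqrt_pi = np.sqrt(pi)
    A = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    eigval, eigvec = np.linalg.eigh((A + A.T) / 2.0)
    left = eigvec / sqrt_pi[:, None]          # D^{-1/2} U
    right = eigvec.T * sqrt_pi[None, :]       # U^T D^{1/2}
    return pi, eigval, left, right


def rate_matrix() -> np.ndarray:
    """The scaled JTT rate matrix Q (rows sum to 0, mean rate 1)."""
    pi, eigval, left, right = _model()
    return left @ np.diag(eigval) @ right


def stationary_frequencies() -> np.ndarray:
    return _model()[0].copy()


def transition_matrix(t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1."""
    if t < 0:
        raise ValueError("t must be >= 0")
    pi, eigval, left, right = _model()
    P = (left * np.exp(eigval * t)[None, :]) @ right
    return np.clip(P, 0.0, None)


def expected_identity(t: float) -> float:
    """Probability that a site is identical after divergence time t."""
    pi = _model()[0]
    return float(np.dot(pi, np.diag(transition_matrix(t))))


def _pair_counts(row_a: str, row_b: str) -> np.ndarray:
    """20x20 matrix of ungapped aligned residue-pair counts (pairwise deletion)."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    N = np.zeros((20, 20))
    for x, y in zip(row_a.upper(), row_b.upper()):
        i = AA_INDEX.get(x)
        j = AA_INDEX.get(y)
        if i is None or j is None:  # gaps and ambiguous residues dropped
            continue
        N[i, j] += 1
    return N


def log_likelihood(N: np.ndarray, t: float) -> float:
    """Sum over columns of log[ pi(x) P(x->y | t) ] for pair counts N."""
    pi = _model()[0]
    P = transition_matrix(max(t, _T_MIN))
    with np.errstate(divide="ignore"):
        L = np.log(pi[:, None] * P)
    L[np.isneginf(L)] = -1e10
    return float((N * L).sum())


def jtt_ml_distance(
    row_a: str,
    row_b: str,
    d_max: float = D_MAX,
    warn_on_saturation: bool = True,
) -> float:
    """Maximum-likelihood JTT distance between two aligned rows.

    Gapped columns are pairwise-deleted. The likelihood is maximized over
    t in [1e-6, d_max] by bounded scalar optimization (relative tolerance
    1e-8). A distance at the upper bound is reported as d_max with a
    :class:`SaturationWarning`.
    """
    N = _pair_counts(row_a, row_b)
    n_shared = N.sum()
    if n_shared < 1:
        raise ValueError("no shared ungapped columns between rows")
    if N.trace() == n_shared:
        # identical over all comparable sites: optimum sits at the lower bound
        return _T_MIN
    res = minimize_scalar(
        lambda t: -log_likelihood(N, t),
        bounds=(_T_MIN, d_max),
        method="bounded",
        options={"xatol": 1e-8 * d_max},
    )
    t_hat = float(res.x)
    if t_hat >= d_max * (1 - 1e-4):
        if warn_on_saturation:
            warnings.warn(
                f"pairwise distance saturated; clamped to d_max={d_max}",
                SaturationWarning,
                stacklevel=2,
            )
        return d_max
    return t_hat


def jtt_ml_distance_grid(
    row_a: str,
    row_b: str,
    d_max: float = D_MAX,
    n_points: int = 10_000,
    refine: bool = True,
) -> float:
    """Brute-force grid-search counterpart of :func:`jtt_ml_distance`.

    Scans ``n_points`` values of t in [1e-6, d_max]; with ``refine`` a second
    grid of the same size spans one coarse step around the best point. Kept
    independent of the scalar optimizer so the two can check each other.
    """
    N = _pair_counts(row_a, row_b)
    if N.sum() < 1:
        raise ValueError("no shared ungapped columns between rows")

    def best_on(ts: np.ndarray) -> float:
        lls = [log_likelihood(N, t) for t in ts]
        return float(ts[int(np.argmax(lls))])

    ts = np.linspace(_T_MIN, d_max, n_points)
    t0 = best_on(ts)
    if refine:
        step = ts[1] - ts[0]
        ts2 = np.linspace(max(_T_MIN, t0 - step), min(d_max, t0 + step), n_points)
        t0 = best_on(ts2)
    return t0


def corrected_identity_distance(row_a: str, row_b: str, d_max: float = D_MAX) -> float:
    """JTT-corrected p-distance: invert the model's expected-identity curve.

    Solves ``expected_identity(t) = observed identity`` for t; a monotone
    alternative to full ML (``distance_method="identity"`` in the pipeline).
    """
    from scipy.optimize import brentq

    N = _pair_counts(row_a, row_b)
    n = N.sum()
    if n < 1:
        raise ValueError("no shared ungapped columns between rows")
    obs = N.trace() / n
    if obs >= expected_identity(_T_MIN):
        return _T_MIN
    if obs <= expected_identity(d_max):
        warnings.warn(
            f"identity {obs:.3f} below saturation level; clamped to d_max={d_max}",
            SaturationWarning,
            stacklevel=2,
        )
        return d_max
    return float(brentq(lambda t: expected_identity(t) - obs, _T_MIN, d_max, xtol=1e-10))
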