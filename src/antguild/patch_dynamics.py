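"""Food-patch competition dynamics and their quasi-steady state.

The community model tracks discrete food patches per unit area.  Patches
are produced seasonally at rate ``lambda_s * sigma(t)``, are discovered by
foraging ants, are defended by the discovering colony's species, can be
taken over during confrontations according to a behavioral dominance
hierarchy, and are removed either by the holder finishing them
(``lambda_c * c_i``) or by non-focal species (``b``).

With ``D_i = lambda_r * r_i * a_i * N_i * f_i(t)`` the per-area discovery
pressure of species ``i``, the patch equations used throughout are::

    dp0/dt = lambda_s*sigma - p0 * sum_j D_j - b * p0
    dpi/dt = D_i * (p0 + sum_{j!=i} W[i,j] * p_j)
             - p_i * sum_{j!=i} W[j,i] * D_j
             - (lambda_c*c_i + b) * p_i

where ``W[i, j]`` is the probability that species ``i`` takes a contested
patch from species ``j`` (strict hierarchy: 1 iff ``i`` is the more
dominant, equalized dominance: 0.5 everywhere off the diagonal).

Because patch dynamics equilibrate within minutes to hours while colony
densities change year to year, the patch state is resolved at its
quasi-steady state (QSS) separately for each day: ``p0*`` has a closed
form and the occupied densities solve an S x S linear system (triangular
in rank order for a strict hierarchy).  ``patch_ode_rhs`` provides the
full right-hand side as an independent verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phenology import PhenologyCurve

__all__ = [
    "SpeciesTraits",
    "Microhabitat",
    "PatchState",
    "win_matrix",
    "attack_rates",
    "patch_qss",
    "patch_ode_rhs",
    "qss_batch",
]


@dataclass(frozen=True)
class SpeciesTraits:
    """Competitive phenotype of one ant species.

    ``dominance_rank`` counts from 1 (most subordinate) upward.  ``r`` and
    ``c`` are discovery and clearance rates relative to the N. faisonensis
    standard (dimensionless); ``w`` is worker mass in mg; ``a`` is foragers
    per colony.
    """

    name: str
    dominance_rank: int
    r: float
    c: float
    w: float
    a: float
    foraging: PhenologyCurve | None = None

    def __post_init__(self):
        for attr in ("r", "c", "w", "a"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"trait {attr!r} must be positive")


@dataclass(frozen=True)
class Microhabitat:
    """One resource-parameter vector defining a simulated site.

    lambda_s: maximal patch production rate (patches / time / area)
    lambda_c: inverse patch size (1 / time); large = small, quickly
        cleared patches
    eps_prime: food quality, already divided by the colony death rate
        (eps' = eps / mu)
    b: clearance rate by non-focal species (1 / time)
    lambda_r: discovery scale factor; 1 by convention, which fixes the
        model's time and area units.
    """

    lambda_s: float
    lambda_c: float
    eps_prime: float
    b: float
    lambda_r: float = 1.0

    def __post_init__(self):
        for attr in ("lambda_s", "lambda_c", "eps_prime", "b", "lambda_r"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")


@dataclass(frozen=True)
class PatchState:
    """Patch densities per unit area: unoccupied ``p0`` and per-species ``p``."""

    p0: float
    p: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))


def win_matrix(ranks, mode: str = "strict") -> np.ndarray:
    """Patch-takeover probability matrix from dominance ranks.

    strict mode: ``W[i, j] = 1`` iff species i outranks species j (a clear
    and strict behavioral hierarchy); equalized mode: every confrontation
    is a coin flip, all off-diagonal entries 0.5.
    """
    ranks = np.asarray(ranks)
    S = ranks.size
    if sorted(ranks.tolist()) != list(range(1, S + 1)):
        raise ValueError("ranks must be a permutation of 1..S")
    if mode == "strict":
        W = (ranks[:, None] > ranks[None, :]).astype(float)
    elif mode == "equalized":
        W = np.full((S, S), 0.5)
        np.fill_diagonal(W, 0.0)
    else:
        raise ValueError(f"unknown win-matrix mode {mode!r}")
    return W


def attack_rates(N, r, a, f, lambda_r: float = 1.0) -> np.ndarray:
    """Per-area discovery pressure ``D_i = lambda_r * r_i * a_i * N_i * f_i``.

    All arguments broadcast; ``f`` is each species' foraging fraction on
    the day in question.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("colony densities must be non-negative")
    return lambda_r * np.asarray(r, float) * np.asarray(a, float) * N * np.asarray(f, float)


def _qss_matrix(D, lam_c_c, b, W):
    """Coefficient matrix of the QSS linear system (batched over leading axes).

    Row i:  (lambda_c*c_i + b + sum_{j!=i} W[j,i] D_j) p_i
            - D_i sum_{j!=i} W[i,j] p_j  =  D_i p0*
    """
    S = W.shape[0]
    loss_to_dominants = D @ W  # sum_j D_j W[j, i]; diag(W) = 0
    A = -W * D[..., :, None]  # A[..., i, j] = -W[i,j] * D_i
    idx = np.arange(S)
    A[..., idx, idx] = lam_c_c + b[..., None] + loss_to_dominants
    return A


def _solve_batch(A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Batched Gaussian elimination without pivoting.

    The QSS matrix is column diagonally dominant with positive diagonal
    (an M-matrix), so elimination without pivoting is stable and the
    solution is non-negative for a non-negative right-hand side.  For the
    small S here this is much faster than ``np.linalg.solve`` on large
    batches.
    """
    S = A.shape[-1]
    A = np.array(A, dtype=float, copy=True)
    x = np.array(rhs, dtype=float, copy=True)
    for k in range(S):
        piv = A[..., k, k]
        for i in range(k + 1, S):
            m = A[..., i, k] / piv
            A[..., i, k + 1 :] -= m[..., None] * A[..., k, k + 1 :]
            x[..., i] -= m * x[..., k]
    for k in range(S - 1, -1, -1):
        acc = x[..., k]
        for j in range(k + 1, S):
            acc = acc - A[..., k, j] * x[..., j]
        x[..., k] = acc / A[..., k, k]
    return x


def qss_batch(D, lam_s_sigma, lam_c_c, b, W):
    """Quasi-steady-state patch densities, vectorized over leading axes.

    Parameters
    ----------
    D : (..., S) discovery pressures
    lam_s_sigma : (...) seasonal patch production ``lambda_s * sigma(day)``
    lam_c_c : (..., S) per-species clearance ``lambda_c * c_i``
    b : (...) non-focal clearance rate
    W : (S, S) takeover matrix

    Returns ``(p0, p)`` with shapes ``(...)`` and ``(..., S)``.
    """
    D = np.asarray(D, dtype=float)
    b = np.asarray(b, dtype=float)
    lam_s_sigma = np.asarray(lam_s_sigma, dtype=float)
    lam_c_c = np.broadcast_to(np.asarray(lam_c_c, dtype=float), D.shape)
    denom = b + D.sum(axis=-1)
    if np.any(denom <= 0):
        raise ValueError("b + total discovery pressure must be positive")
    p0 = lam_s_sigma / denom
    A = _qss_matrix(D, lam_c_c, b, W)
    p = _solve_batch(A, D * p0[..., None])
    # tiny negative round-off is clipped; anything materially negative is a bug
    if np.any(p < -1e-9 * max(1.0, float(np.max(np.abs(p))))):
        raise AssertionError("QSS solve produced negative patch densities")
    return p0, np.maximum(p, 0.0)


def patch_qss(D, mh: Microhabitat, W: np.ndarray, sigma_day: float, c) -> PatchState:
    """Daily quasi-steady state for one microhabitat.

    ``p0* = lambda_s*sigma / (b + sum_j D_j)`` in closed form; the occupied
    densities solve the linear takeover/clearance balance (see module
    docstring).  ``c`` holds the per-species relative clearance rates.
    The returned state zeroes the patch ODE right-hand side.
    """
    D = np.asarray(D, dtype=float)
    c = np.asarray(c, dtype=float)
    raise_if_bad_W(W, D.size)
    p0, p = qss_batch(D, mh.lambda_s * sigma_day, mh.lambda_c * c, np.asarray(mh.b), W)
    return PatchState(float(p0), p)


def raise_if_bad_W(W: np.ndarray, S: int) -> None:
    W = np.asarray(W)
    if W.shape != (S, S):
        raise ValueError("win matrix has wrong shape")
    if np.any(np.diagonal(W) != 0):
        raise ValueError("win matrix diagonal must be zero")
    if np.any(W + W.T > 1 + 1e-12):
        raise ValueError("W[i,j] + W[j,i] must not exceed 1")


def patch_ode_rhs(state: PatchState, D, mh: Microhabitat, W: np.ndarray, sigma_day: float, c):
    """Full patch ODE right-hand side (the verification oracle for the QSS).

    Returns ``(dp0_dt, dp_dt)``.
    """
    D = np.asarray(D, dtype=float)
    c = np.asarray(c, dtype=float)
    p0 = state.p0
    p = np.asarray(state.p, dtype=float)
    dp0 = mh.lambda_s * sigma_day - p0 * D.sum() - mh.b * p0
    gains = D * (p0 + W @ p)          # discovery of empty patches + takeovers won
    losses_takeover = p * (D @ W)     # patches lost to more dominant discoverers
    losses_clear = (mh.lambda_c * c + mh.b) * p
    return dp0, gains - losses_takeover - losses_clear
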