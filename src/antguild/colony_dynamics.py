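"""Hybrid annual colony dynamics.

Colony densities are treated as constant within a year: each day's patch
occupancy is resolved at quasi-steady state given the day's foraging
fractions ``f_i(d)`` and food production ``sigma(d)``, and the yearly
integral of occupied patches is approximated by the sum of the daily QSS
values.  Food credited to a species when it clears a patch is converted to
new colonies, giving the per-species yearly birth potential::

    B_i = eps' * lambda_c * c_i / (w_i * a_i) * sum_d p_i*(d) * dt

(dividing by worker mass ``w_i`` turns food mass into workers and by
``a_i`` workers into colonies).  Colony densities are then updated by a
discrete annual map::

    N_i(y+1) = N_i(y) + mu * (B_i - L * N_i(y))

whose fixed point ``N_i* = B_i(N*) / L`` does not depend on the colony
death rate ``mu`` -- which is why the model only needs the compound food
quality ``eps' = eps / mu``.  ``mu`` merely sets the relaxation speed of
the map and is numerical plumbing here.

The map is iterated to a community equilibrium; species whose equilibrium
share of colonies falls below an extinction threshold are recorded absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .patch_dynamics import Microhabitat, SpeciesTraits, qss_batch
from .phenology import DAYS_PER_YEAR, PhenologyCurve

__all__ = [
    "DynamicsConfig",
    "CommunityState",
    "EquilibriumRecord",
    "annual_yield",
    "annual_update",
    "iterate_to_equilibrium",
    "ensemble_equilibria",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Plumbing for the annual map.

    mu is the colony death rate per unit time; equilibria are invariant to
    it (to the convergence tolerance), so its default is chosen purely for
    stable, fast relaxation.  The extinction threshold is a relative
    colony share; convergence is measured as the largest per-species
    density change relative to the community total.
    """

    L: float = DAYS_PER_YEAR
    dt: float = 1.0
    mu: float = 0.5 / DAYS_PER_YEAR
    extinction_threshold: float = 1e-3
    convergence_tol: float = 1e-6
    max_years: int = 2000

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if not 0 < self.extinction_threshold <= 0.01:
            raise ValueError("extinction_threshold must lie in (0, 0.01]")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass(frozen=True)
class CommunityState:
    """Per-species colony densities (colonies per unit area)."""

    N: np.ndarray

    def __post_init__(self):
        N = np.asarray(self.N, dtype=float)
        if np.any(N < 0):
            raise ValueError("colony densities must be non-negative")
        object.__setattr__(self, "N", N)


@dataclass(frozen=True)
class EquilibriumRecord:
    N: np.ndarray
    present: np.ndarray
    years: int
    converged: bool


def _daily_arrays(traits: Sequence[SpeciesTraits], sigma: PhenologyCurve, L: int):
    F = np.column_stack([sp.foraging.daily() for sp in traits])  # (L, S)
    sig = sigma.daily()
    if F.shape[0] != L or sig.shape[0] != L:
        raise ValueError("phenology grids must cover every day of the year")
    return F, sig


def annual_yield(
    community: CommunityState,
    traits: Sequence[SpeciesTraits],
    mh: Microhabitat,
    W: np.ndarray,
    sigma: PhenologyCurve,
    config: DynamicsConfig = DynamicsConfig(),
) -> np.ndarray:
    """Yearly birth potential ``B_i`` at fixed colony densities.

    Sums daily QSS patch holdings over the year and converts them to new
    colonies via the food-quality and body-size terms.
    """
    L = int(round(config.L))
    F, sig = _daily_arrays(traits, sigma, L)
    r = np.array([sp.r for sp in traits])
    c = np.array([sp.c for sp in traits])
    w = np.array([sp.w for sp in traits])
    a = np.array([sp.a for sp in traits])
    D = mh.lambda_r * r * a * community.N * F  # (L, S)
    _, p = qss_batch(D, mh.lambda_s * sig, mh.lambda_c * c, np.full(L, mh.b), W)
    return mh.eps_prime * mh.lambda_c * c / (w * a) * p.sum(axis=0) * config.dt


def annual_update(
    community: CommunityState,
    B: np.ndarray,
    config: DynamicsConfig = DynamicsConfig(),
) -> CommunityState:
    """One year-to-year step ``N <- N + mu*(B - L*N)``, clipped at zero."""
    N_new = community.N + config.mu * (B - config.L * community.N)
    if not np.all(np.isfinite(N_new)):
        raise FloatingPointError(f"non-finite colony densities in annual update: {N_new}")
    return CommunityState(np.maximum(N_new, 0.0))


def iterate_to_equilibrium(
    community0: CommunityState,
    traits: Sequence[SpeciesTraits],
    mh: Microhabitat,
    W: np.ndarray,
    sigma: PhenologyCurve,
    config: DynamicsConfig = DynamicsConfig(),
) -> EquilibriumRecord:
    """Iterate the annual map until the community stops changing.

    Convergence: the largest per-species density change in a year is at
    most ``convergence_tol`` times the community total (or the whole
    community has decayed to extinction).  Hitting ``max_years`` is
    reported through the ``converged`` flag, never silently truncated.
    """
    N = np.asarray(community0.N, dtype=float).copy()
    tot0 = max(N.sum(), 1e-300)
    years = 0
    converged = False
    for years in range(1, config.max_years + 1):
        B = annual_yield(CommunityState(N), traits, mh, W, sigma, config)
        N_new = annual_update(CommunityState(N), B, config).N
        tot = N_new.sum()
        if tot <= 1e-12 * tot0:
            N_new = np.zeros_like(N_new)
            N = N_new
            converged = True
            break
        if np.max(np.abs(N_new - N)) <= config.convergence_tol * tot:
            N = N_new
            converged = True
            break
        N = N_new
    share = N / N.sum() if N.sum() > 0 else np.zeros_like(N)
    present = share >= config.extinction_threshold
    N = np.where(present, N, 0.0)
    return EquilibriumRecord(N=N, present=present, years=years, converged=converged)


# --- vectorized ensemble engine ----------------------------------------------


def ensemble_equilibria(
    r,
    c,
    w,
    a,
    lambda_s,
    lambda_c,
    eps_prime,
    b,
    W,
    F,
    sig,
    config: DynamicsConfig = DynamicsConfig(),
    N0=None,
    lambda_r: float = 1.0,
):
    """Community equilibria for K microhabitats at once.

    Parameters
    ----------
    r, c, w, a : (K, S) or (S,) per-habitat species traits (per-habitat
        shapes support trait-equalization scenarios that redraw the shared
        trait value for every microhabitat).
    lambda_s, lambda_c, eps_prime, b : (K,) resource parameters.
    W : (S, S) takeover matrix shared by the ensemble.
    F : (L, S) daily foraging fractions; sig : (L,) or (K, L) daily food
        production (per-habitat for supplementation designs).
    N0 : (K, S) initial colony densities (default 1 everywhere; zero a
        species' column to exclude it, e.g. single-species runs).

    Returns a dict with equilibrium densities ``N`` (K, S), boolean
    ``present`` flags, per-habitat ``years`` and ``converged``.

    The per-year work is one batched QSS solve over (days x habitats), so
    ensembles of thousands of microhabitats run in seconds.
    """
    lambda_s = np.asarray(lambda_s, float)
    K = lambda_s.size
    F = np.asarray(F, float)
    L, S = F.shape

    def per_hab(x):
        x = np.asarray(x, float)
        return np.broadcast_to(x, (K, S)).copy() if x.ndim == 1 else x

    r, c, w, a = map(per_hab, (r, c, w, a))
    lambda_c = np.asarray(lambda_c, float)
    eps_prime = np.asarray(eps_prime, float)
    b = np.asarray(b, float)
    sig = np.asarray(sig, float)
    per_hab_sigma = sig.ndim == 2

    if N0 is None:
        N = np.ones((K, S))
    else:
        N = np.array(N0, float, copy=True)
    tot0 = np.maximum(N.sum(axis=1), 1e-300)

    years = np.zeros(K, dtype=int)
    converged = np.zeros(K, dtype=bool)
    active = np.arange(K)

    birth_coef = eps_prime[:, None] * lambda_c[:, None] * c / (w * a)  # (K, S)
    mu, Lyr, tol = config.mu, config.L, config.convergence_tol

    for _ in range(config.max_years):
        if active.size == 0:
            break
        Na = N[active]  # (k, S)
        DN = lambda_r * r[active] * a[active] * Na  # (k, S)
        D = F[:, None, :] * DN[None, :, :]  # (L, k, S)
        sig_a = sig[active].T[:, :] if per_hab_sigma else sig[:, None]
        lam_s_sig = lambda_s[active][None, :] * sig_a  # (L, k)
        lam_cc = (lambda_c[active][:, None] * c[active])[None, :, :]  # (1, k, S)
        _, p = qss_batch(D, lam_s_sig, np.broadcast_to(lam_cc, D.shape), b[active][None, :], W)
        B = birth_coef[active] * p.sum(axis=0) * config.dt  # (k, S)
        N_new = np.maximum(Na + mu * (B - Lyr * Na), 0.0)
        if not np.all(np.isfinite(N_new)):
            raise FloatingPointError("non-finite colony densities in ensemble update")
        years[active] += 1
        tot = N_new.sum(axis=1)
        dead = tot <= 1e-12 * tot0[active]
        N_new[dead] = 0.0
        done = dead | (np.max(np.abs(N_new - Na), axis=1) <= tol * tot)
        N[active] = N_new
        converged[active[done]] = True
        active = active[~done]

    share = np.divide(N, N.sum(axis=1, keepdims=True), out=np.zeros_like(N), where=N.sum(axis=1, keepdims=True) > 0)
    present = share >= config.extinction_threshold
    N = np.where(present, N, 0.0)
    return {"N": N, "present": present, "years": years, "converged": converged}
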