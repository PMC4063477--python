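"""Ensemble reporting: composition fractions, relative abundances, evenness.

The unit of replication is the microhabitat; reported quantities are the
fraction of microhabitats with each possible species combination, the
per-species relative abundance averaged over the ensemble, and Pielou's
evenness of that distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import EnsembleResult

__all__ = [
    "EnsembleSummary",
    "composition_fractions",
    "mean_relative_abundance",
    "pielou_evenness",
    "abundance_weights",
    "summarize",
]


@dataclass(frozen=True)
class EnsembleSummary:
    scenario: str
    K: int
    composition_fractions: dict[str, float]
    mean_rel_abundance: dict[str, float]
    evenness: float


def _patterns(S: int) -> list[str]:
    return [format(m, f"0{S}b") for m in range(2**S)]


def composition_fractions(ensemble: EnsembleResult) -> dict[str, float]:
    """Fraction of microhabitats with each presence pattern.

    Patterns are bit strings in species order ("101" = first and third
    species present); fractions over all 2^S patterns sum to 1.
    """
    pres = ensemble.presence_matrix()
    K, S = pres.shape
    codes = pres @ (1 << np.arange(S - 1, -1, -1))
    counts = np.bincount(codes, minlength=2**S)
    return {pat: counts[int(pat, 2)] / K for pat in _patterns(S)}


def mean_relative_abundance(
    ensemble: EnsembleResult, method: str = "ratio_of_means", weights=None
) -> np.ndarray:
    """Ensemble-averaged relative abundance per species.

    Default is the ratio of means, ``sum_k N_ik / sum_k sum_j N_jk``,
    consistent with percent changes computed on ensemble totals.  The
    mean-of-ratios alternative averages each microhabitat's relative
    abundances (all-extinct microhabitats contribute nothing to either
    convention).

    ``weights`` converts colony counts to another abundance currency
    before forming shares: per-species foragers ``a_i`` gives worker
    abundance, ``w_i * a_i`` gives standing worker biomass.  Cross-species
    comparisons of "abundance" between species whose workers differ 13x in
    body mass depend strongly on this choice; see
    :func:`abundance_weights`.
    """
    N = ensemble.N_matrix()
    if weights is not None:
        N = N * np.asarray(weights, dtype=float)
    tot = N.sum(axis=1)
    if not np.any(tot > 0):
        raise ValueError("all microhabitats extinct: relative abundances undefined")
    if method == "ratio_of_means":
        return N.sum(axis=0) / N.sum()
    if method == "mean_of_ratios":
        alive = tot > 0
        q = N[alive] / tot[alive, None]
        return q.mean(axis=0)
    raise ValueError(f"unknown method {method!r}")


def pielou_evenness(rel_abundance) -> float:
    """Pielou's evenness ``H / ln(S)`` of a relative-abundance distribution.

    ``H = -sum q_i ln q_i`` over positive entries; the denominator uses the
    full species count S, and a single-species distribution returns 0
    (H = 0 by convention).  Input must sum to 1.
    """
    q = np.asarray(rel_abundance, dtype=float)
    if q.ndim != 1 or q.size < 2:
        raise ValueError("need a 1-d distribution over at least 2 species")
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("relative abundances must be non-negative and sum to 1")
    pos = q[q > 0]
    H = float(-(pos * np.log(pos)).sum())
    return H / np.log(q.size)


def abundance_weights(ensemble: EnsembleResult, convention: str = "colonies") -> np.ndarray:
    """Per-species multipliers turning colony counts into an abundance currency.

    "colonies" counts nests, "workers" counts foragers (``a_i N_i``), and
    "biomass" weighs standing forager biomass (``w_i a_i N_i``).  Biomass is
    the currency under which the model's historical community is close to
    even; colony counts are always dominated by the smallest-bodied species,
    whose workers cost 13x less food each.
    """
    from .synthetic_data import _TRAIT_TABLE  # default three-species guild

    if convention == "colonies":
        return np.ones(len(ensemble.species))
    rows = [_TRAIT_TABLE[sp] for sp in ensemble.species]
    if convention == "workers":
        return np.array([row["a"] for row in rows])
    if convention == "biomass":
        return np.array([row["w"] * row["a"] for row in rows])
    raise ValueError(f"unknown abundance convention {convention!r}")


def summarize(
    ensemble: EnsembleResult, method: str = "ratio_of_means", weights=None
) -> EnsembleSummary:
    """Collate one scenario's reporting quantities."""
    q = mean_relative_abundance(ensemble, method, weights=weights)
    return EnsembleSummary(
        scenario=ensemble.scenario.name,
        K=ensemble.K,
        composition_fractions=composition_fractions(ensemble),
        mean_rel_abundance={sp: float(v) for sp, v in zip(ensemble.species, q)},
        evenness=pielou_evenness(q),
    )
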