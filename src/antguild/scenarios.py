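"""Experiment drivers: baseline, trait equalizations, climate scenarios.

Each experiment runs the community model to equilibrium over an ensemble
of K "microhabitats" -- resource-parameter vectors (lambda_s, lambda_c,
eps', b) drawn uniformly from their empirical ranges -- and reports one
equilibrium record per microhabitat.  Scenario contrasts use common random
numbers: at the same seed and K, every scenario sees the *identical*
microhabitat stream, so differences between scenarios are never sampling
noise.  Trait-equalization scenarios redraw the shared trait value
independently for each microhabitat from a separate random stream that
does not disturb the microhabitat draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .colony_dynamics import DynamicsConfig, ensemble_equilibria
from .patch_dynamics import Microhabitat, SpeciesTraits, win_matrix
from .phenology import DAYS_PER_YEAR, PhenologyCurve, apply_warming, shift_phenology
from .synthetic_data import (
    SPECIES,
    default_traits,
    load_fixture_phenologies,
    load_temperature_series,
    load_thermal_responses,
)

__all__ = [
    "TABLE1_RANGES",
    "EQUALIZABLE_TRAITS",
    "Scenario",
    "EnsembleResult",
    "sample_microhabitats",
    "equalize_trait",
    "run_ensemble",
    "run_single_species",
    "percent_change",
    "scenario_grid",
]

#: Uniform sampling ranges for the resource parameters.
TABLE1_RANGES = {
    "lambda_s": (0.0, 200.0),
    "lambda_c": (0.0, 200.0),
    "eps_prime": (0.0, 2.0),
    "b": (0.1, 0.2),
}

EQUALIZABLE_TRAITS = ("discovery", "clearance", "mass", "dominance", "thermal_niche")
_TRAIT_ATTR = {"discovery": "r", "clearance": "c", "mass": "w"}


@dataclass(frozen=True)
class Scenario:
    """One experiment: what is changed relative to the fully parameterized model.

    kind: "baseline", "equalize" (with ``trait``), "shift" (with ``weeks``)
    or "warm" (with ``delta_t``).  ``solo`` restricts the community to a
    single species (competitors' densities fixed at zero).
    """

    kind: str = "baseline"
    trait: str | None = None
    weeks: int | None = None
    delta_t: float | None = None
    solo: str | None = None

    def __post_init__(self):
        if self.kind not in ("baseline", "equalize", "shift", "warm"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "equalize" and self.trait not in EQUALIZABLE_TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.kind == "shift" and self.weeks not in (1, 2, 3, 4):
            raise ValueError("shift scenarios use weeks in 1..4")
        if self.kind == "warm" and self.delta_t not in (1, 2, 3, 4, 5):
            raise ValueError("warming scenarios use delta_t in 1..5")
        if self.solo is not None and self.solo not in SPECIES:
            raise ValueError(f"unknown species {self.solo!r}")

    @property
    def name(self) -> str:
        core = {
            "baseline": "baseline",
            "equalize": f"equalize-{self.trait}",
            "shift": f"shift-{self.weeks}wk",
            "warm": f"warm-{self.delta_t}C",
        }[self.kind]
        return core if self.solo is None else f"{core}/solo-{self.solo}"

    def variants(self) -> list["Scenario"]:
        """The community run plus the three single-species runs."""
        return [replace(self, solo=None)] + [replace(self, solo=sp) for sp in SPECIES]


@dataclass(frozen=True)
class EnsembleResult:
    """Equilibrium records for one scenario over K microhabitats."""

    scenario: Scenario
    K: int
    seed: int
    species: tuple[str, ...]
    records: pd.DataFrame

    def N_matrix(self) -> np.ndarray:
        return self.records[[f"N_{sp}" for sp in self.species]].to_numpy()

    def presence_matrix(self) -> np.ndarray:
        return self.records[[f"present_{sp}" for sp in self.species]].to_numpy(bool)

    def total_abundance(self) -> np.ndarray:
        """Per-species colony totals summed over microhabitats."""
        return self.N_matrix().sum(axis=0)


def sample_microhabitats(K: int, ranges=None, rng_seed: int = 0) -> list[Microhabitat]:
    """K independent uniform draws of the resource-parameter vector.

    The draw order is fixed (lambda_s, lambda_c, eps_prime, b per habitat),
    so the stream depends only on the seed and K -- the basis of the
    common-random-number discipline across scenarios.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    ranges = dict(TABLE1_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"inverted range for {name!r}")
    rng = np.random.default_rng(rng_seed)
    u = rng.random((K, 4))
    cols = {}
    for j, name in enumerate(("lambda_s", "lambda_c", "eps_prime", "b")):
        lo, hi = ranges[name]
        cols[name] = lo + (hi - lo) * u[:, j]
    return [
        Microhabitat(cols["lambda_s"][k], cols["lambda_c"][k], cols["eps_prime"][k], cols["b"][k])
        for k in range(K)
    ]


def equalize_trait(
    traits: Sequence[SpeciesTraits],
    which: str,
    rng: np.random.Generator,
):
    """Remove interspecific variation in one trait.

    discovery/clearance/mass: every species gets the same value, drawn
    uniformly from the range the three species span.  dominance: contested
    patches become coin flips (all off-diagonal takeover probabilities
    0.5).  thermal_niche: every species forages at full effort year-round.
    Returns ``(traits', W')``.
    """
    if which not in EQUALIZABLE_TRAITS:
        raise ValueError(f"unknown trait {which!r}")
    ranks = [sp.dominance_rank for sp in traits]
    W = win_matrix(ranks, "strict")
    if which == "dominance":
        return list(traits), win_matrix(ranks, "equalized")
    if which == "thermal_niche":
        flat = PhenologyCurve(np.arange(0.0, DAYS_PER_YEAR), np.ones(365))
        return [replace(sp, foraging=flat) for sp in traits], W
    attr = _TRAIT_ATTR[which]
    vals = [getattr(sp, attr) for sp in traits]
    shared = float(rng.uniform(min(vals), max(vals)))
    return [replace(sp, **{attr: shared}) for sp in traits], W


def _scenario_phenologies(scenario: Scenario, traits, resource):
    """Foraging matrix F (L, S) and daily resource sigma (L,) for a scenario."""
    curves = [sp.foraging for sp in traits]
    sigma = resource
    if scenario.kind == "shift":
        curves = [shift_phenology(cv, scenario.weeks) for cv in curves]
        sigma = shift_phenology(resource, scenario.weeks)
    elif scenario.kind == "warm":
        temps = load_temperature_series()
        responses = load_thermal_responses()
        curves = [
            apply_warming(cv, responses[sp.name], temps, scenario.delta_t)
            for cv, sp in zip(curves, traits)
        ]
    elif scenario.kind == "equalize" and scenario.trait == "thermal_niche":
        flat = PhenologyCurve(np.arange(0.0, DAYS_PER_YEAR), np.ones(365))
        curves = [flat for _ in curves]
    F = np.column_stack([cv.daily() for cv in curves])
    return F, sigma.daily()


def run_ensemble(
    scenario: Scenario,
    K: int,
    seed: int,
    traits: Sequence[SpeciesTraits] | None = None,
    resource: PhenologyCurve | None = None,
    ranges=None,
    config: DynamicsConfig = DynamicsConfig(),
) -> EnsembleResult:
    """Run one scenario over K common-random-number microhabitats.

    Per-microhabitat non-convergence is recorded in the ``converged``
    column, never raised.
    """
    if traits is None:
        traits = default_traits()
    if resource is None:
        resource = load_fixture_phenologies()["resource"]
    species = tuple(sp.name for sp in traits)
    S = len(species)

    mhs = sample_microhabitats(K, ranges, seed)
    lam_s = np.array([m.lambda_s for m in mhs])
    lam_c = np.array([m.lambda_c for m in mhs])
    eps = np.array([m.eps_prime for m in mhs])
    b = np.array([m.b for m in mhs])

    r = np.array([sp.r for sp in traits])
    c = np.array([sp.c for sp in traits])
    w = np.array([sp.w for sp in traits])
    a = np.array([sp.a for sp in traits])
    W = win_matrix([sp.dominance_rank for sp in traits], "strict")

    if scenario.kind == "equalize" and scenario.trait in _TRAIT_ATTR:
        # shared value redrawn independently for every microhabitat, from a
        # stream separate from the microhabitat draws
        eq_rng = np.random.default_rng([seed, 1])
        attr = _TRAIT_ATTR[scenario.trait]
        base = {"r": r, "c": c, "w": w}[attr]
        shared = eq_rng.uniform(base.min(), base.max(), size=K)
        arrs = {"r": r, "c": c, "w": w}
        arrs[attr] = np.repeat(shared[:, None], S, axis=1)
        r, c, w = arrs["r"], arrs["c"], arrs["w"]
    elif scenario.kind == "equalize" and scenario.trait == "dominance":
        W = win_matrix([sp.dominance_rank for sp in traits], "equalized")

    F, sig = _scenario_phenologies(scenario, traits, resource)

    N0 = np.ones((K, S))
    if scenario.solo is not None:
        keep = species.index(scenario.solo)
        N0[:, [j for j in range(S) if j != keep]] = 0.0

    out = ensemble_equilibria(r, c, w, a, lam_s, lam_c, eps, b, W, F, sig, config, N0=N0)

    rec = pd.DataFrame({"lambda_s": lam_s, "lambda_c": lam_c, "eps_prime": eps, "b": b})
    for j, sp in enumerate(species):
        rec[f"N_{sp}"] = out["N"][:, j]
        rec[f"present_{sp}"] = out["present"][:, j]
    rec["years"] = out["years"]
    rec["converged"] = out["converged"]
    return EnsembleResult(scenario=scenario, K=K, seed=seed, species=species, records=rec)


def run_single_species(
    scenario: Scenario,
    species: str,
    K: int,
    seed: int,
    **kwargs,
) -> EnsembleResult:
    """As :func:`run_ensemble` with competitors' densities fixed at zero."""
    return run_ensemble(replace(scenario, solo=species), K, seed, **kwargs)


def percent_change(reference: EnsembleResult, treated: EnsembleResult) -> dict[str, float]:
    """Per-species percent change in ensemble totals between two scenarios.

    ``100 * (sum_k N'_ik - sum_k N_ik) / sum_k N_ik`` over the common K
    microhabitats; NaN where the reference total is zero (undefined).
    """
    if reference.K != treated.K or reference.species != treated.species:
        raise ValueError("ensembles must share K and the species set")
    if reference.seed != treated.seed:
        raise ValueError("percent change requires common random numbers (same seed)")
    ref = reference.total_abundance()
    new = treated.total_abundance()
    out = {}
    for sp, x, y in zip(reference.species, ref, new):
        out[sp] = float(100.0 * (y - x) / x) if x > 0 else float("nan")
    return out


def scenario_grid() -> list[Scenario]:
    """The experiment list: baseline, 5 equalizations, 4 shifts, 5 warmings."""
    grid = [Scenario()]
    grid += [Scenario(kind="equalize", trait=t) for t in EQUALIZABLE_TRAITS]
    grid += [Scenario(kind="shift", weeks=wk) for wk in (1, 2, 3, 4)]
    grid += [Scenario(kind="warm", delta_t=dt) for dt in (1, 2, 3, 4, 5)]
    return grid
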