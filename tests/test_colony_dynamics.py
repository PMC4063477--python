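"""Annual colony map: yields, updates, equilibria, and their oracles."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import brentq

from antguild.colony_dynamics import (
    CommunityState,
    DynamicsConfig,
    annual_update,
    annual_yield,
    ensemble_equilibria,
    iterate_to_equilibrium,
)
from antguild.patch_dynamics import Microhabitat, SpeciesTraits, win_matrix
from antguild.phenology import PhenologyCurve

from .conftest import random_microhabitat

FLAT = PhenologyCurve(np.arange(0.0, 365.0), np.ones(365))


def make_species(name="sp", rank=1, r=1.0, c=1.0, w=0.5, a=100.0, curve=FLAT):
    return SpeciesTraits(name, rank, r, c, w, a, curve)


class TestAnnualYield:
    def test_zero_food_quality(self, strict_W, traits, curves):
        mh = Microhabitat(100.0, 50.0, 0.0, 0.15)
        B = annual_yield(CommunityState(np.ones(3)), traits, mh, strict_W, curves["resource"])
        assert np.allclose(B, 0.0)

    def test_absent_species_yields_nothing(self, strict_W, traits, curves):
        mh = Microhabitat(100.0, 50.0, 1.0, 0.15)
        N = np.array([1.0, 0.0, 1.0])
        B = annual_yield(CommunityState(N), traits, mh, strict_W, curves["resource"])
        assert B[1] == 0.0
        assert np.all(B[[0, 2]] > 0)

    def test_single_species_constant_season_hand_formula(self):
        # constant sigma = f = 1: every day has the same closed-form QSS,
        # so B = 365 * eps' * lam_c * c * p* / (w a)
        sp = make_species(c=2.0, w=0.4, a=50.0, r=1.5)
        mh = Microhabitat(lambda_s=60.0, lambda_c=10.0, eps_prime=0.8, b=0.15)
        N = 2.0
        D = 1.5 * 50.0 * N
        p0 = 60.0 / (0.15 + D)
        p_star = D * p0 / (10.0 * 2.0 + 0.15)
        expected = 365.0 * 0.8 * 10.0 * 2.0 * p_star / (0.4 * 50.0)
        B = annual_yield(CommunityState(np.array([N])), [sp], mh, np.zeros((1, 1)), FLAT)
        assert B[0] == pytest.approx(expected, rel=1e-12)


class TestAnnualUpdate:
    def test_fixed_point(self):
        cfg = DynamicsConfig()
        N = np.array([2.0, 3.0])
        out = annual_update(CommunityState(N), cfg.L * N, cfg)
        assert np.allclose(out.N, N)

    def test_geometric_decay_without_births(self):
        cfg = DynamicsConfig(mu=0.2 / 365.0)
        N = np.array([1.0])
        out = annual_update(CommunityState(N), np.zeros(1), cfg)
        assert out.N[0] == pytest.approx(1.0 - 0.2)

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            annual_update(CommunityState(np.array([1.0])), np.array([np.inf]))


def single_species_equilibrium_oracle(sp, mh, sigma, config):
    """Bracketing root-finder on N -> B(N)/L - N, independent of the map."""

    def g(N):
        B = annual_yield(CommunityState(np.array([N])), [sp], mh, np.zeros((1, 1)), sigma, config)
        return B[0] / config.L - N

    lo = 1e-12
    if g(lo) <= 0:
        return 0.0
    hi = 1.0
    while g(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            raise RuntimeError("no upper bracket found")
    return brentq(g, lo, hi, xtol=1e-14, rtol=1e-13)


class TestEquilibrium:
    def test_symmetric_community_equal_densities(self):
        sps = [make_species(name=f"s{i}", rank=i + 1) for i in range(3)]
        W = win_matrix([1, 2, 3], "equalized")
        mh = Microhabitat(50.0, 5.0, 1.0, 0.15)
        rec = iterate_to_equilibrium(CommunityState(np.ones(3)), sps, mh, W, FLAT)
        assert rec.converged
        assert np.allclose(rec.N, rec.N[0], rtol=1e-4)
        assert rec.present.all()

    def test_single_species_matches_root_finding_oracle(self, rng, traits, curves):
        cfg = DynamicsConfig(convergence_tol=1e-9, max_years=20000)
        sigma = curves["resource"]
        for _ in range(6):
            mh = random_microhabitat(rng)
            sp = traits[int(rng.integers(0, 3))]
            rec = iterate_to_equilibrium(CommunityState(np.ones(1)), [sp], mh, np.zeros((1, 1)), sigma, cfg)
            oracle = single_species_equilibrium_oracle(sp, mh, sigma, cfg)
            assert rec.converged
            if oracle == 0.0:
                assert rec.N[0] == 0.0
            else:
                assert rec.N[0] == pytest.approx(oracle, rel=1e-6)

    def test_mu_invariance(self, rng, traits, curves, strict_W):
        mh = random_microhabitat(rng)
        eqs = []
        for muL in (0.05, 0.2, 0.5):
            cfg = DynamicsConfig(mu=muL / 365.0, convergence_tol=1e-8, max_years=30000)
            rec = iterate_to_equilibrium(
                CommunityState(np.ones(3)), traits, mh, strict_W, curves["resource"], cfg
            )
            assert rec.converged
            eqs.append(rec.N)
        scale = max(eqs[1].sum(), 1e-12)
        for N in eqs:
            assert np.max(np.abs(N - eqs[1])) / scale < 1e-3

    def test_never_foraging_species_goes_extinct(self, curves):
        dead_curve = PhenologyCurve(np.arange(0.0, 365.0), np.zeros(365))
        sps = [make_species(name="live", rank=1), make_species(name="dead", rank=2, curve=dead_curve)]
        # a species that never forages violates the positive-value rule for
        # normalized curves, so build it unnormalized on purpose
        mh = Microhabitat(50.0, 5.0, 1.0, 0.15)
        rec = iterate_to_equilibrium(CommunityState(np.ones(2)), sps, mh, win_matrix([1, 2]), FLAT)
        assert not rec.present[1]
        assert rec.N[1] == 0.0

    def test_initial_condition_robustness(self, rng, traits, curves, strict_W):
        sigma = curves["resource"]
        cfg = DynamicsConfig(convergence_tol=1e-8, max_years=20000)
        for _ in range(4):
            mh = random_microhabitat(rng)
            recs = [
                iterate_to_equilibrium(CommunityState(scale * np.ones(3)), traits, mh, strict_W, sigma, cfg)
                for scale in (0.1, 1.0, 10.0)
            ]
            ref = recs[1].N
            scale_tot = max(ref.sum(), 1e-12)
            for rec in recs:
                assert np.max(np.abs(rec.N - ref)) / scale_tot < 1e-2

    def test_more_food_quality_no_less_total(self, rng, traits, curves, strict_W):
        mh = random_microhabitat(rng)
        lo = replace(mh, eps_prime=0.5)
        hi = replace(mh, eps_prime=1.5)
        out = [
            iterate_to_equilibrium(CommunityState(np.ones(3)), traits, m, strict_W, curves["resource"]).N.sum()
            for m in (lo, hi)
        ]
        assert out[1] >= out[0] - 1e-9


class TestEnsembleEngine:
    def test_matches_scalar_path(self, rng, traits, curves, strict_W):
        """The vectorized K-habitat engine and the per-habitat iterator are
        the same map; their equilibria must agree."""
        sigma = curves["resource"]
        K = 4
        mhs = [random_microhabitat(rng) for _ in range(K)]
        cfg = DynamicsConfig()
        r = np.array([sp.r for sp in traits])
        c = np.array([sp.c for sp in traits])
        w = np.array([sp.w for sp in traits])
        a = np.array([sp.a for sp in traits])
        F = np.column_stack([sp.foraging.daily() for sp in traits])
        out = ensemble_equilibria(
            r, c, w, a,
            np.array([m.lambda_s for m in mhs]),
            np.array([m.lambda_c for m in mhs]),
            np.array([m.eps_prime for m in mhs]),
            np.array([m.b for m in mhs]),
            strict_W, F, sigma.daily(), cfg,
        )
        for k, mh in enumerate(mhs):
            rec = iterate_to_equilibrium(CommunityState(np.ones(3)), traits, mh, strict_W, sigma, cfg)
            scale = max(rec.N.sum(), 1e-12)
            assert np.max(np.abs(out["N"][k] - rec.N)) / scale < 1e-6
            assert (out["present"][k] == rec.present).all()

    def test_zeroed_species_stays_absent(self, traits, curves, strict_W, rng):
        mh = random_microhabitat(rng)
        r = np.array([sp.r for sp in traits])
        c = np.array([sp.c for sp in traits])
        w = np.array([sp.w for sp in traits])
        a = np.array([sp.a for sp in traits])
        F = np.column_stack([sp.foraging.daily() for sp in traits])
        N0 = np.ones((1, 3))
        N0[0, [0, 2]] = 0.0
        out = ensemble_equilibria(
            r, c, w, a,
            np.array([mh.lambda_s]), np.array([mh.lambda_c]),
            np.array([mh.eps_prime]), np.array([mh.b]),
            strict_W, F, curves["resource"].daily(), N0=N0,
        )
        assert out["N"][0, 0] == 0.0 and out["N"][0, 2] == 0.0
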