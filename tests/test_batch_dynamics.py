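"""Deterministic batch-growth and serial-dilution dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dilusim import (
    BatchConfig,
    CommunityState,
    NutrientState,
    StrategyVector,
    batch_derivatives,
    dilute,
    equally_spaced_community,
    hull_contains,
    run_batch,
    run_serial,
    uptake_rates,
)
from dilusim.exceptions import (
    DegenerateCommunityError,
    DimensionMismatchError,
    NondepletionError,
)

from .oracles import euler_batch


def community(strategies, biomass):
    return CommunityState(np.asarray(strategies, float), np.asarray(biomass, float))


class TestUptake:
    def test_half_saturation_gives_half_alpha(self):
        comm = community([[0.6, 0.4]], [1.0])
        nut = NutrientState([1.0, 1.0], half_saturation=1.0)
        j = uptake_rates(comm, nut)
        assert j[0, 0] == pytest.approx(0.3)
        assert j[0, 1] == pytest.approx(0.2)

    def test_zero_concentration_zero_uptake(self):
        comm = community([[0.6, 0.4], [0.1, 0.9]], [1.0, 2.0])
        j = uptake_rates(comm, NutrientState([0.0, 0.0], 1.0))
        assert np.all(j == 0)

    def test_saturating_limit_approaches_alpha(self):
        comm = community([[0.6, 0.4]], [1.0])
        j = uptake_rates(comm, NutrientState([1e6, 1e6], 1.0))
        assert j[0] == pytest.approx([0.6, 0.4], rel=1e-6)

    def test_dimension_mismatch_raises(self):
        comm = community([[0.6, 0.4]], [1.0])
        with pytest.raises(DimensionMismatchError):
            uptake_rates(comm, NutrientState([1.0, 1.0, 1.0], 1.0))


class TestDerivatives:
    def test_empty_biomass_gives_zero_derivatives(self):
        comm = community([[0.5, 0.5]], [0.0])
        dc, drho = batch_derivatives(comm, NutrientState([1.0, 1.0], 1.0))
        assert np.all(dc == 0) and np.all(drho == 0)

    def test_single_species_direct_evaluation(self):
        comm = community([[1.0]], [1.0])
        dc, drho = batch_derivatives(comm, NutrientState([1.0], 1.0))
        assert dc[0] == pytest.approx(-0.5)
        assert drho[0] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(1, 5), st.integers(1, 3), st.integers(0, 2**32 - 1))
    def test_total_mass_flux_is_zero(self, m, p, seed):
        rng = np.random.default_rng(seed)
        alphas = rng.dirichlet(np.ones(p), size=m)
        comm = community(alphas, rng.uniform(0, 2, m))
        dc, drho = batch_derivatives(
            comm, NutrientState(rng.uniform(0, 3, p), rng.uniform(0.1, 5))
        )
        assert dc.sum() + drho.sum() == pytest.approx(0, abs=1e-12)


class TestRunBatch:
    def test_mass_conservation_single_species(self):
        comm = community([[1.0]], [1.0])
        cfg = BatchConfig(c0=2.0, nutrient_fractions=[1.0], rho0=1.0, K=1.0)
        end, tc = run_batch(comm, cfg)
        assert end.total_biomass == pytest.approx(3.0, abs=1e-6 * cfg.c0)

    def test_identical_strategies_stay_equal(self):
        comm = community([[0.3, 0.7], [0.3, 0.7]], [0.5, 0.5])
        cfg = BatchConfig(c0=1.0, nutrient_fractions=[0.6, 0.4], rho0=1.0, K=1.0)
        end, _ = run_batch(comm, cfg)
        assert end.biomass[0] == pytest.approx(end.biomass[1], rel=1e-9)

    def test_specialists_symmetric_under_nutrient_swap(self):
        comm = community([[1.0, 0.0], [0.0, 1.0]], [0.5, 0.5])
        cfg = BatchConfig(c0=0.01, nutrient_fractions=[0.5, 0.5], rho0=1.0, K=1.0)
        end, _ = run_batch(comm, cfg)
        assert end.biomass[0] == pytest.approx(end.biomass[1], rel=1e-7)

    def test_nondepletion_error_carries_timecourse(self):
        # Nobody can consume nutrient 2, so total nutrient never depletes.
        comm = community([[1.0, 0.0]], [1.0])
        cfg = BatchConfig(
            c0=1.0, nutrient_fractions=[0.5, 0.5], rho0=1.0, K=1.0, max_time=50.0
        )
        with pytest.raises(NondepletionError) as err:
            run_batch(comm, cfg)
        assert err.value.timecourse is not None
        assert err.value.timecourse.times[-1] == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_forward_euler_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alphas = rng.dirichlet(np.ones(2), size=5)
        biomass = rng.uniform(0.1, 0.4, 5)
        c_init = np.array([0.7, 0.3])
        comm = community(alphas, biomass)
        cfg = BatchConfig(
            c0=1.0, nutrient_fractions=[0.7, 0.3], rho0=biomass.sum(), K=1.0
        )
        end, _ = run_batch(comm, cfg)
        _, rho_euler = euler_batch(alphas, biomass, c_init, K=1.0)
        assert end.biomass == pytest.approx(rho_euler, rel=1e-3)


class TestDilute:
    def test_proportional_rescale(self):
        comm = community([[1.0, 0.0], [0.0, 1.0]], [3.0, 1.0])
        out = dilute(comm, 1.0)
        assert out.biomass == pytest.approx([0.75, 0.25])

    def test_idempotent_at_fixed_rho0(self):
        comm = community([[1.0, 0.0], [0.0, 1.0]], [3.0, 1.0])
        once = dilute(comm, 2.0)
        twice = dilute(once, 2.0)
        assert twice.biomass == pytest.approx(once.biomass)

    def test_zero_biomass_raises(self):
        comm = community([[1.0, 0.0]], [0.0])
        with pytest.raises(DegenerateCommunityError):
            dilute(comm, 1.0)


class TestRunSerial:
    def test_single_species_steady_at_batch_one(self):
        comm = community([[0.5, 0.5]], [1.0])
        cfg = BatchConfig(c0=1.0, nutrient_fractions=[0.5, 0.5], rho0=1.0, K=1.0)
        _, ss = run_serial(comm, cfg, max_batches=3)
        assert ss == 1

    def test_unfed_specialist_declines_monotonically(self):
        # Supply is entirely nutrient 1; the nutrient-2 specialist never grows
        # and its inoculum fraction must fall every batch.  The end-of-batch
        # state is cross-checked against the fixed-step Euler oracle.
        strategies = np.array([[1.0, 0.0], [0.0, 1.0]])
        comm = community(strategies, [0.5, 0.5])
        cfg = BatchConfig(c0=1.0, nutrient_fractions=[1.0, 0.0], rho0=1.0, K=1.0)
        table, _ = run_serial(comm, cfg, max_batches=5)
        frac2 = table.iloc[:, 1].to_numpy()
        assert np.all(np.diff(frac2) < 0)
        end, _ = run_batch(dilute(comm, 1.0), cfg)
        _, rho_euler = euler_batch(
            strategies, np.array([0.5, 0.5]), np.array([1.0, 0.0]), K=1.0
        )
        assert end.biomass == pytest.approx(rho_euler, rel=1e-3)

    def test_extinction_cutoff_removes_rare_species(self):
        # Supply entirely nutrient 1: the nutrient-2 specialist declines and,
        # with the optional cutoff, is zeroed once rare; by default it is not.
        comm = community([[1.0, 0.0], [0.0, 1.0]], [0.5, 0.5])
        cfg = BatchConfig(c0=2.0, nutrient_fractions=[1.0, 0.0], rho0=1.0, K=1.0)
        kept, _ = run_serial(comm, cfg, max_batches=8)
        cut, _ = run_serial(comm, cfg, max_batches=8, extinction_cutoff=0.05)
        assert kept.iloc[-1, 1] > 0
        assert cut.iloc[-1, 1] == 0
        assert cut.iloc[-1, 0] == pytest.approx(1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        alphas = rng.dirichlet(np.ones(2), size=4)
        biomass = rng.uniform(0.1, 0.5, 4)
        cfg = BatchConfig(c0=1.0, nutrient_fractions=[0.6, 0.4], rho0=1.0, K=1.0)
        perm = np.array([2, 0, 3, 1])
        t1, _ = run_serial(community(alphas, biomass), cfg, 3)
        t2, _ = run_serial(community(alphas[perm], biomass[perm]), cfg, 3)
        assert t1.to_numpy()[:, perm] == pytest.approx(t2.to_numpy(), rel=1e-9)


class TestStrategyConstructors:
    def test_equally_spaced_three(self):
        comm = equally_spaced_community(3)
        alphas = np.array([s.alphas for s in comm])
        np.testing.assert_allclose(
            alphas, [[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]], atol=1e-15
        )

    def test_endpoints_are_pure_specialists(self):
        comm = equally_spaced_community(21)
        assert comm[0].alphas == pytest.approx([0.0, 1.0])
        assert comm[-1].alphas == pytest.approx([1.0, 0.0])

    def test_budget_always_one(self):
        for s in equally_spaced_community(14):
            assert s.alphas.sum() == pytest.approx(1.0, abs=1e-12)

    def test_higher_simplex_unsupported(self):
        with pytest.raises(DimensionMismatchError):
            equally_spaced_community(5, p=3)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            StrategyVector([-0.1, 1.1])

    def test_budget_violation_rejected(self):
        with pytest.raises(ValueError):
            StrategyVector([0.5, 0.6])


class TestHullContains:
    @pytest.mark.parametrize(
        "supply, expected",
        [([0.5, 0.5], True), ([0.9, 0.1], False), ([0.2, 0.8], True)],
    )
    def test_two_nutrient_interval(self, supply, expected):
        strategies = [StrategyVector([a, 1 - a]) for a in (0.2, 0.5, 0.8)]
        assert hull_contains(strategies, supply) is expected

    def test_supply_on_vertex_is_inside(self):
        strategies = [StrategyVector([0.3, 0.7]), StrategyVector([0.6, 0.4])]
        assert hull_contains(strategies, [0.3, 0.7])

    def test_three_nutrient_hull(self):
        strategies = [
            StrategyVector([0.8, 0.1, 0.1]),
            StrategyVector([0.1, 0.8, 0.1]),
            StrategyVector([0.1, 0.1, 0.8]),
        ]
        assert hull_contains(strategies, [1 / 3, 1 / 3, 1 / 3])
        assert not hull_contains(strategies, [0.9, 0.05, 0.05])
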