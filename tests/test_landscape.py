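"""Free-energy landscapes: barriers, staircase pathway, matching, slopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisscross.architectures import (
    AssemblyState,
    CrisscrossSlats,
    HexTileTube,
    SquareTileTube,
)
from crisscross.calibration import (
    G_MC_SLATS,
    G_MC_TILES,
    REFERENCE_BARRIERS,
    benchmark_landscape,
    benchmark_params,
    calibrate_slats,
    calibrate_tiles,
)
from crisscross.energies import EnergyParams, epsilon_from_gse, gse_from_epsilon
from crisscross.landscape import (
    UnbracketedError,
    barrier_vs_epsilon,
    critical_nucleus,
    eps0_barrier,
    exhaustive_min_peak,
    free_energy,
    landscape_with_seed,
    match_architectures,
    relative_nucleation_rate,
)


class TestEnergies:
    def test_free_energy_arithmetic(self, cs6):
        params = EnergyParams(g_mc=6.0, g_se=4.0 / 3.0, epsilon=2.0)
        state = AssemblyState.from_occupancy(cs6, [("y", 0), ("x", 0)])
        assert state.B == 1
        assert free_energy(state, params) == pytest.approx(12 - 4 / 3)
        assert free_energy(AssemblyState.empty(), params) == 0.0

    def test_gse_reversible_limit(self):
        assert gse_from_epsilon(0.0, 6, 6.0) == pytest.approx(1.0)
        assert gse_from_epsilon(2.0, 6, 6.0) == pytest.approx(8 / 6)

    @given(
        st.floats(0.0, 5.0),
        st.integers(1, 12),
        st.floats(0.5, 12.0),
    )
    def test_gse_epsilon_round_trip(self, eps, n, g_mc):
        g_se = gse_from_epsilon(eps, n, g_mc)
        assert epsilon_from_gse(g_se, n, g_mc) == pytest.approx(eps, abs=1e-12)

    def test_gmc_from_concentration(self):
        p = EnergyParams.for_architecture(6, 2.0, concentration=1e-6)
        assert p.g_mc == pytest.approx(6.0)

    def test_additive_under_attachment(self, cs6):
        params = EnergyParams.for_architecture(6, 2.0, concentration=1e-6)
        state = AssemblyState.from_occupancy(cs6, [("y", 0)])
        grown = state.attach(cs6, ("x", 0))
        dG = free_energy(grown, params) - free_energy(state, params)
        assert dG == pytest.approx(params.g_mc - 1 * params.g_se)


class TestCriticalNucleus:
    def test_cs_nucleus_is_2n_at_near_reversible(self, cs6):
        params = EnergyParams.for_architecture(6, 0.0, concentration=1e-6)
        ls = critical_nucleus(cs6, params)
        assert ls.critical_size == 12
        assert ls.bonds_at_critical == 36
        # at eps -> 0 the staircase peak IS the junction free energy
        assert ls.barrier == pytest.approx(ls.peak)
        assert ls.barrier == pytest.approx(6 * params.g_mc)

    def test_profile_starts_at_zero(self, cs6):
        ls = critical_nucleus(cs6, benchmark_params("CS6"))
        assert ls.G_profile[0] == 0.0

    def test_staircase_bond_conservation(self, cs6):
        # B accumulated along the pathway equals B of the final occupancy
        params = benchmark_params("CS6")
        ls = critical_nucleus(cs6, params)
        final = ls.pathway[-1]
        n_att = len(final)
        G_final = ls.G_profile[n_att]
        B_from_G = (n_att * params.g_mc - G_final) / params.g_se
        assert B_from_G == pytest.approx(cs6.bond_count(final), abs=1e-9)

    def test_dimer_chain_barrier_at_single_monomer(self):
        # n = 1 chain with g_se > g_mc (eps > 0): every addition past the
        # first is downhill, so the barrier is g_mc at N = 1; verified by
        # exhaustive enumeration of all assemblies to size 4
        arch = CrisscrossSlats(half_coordination=1)
        params = EnergyParams.for_architecture(1, 1.0, g_mc=3.0)
        assert params.g_se > params.g_mc
        ls = critical_nucleus(arch, params, max_size=4, method="search")
        assert ls.barrier == pytest.approx(3.0)
        assert ls.critical_size == 1
        assert exhaustive_min_peak(arch, params.g_mc, params.g_se, 4) == pytest.approx(
            3.0
        )

    def test_unbracketed_raises(self, cs6):
        params = benchmark_params("CS6")
        with pytest.raises(UnbracketedError):
            critical_nucleus(cs6, params, max_size=5)
        # negative eps: chain rises forever
        bad = EnergyParams.for_architecture(6, -1.0, g_mc=6.0)
        with pytest.raises(UnbracketedError):
            critical_nucleus(cs6, bad)


class TestOracleEquivalence:
    @pytest.mark.parametrize("max_size", [5, 7])
    @pytest.mark.parametrize(
        "arch",
        [
            SquareTileTube(3),
            HexTileTube(3),
            CrisscrossSlats(2),
        ],
        ids=["ST3", "HT3", "CS2"],
    )
    def test_best_first_equals_exhaustive(self, arch, max_size):
        g_mc = G_MC_TILES
        g_se = gse_from_epsilon(2.0, arch.n, g_mc)
        params = EnergyParams(g_mc=g_mc, g_se=g_se, epsilon=2.0)
        ls = critical_nucleus(arch, params, max_size=max_size, method="search")
        oracle = exhaustive_min_peak(arch, g_mc, g_se, max_size)
        assert ls.peak == pytest.approx(oracle, abs=1e-9)

    def test_cs_staircase_is_minimal(self):
        # the analytic staircase pathway max equals the exact search min-max
        arch = CrisscrossSlats(half_coordination=3)
        for eps in (0.0, 1.0, 2.0):
            params = EnergyParams.for_architecture(3, eps, g_mc=6.0)
            stair = critical_nucleus(arch, params, max_size=8)
            exact = critical_nucleus(arch, params, max_size=8, method="search")
            assert stair.peak == pytest.approx(exact.peak, abs=1e-9)


class TestBarrierCurve:
    def test_monotone_in_epsilon(self, cs6, st3):
        for arch in (cs6, st3):
            p0 = EnergyParams.for_architecture(arch.n, 0.0, concentration=1e-6)
            curve = barrier_vs_epsilon(arch, p0, np.linspace(0, 3, 13))
            barriers = [pt.barrier for pt in curve]
            sizes = [pt.critical_size for pt in curve]
            assert all(b >= b2 - 1e-12 for b, b2 in zip(barriers, barriers[1:]))
            assert all(s >= s2 for s, s2 in zip(sizes, sizes[1:]))

    def test_slope_law_minus_bstar_over_n(self, cs6):
        # where the critical nucleus composition is constant,
        # d(barrier)/d(eps) = -B*/n exactly
        p0 = EnergyParams.for_architecture(6, 0.0, g_mc=G_MC_SLATS)
        eps, delta = 1.0, 1e-4
        pts = barrier_vs_epsilon(cs6, p0, [eps, eps + delta])
        assert pts[0].critical_size == pts[1].critical_size == 12
        slope = (pts[1].barrier - pts[0].barrier) / delta
        b_star = 36
        assert slope == pytest.approx(-b_star / 6, abs=1e-6)

    def test_rejects_bad_grid(self, cs6):
        p0 = EnergyParams.for_architecture(6, 0.0, concentration=1e-6)
        with pytest.raises(ValueError):
            barrier_vs_epsilon(cs6, p0, [-1.0, 0.0])


class TestRelativeRate:
    def test_decades_difference(self):
        assert relative_nucleation_rate(34.4, 10.8) == pytest.approx(23.6)
        assert relative_nucleation_rate(13.9, 10.8) == pytest.approx(3.1)
        assert relative_nucleation_rate(5.0, 5.0) == 0.0


class TestSeededLandscape:
    def test_seeded_profile_flat_then_downhill(self, cs6):
        params = benchmark_params("CS6")
        ls = landscape_with_seed(cs6, params)
        assert ls.seeded
        n = cs6.n
        assert list(ls.G_profile[: 2 * n + 1]) == [0.0] * (2 * n + 1)
        steps = np.diff(ls.G_profile[2 * n :])
        assert np.allclose(steps, -params.epsilon)

    def test_seeded_never_above_unseeded_barrier(self, cs6):
        params = benchmark_params("CS6")
        seeded = landscape_with_seed(cs6, params)
        unseeded = critical_nucleus(cs6, params)
        assert max(seeded.G_profile) <= unseeded.barrier

    def test_requires_cs(self, st3):
        with pytest.raises(ValueError):
            landscape_with_seed(st3, benchmark_params("ST"))


class TestEps0AndMatching:
    @pytest.mark.parametrize("m", [3, 4])
    def test_tube_eps0_formulas_match_exact_search(self, m):
        g_mc = 6.0
        for arch, size in ((SquareTileTube(m), m + 3), (HexTileTube(m), m + 3)):
            g_se = g_mc / arch.n
            exact = exhaustive_min_peak(arch, g_mc, g_se, size)
            assert eps0_barrier(arch, g_mc) == pytest.approx(exact, abs=1e-9)

    def test_match_cs_to_st(self, cs6):
        ref = benchmark_params("CS6", 0.0)
        res = match_architectures(cs6, ref, "ST")
        assert abs(res.barrier_eps0 - eps0_barrier(cs6, ref.g_mc)) < 1e-6
        assert res.architecture.circumference >= 3
        assert eps0_barrier(res.architecture, res.params.g_mc) == pytest.approx(
            res.barrier_eps0, abs=1e-9
        )

    def test_match_st_to_ht_verified_by_search(self, st3):
        # small circumferences: the matched barrier is confirmed by the exact
        # search, not just the ring formula
        ref = EnergyParams.for_architecture(2, 0.0, g_mc=G_MC_TILES)
        res = match_architectures(st3, ref, "HT", max_circumference=4)
        assert abs(res.barrier_eps0 - eps0_barrier(st3, ref.g_mc)) < 1e-6
        m = res.architecture.circumference
        exact = exhaustive_min_peak(
            res.architecture, res.params.g_mc, res.params.g_se, m + 3
        )
        assert exact == pytest.approx(res.barrier_eps0, abs=1e-9)

    def test_match_to_itself_is_identity(self, cs6):
        ref = benchmark_params("CS6", 0.0)
        res = match_architectures(cs6, ref, "CS")
        assert res.params.g_mc == pytest.approx(ref.g_mc)

    def test_infeasible_circumference_bound(self, cs6):
        from crisscross.landscape import MatchError

        with pytest.raises(MatchError):
            match_architectures(cs6, benchmark_params("CS6", 0.0), "ST",
                                max_circumference=1)


class TestCalibration:
    def test_calibration_round_trip(self):
        assert calibrate_tiles() == pytest.approx(G_MC_TILES, abs=1e-9)
        assert calibrate_slats() == pytest.approx(G_MC_SLATS, abs=1e-9)

    def test_tile_benchmark_barriers_print_correctly(self):
        # HT is out-of-sample: only ST was fitted
        assert round(benchmark_landscape("ST").barrier, 1) == REFERENCE_BARRIERS["ST"]
        assert round(benchmark_landscape("HT").barrier, 1) == REFERENCE_BARRIERS["HT"]
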