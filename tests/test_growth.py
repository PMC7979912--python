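"""Stochastic growth model: simulation, analytic solution, fitting, PDI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisscross.growth import (
    GrowthParams,
    LengthSample,
    analytic_mean_length,
    fit_growth_model,
    polydispersity_index,
    rate_constant_from_velocity,
    ribbon_count_from_seeds,
    simulate_ribbons,
    velocity_from_rate_constant,
)

FAST = GrowthParams(v=0.75, k_stall=2e-3, k_resume=1e-3, k_term=2e-5)


class TestSimulate:
    def test_deterministic_limit(self):
        p = GrowthParams(v=0.5)
        samples = simulate_ribbons(p, [1, 2], 20, rng_seed=0)
        assert np.allclose(samples[0].lengths, 0.5 * 3600)
        assert np.allclose(samples[1].lengths, 0.5 * 7200)

    def test_reproducible_under_seed(self):
        a = simulate_ribbons(FAST, [1, 4], 50, rng_seed=11)
        b = simulate_ribbons(FAST, [1, 4], 50, rng_seed=11)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.lengths, sb.lengths)

    def test_mean_matches_analytic_within_3se(self):
        samples = simulate_ribbons(FAST, [1, 2, 4, 8, 16], 10_000, rng_seed=5)
        for s in samples:
            mean, _ = analytic_mean_length(FAST, s.time_h)
            assert abs(s.mean - mean) < 3 * s.sem

    def test_large_t_mean_approaches_veff_over_kterm(self):
        p = GrowthParams(v=0.3, k_term=1e-4)
        samples = simulate_ribbons(p, [200.0], 10_000, rng_seed=9)
        s = samples[0]
        assert abs(s.mean - p.v_eff / p.k_term) < 3 * s.sem

    def test_lengths_monotone_per_ribbon(self):
        samples = simulate_ribbons(FAST, [1, 2, 4], 200, rng_seed=3)
        stack = np.vstack([s.lengths for s in samples])
        assert (np.diff(stack, axis=0) >= -1e-9).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            GrowthParams(v=-1.0)
        with pytest.raises(ValueError):
            simulate_ribbons(FAST, [2, 1], 5, rng_seed=0)
        with pytest.raises(ValueError):
            simulate_ribbons(FAST, [1], 0, rng_seed=0)


class TestAnalyticMean:
    def test_zero_time(self):
        assert analytic_mean_length(FAST, 0.0) == (0.0, 0.0)

    def test_kterm_zero_limit_is_linear(self):
        p = GrowthParams(v=0.75, k_stall=2e-3, k_resume=1e-3, k_term=0.0)
        mean, sd = analytic_mean_length(p, 2.0)
        assert mean == pytest.approx(p.v_eff * 7200)

    def test_continuity_at_small_kterm(self):
        p0 = GrowthParams(v=0.5, k_term=0.0)
        p1 = GrowthParams(v=0.5, k_term=1e-12)
        m0, _ = analytic_mean_length(p0, 3.0)
        m1, _ = analytic_mean_length(p1, 3.0)
        assert m1 == pytest.approx(m0, rel=1e-6)

    def test_sd_matches_simulation_without_stalling(self):
        p = GrowthParams(v=0.5, k_term=5e-5)
        mean, sd = analytic_mean_length(p, 8.0)
        s = simulate_ribbons(p, [8.0], 20_000, rng_seed=2)[0]
        assert abs(s.lengths.std() - sd) / sd < 0.05

    @given(st.floats(0.1, 30.0), st.floats(1e-6, 1e-3))
    @settings(max_examples=25)
    def test_mean_monotone_in_t_and_kterm(self, t, k):
        p = GrowthParams(v=0.5, k_term=k)
        m1, _ = analytic_mean_length(p, t)
        m2, _ = analytic_mean_length(p, t + 1.0)
        assert m2 >= m1
        p_hi = GrowthParams(v=0.5, k_term=k * 2)
        m_hi, _ = analytic_mean_length(p_hi, t)
        assert m_hi <= m1 + 1e-9


class TestFit:
    def test_noiseless_self_consistency(self):
        ts = [1, 2, 4, 8, 16]
        samples = [
            LengthSample(t, np.full(30, analytic_mean_length(FAST, t)[0]))
            for t in ts
        ]
        fit = fit_growth_model(samples, n_bootstrap=10)
        assert fit.v_eff == pytest.approx(FAST.v_eff, rel=1e-6)
        assert fit.k_term == pytest.approx(FAST.k_term, rel=1e-6)

    def test_too_few_timepoints(self):
        s = [LengthSample(1.0, np.ones(5)), LengthSample(2.0, np.ones(5))]
        with pytest.raises(ValueError):
            fit_growth_model(s)

    def test_all_zero_lengths(self):
        s = [LengthSample(t, np.zeros(5)) for t in (1.0, 2.0, 3.0)]
        with pytest.raises(ValueError):
            fit_growth_model(s)

    def test_nucleation_rate_from_counts(self):
        ts = [1, 2, 4]
        samples = [
            LengthSample(t, np.full(30, analytic_mean_length(FAST, t)[0]))
            for t in ts
        ]
        J = 5e-19
        counts = [(t, J * t * 3600) for t in (2.0, 5.0, 10.0)]
        fit = fit_growth_model(samples, n_bootstrap=5, unseeded_counts=counts)
        assert fit.J == pytest.approx(J, rel=1e-9)


class TestPDI:
    def test_monodisperse_is_one(self):
        assert polydispersity_index([5.0, 5.0, 5.0]) == pytest.approx(1.0)

    def test_exponential_is_two_in_expectation(self):
        ls = np.random.default_rng(0).exponential(1000.0, 400_000)
        assert polydispersity_index(ls) == pytest.approx(2.0, rel=0.02)

    @given(
        st.lists(st.floats(0.1, 1e4), min_size=1, max_size=50)
    )
    def test_always_at_least_one(self, lengths):
        assert polydispersity_index(lengths) >= 1.0 - 1e-12

    def test_seeded_less_polydisperse_than_unseeded(self):
        # synchronized (seeded) starts vs staggered Poisson nucleation with
        # identical growth kinetics
        rng = np.random.default_rng(7)
        t_end = 8 * 3600.0
        seeded = simulate_ribbons(FAST, [8.0], 10_000, rng_seed=1)[0].lengths
        starts = rng.uniform(0.0, t_end, 10_000)
        unseeded_raw = simulate_ribbons(FAST, [8.0], 10_000, rng_seed=2)[0].lengths
        unseeded = unseeded_raw * (t_end - starts) / t_end
        assert polydispersity_index(seeded) < polydispersity_index(unseeded)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            polydispersity_index([])
        with pytest.raises(ValueError):
            polydispersity_index([0.0, 0.0])


class TestRateConstant:
    def test_printed_scale(self):
        # 0.75 nm/s at 1 uM slats and 1.5 nm/slat -> 0.5e6 /M/s
        assert rate_constant_from_velocity(0.75, 1e-6, 1.5) == pytest.approx(0.5e6)

    def test_zero_velocity(self):
        assert rate_constant_from_velocity(0.0, 1e-6) == 0.0

    @given(st.floats(1e-3, 10.0), st.floats(1e-8, 1e-5))
    def test_round_trip(self, v, conc):
        k = rate_constant_from_velocity(v, conc)
        assert velocity_from_rate_constant(k, conc) == pytest.approx(v, rel=1e-12)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            rate_constant_from_velocity(0.5, 0.0)


class TestRibbonCount:
    def test_full_conversion(self):
        assert ribbon_count_from_seeds(2e-9, 1.0) == 2e-9

    def test_linearity(self):
        assert ribbon_count_from_seeds(1e-9) * 2 == ribbon_count_from_seeds(2e-9)
        assert ribbon_count_from_seeds(2e-9, 0.0) == 0.0

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            ribbon_count_from_seeds(1e-9, 1.5)
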