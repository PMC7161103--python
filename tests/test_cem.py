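import numpy as np
import pytest

from epmclock import (
    CEMConfig,
    SiteParameters,
    aligned_pearson,
    fit_epm,
    fit_mc,
    rss,
    simulate_epm,
    simulate_mc,
    site_step,
)
from epmclock.oracle import build_design_system, solve_mc_naive

from conftest import random_instance


def _assert_nonincreasing(trace):
    arr = np.asarray(trace)
    tol = 1e-12 * max(1.0, float(arr[0]))
    assert np.all(np.diff(arr) <= tol), f"RSS trace increased: {arr}"


class TestRSS:
    def test_zero_at_true_parameters_of_noiseless_data(self):
        matrix, ages, truth = simulate_mc(n=5, m=6, sigma=0.0, seed=1)
        params = SiteParameters(rates=truth.rates, start_states=truth.start_states)
        assert rss(matrix, params, ages.ages) == pytest.approx(0.0, abs=1e-20)

    def test_single_entry_hand_value(self):
        # one residual: (3 - (1 + 1*1))^2 = 1; second individual on the line
        from epmclock import MethylationMatrix

        matrix = MethylationMatrix(np.array([[3.0, 3.0]]), ["s"], ["a", "b"])
        params = SiteParameters(rates=[1.0], start_states=[1.0])
        assert rss(matrix, params, np.array([1.0, 2.0])) == pytest.approx(1.0)

    def test_equals_oracle_residual_norm(self, rng):
        for _ in range(10):
            matrix, ages = random_instance(rng)
            n = matrix.n_sites
            params = SiteParameters(rates=rng.normal(0, 1, n),
                                    start_states=rng.normal(0, 1, n))
            sys = build_design_system(matrix, ages)
            beta = np.concatenate([params.rates, params.start_states])
            expected = float(np.sum((sys.y - sys.X @ beta) ** 2))
            assert rss(matrix, params, ages.ages) == pytest.approx(
                expected, rel=1e-10, abs=1e-12)


class TestFitMC:
    def test_zero_noise_gives_zero_rss_and_true_parameters(self):
        matrix, ages, truth = simulate_mc(n=10, m=8, sigma=0.0, seed=2)
        result = fit_mc(matrix, ages)
        assert result.final_rss == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(result.params.rates, truth.rates, atol=1e-10)
        np.testing.assert_allclose(result.params.start_states, truth.start_states,
                                   atol=1e-10)
        assert result.converged and result.iterations == 1
        np.testing.assert_array_equal(result.e_ages.e_ages, ages.ages)

    def test_beats_100_random_perturbations(self, mc_instance, rng):
        matrix, ages, _ = mc_instance
        result = fit_mc(matrix, ages)
        n = matrix.n_sites
        for _ in range(100):
            perturbed = SiteParameters(
                rates=result.params.rates + rng.normal(0, 1e-3, n),
                start_states=result.params.start_states + rng.normal(0, 1e-3, n),
            )
            assert rss(matrix, perturbed, ages.ages) >= result.final_rss

    def test_identical_to_bare_site_step(self, mc_instance):
        matrix, ages, _ = mc_instance
        result = fit_mc(matrix, ages)
        direct = site_step(matrix, ages)
        np.testing.assert_array_equal(result.params.rates, direct.rates)
        np.testing.assert_array_equal(result.params.start_states, direct.start_states)

    def test_naive_engine_agrees_with_closed_form(self, mc_instance):
        matrix, ages, _ = mc_instance
        fast = fit_mc(matrix, ages, engine="closed_form")
        slow = fit_mc(matrix, ages, engine="naive")
        np.testing.assert_allclose(fast.params.rates, slow.params.rates, atol=1e-8)
        assert fast.final_rss == pytest.approx(slow.final_rss, rel=1e-10)


class TestFitEPM:
    def test_mc_truth_is_a_fixed_point(self):
        matrix, ages, _ = simulate_mc(n=10, m=8, sigma=0.0, seed=3)
        result = fit_epm(matrix, ages)
        assert result.final_rss == pytest.approx(0.0, abs=1e-16)
        np.testing.assert_allclose(result.e_ages.e_ages, ages.ages, atol=1e-8)
        assert result.converged

    def test_noiseless_epm_data_fit_exactly(self):
        matrix, ages, truth = simulate_epm(n=20, m=12, sigma=0.0, seed=4)
        result = fit_epm(matrix, ages)
        nm = matrix.values.size
        assert result.final_rss <= 1e-16 * nm
        fitted = (result.params.start_states[:, None]
                  + np.outer(result.params.rates, result.e_ages.e_ages))
        np.testing.assert_allclose(fitted, matrix.values, atol=1e-8)

    def test_trace_nonincreasing_and_nested_below_mc(self, epm_instance):
        matrix, ages, _ = epm_instance
        result = fit_epm(matrix, ages)
        _assert_nonincreasing(result.rss_trace)
        assert result.final_rss <= fit_mc(matrix, ages).final_rss
        assert result.final_rss == result.rss_trace[-1]

    def test_trace_nonincreasing_on_random_inputs(self, rng):
        for _ in range(10):
            matrix, ages = random_instance(rng, n=6, m=8)
            result = fit_epm(matrix, ages, CEMConfig(delta_cem=1e-10, max_iters=50))
            _assert_nonincreasing(result.rss_trace)
            assert result.final_rss <= fit_mc(matrix, ages).final_rss + 1e-12

    def test_gauge_transformation_leaves_rss_unchanged(self, epm_instance, rng):
        matrix, ages, _ = epm_instance
        result = fit_epm(matrix, ages)
        t = result.e_ages.e_ages
        for _ in range(20):
            a = rng.uniform(0.2, 5.0) * rng.choice([-1.0, 1.0])
            b = rng.uniform(-50.0, 50.0)
            mapped = SiteParameters(
                rates=result.params.rates / a,
                start_states=result.params.start_states - (b / a) * result.params.rates,
            )
            assert rss(matrix, mapped, a * t + b) == pytest.approx(
                result.final_rss, rel=1e-10, abs=1e-12)

    def test_parameter_recovery_under_noise(self):
        matrix, ages, truth = simulate_epm(n=300, m=80, sigma=0.02, seed=5)
        result = fit_epm(matrix, ages)
        corr = aligned_pearson(result.e_ages.e_ages, truth.epigenetic_ages)
        assert corr >= 0.95

    def test_relative_improvement_mode_converges(self, epm_instance):
        matrix, ages, _ = epm_instance
        cfg = CEMConfig(delta_cem=1e-8, max_iters=200, improvement_mode="relative")
        result = fit_epm(matrix, ages, cfg)
        assert result.converged
        _assert_nonincreasing(result.rss_trace)

    def test_max_iters_cap_respected(self, epm_instance):
        matrix, ages, _ = epm_instance
        result = fit_epm(matrix, ages, CEMConfig(delta_cem=1e-300, max_iters=3))
        assert result.iterations == 3
        assert not result.converged

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CEMConfig(delta_cem=0.0)
        with pytest.raises(ValueError):
            CEMConfig(max_iters=0)
        with pytest.raises(ValueError):
            CEMConfig(improvement_mode="bogus")
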