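import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipm.errors import ConfigurationError, DataError, DomainError
from ipm.process_chain import ProcessChain, propagate
from ipm.simulation import (ooa_probability, parametric_ooa,
                            plausibility_report, run_ipm, sample_parameters,
                            sd_upper_confidence_limit)
from ipm.synthetic import generate_manufacturing_runs

from conftest import fixed_chain, make_cqa, make_param, passthrough_chain


def param_chain(params, usl=100.0, start_sd=0.0):
    cqa = make_cqa(usl=usl, start_sd=start_sd)
    from ipm.process_chain import UnitOperation
    uos = [UnitOperation(name="U1", order=1, models={})]
    return ProcessChain(unit_operations=uos, parameters=params, cqas=[cqa])


class TestSampleParameters:
    def test_degenerate_nor_gives_set_point(self):
        p = make_param(nor_half=0.0)
        draws = sample_parameters(param_chain([p]), 100, rng_seed=1)
        assert (draws["p1"] == 5.0).all()

    def test_sd_is_one_third_of_halfwidth(self):
        p = make_param(sp=0.0, nor_half=0.3, sr_half=1.0)
        draws = sample_parameters(param_chain([p]), 1_000_000, rng_seed=2)
        assert draws["p1"].std(ddof=1) == pytest.approx(0.1, rel=0.01)
        assert draws["p1"].mean() == pytest.approx(0.0, abs=0.001)

    def test_fixed_parameter_constant(self):
        p = make_param()
        draws = sample_parameters(param_chain([p]), 50,
                                  fixed=("p1", p.sr_low), rng_seed=3)
        assert (draws["p1"] == p.sr_low).all()

    def test_fixed_outside_screening_range_rejected(self):
        p = make_param()
        with pytest.raises(DomainError):
            sample_parameters(param_chain([p]), 10,
                              fixed=("p1", p.sr_high + 1.0))

    def test_reproducible_from_seed(self):
        p = make_param()
        a = sample_parameters(param_chain([p]), 100, rng_seed=7)
        b = sample_parameters(param_chain([p]), 100, rng_seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestSdUpperConfidenceLimit:
    def test_value_at_n5(self):
        # chi-square 5% quantile at 4 df -> inflation ~2.372
        expected = np.sqrt(4 / stats.chi2.ppf(0.05, 4))
        assert expected == pytest.approx(2.372, abs=5e-4)
        assert sd_upper_confidence_limit(1.0, 5) == pytest.approx(expected)

    def test_conservatism_and_monotone_decrease(self):
        prev = np.inf
        for n in range(3, 101):
            ratio = sd_upper_confidence_limit(1.0, n)
            assert ratio >= 1.0
            assert ratio < prev
            prev = ratio

    def test_needs_two_values(self):
        with pytest.raises(DataError):
            sd_upper_confidence_limit(1.0, 1)


class TestOOAProbability:
    def test_far_from_limits_is_zero(self):
        vals = np.random.default_rng(0).normal(50, 1, size=100)
        assert ooa_probability(vals, lsl=0.0, usl=100.0) == pytest.approx(
            0.0, abs=1e-8)

    def test_mean_at_upper_limit_gives_fifty(self):
        vals = np.array([9.0, 11.0, 10.0, 10.0])
        assert ooa_probability(vals, usl=10.0) == pytest.approx(50.0)

    def test_inflation_increases_ooa(self):
        vals = np.random.default_rng(1).normal(0, 1, size=5)
        mean, s = vals.mean(), vals.std(ddof=1)
        with_inflation = ooa_probability(vals, lsl=-3.0, usl=3.0)
        without = parametric_ooa(mean, s, lsl=-3.0, usl=3.0, n=None)
        assert with_inflation > without

    def test_infinite_limits_give_exactly_zero(self):
        vals = np.array([1.0, 2.0, 3.0])
        assert ooa_probability(vals, lsl=-np.inf, usl=np.inf) == 0.0

    def test_degenerate_sample_rule(self):
        vals = np.array([5.0, 5.0, 5.0])
        assert ooa_probability(vals, usl=4.0) == 100.0
        assert ooa_probability(vals, usl=6.0) == 0.0

    def test_needs_two_values(self):
        with pytest.raises(DataError):
            ooa_probability(np.array([1.0]), usl=2.0)

    def test_needs_a_limit(self):
        with pytest.raises(DataError):
            ooa_probability(np.array([1.0, 2.0]))

    def test_conservatism_inside_limits(self, rng):
        for _ in range(50):
            mean = rng.uniform(-1, 1)
            s = rng.uniform(0.5, 2)
            lsl, usl = mean - rng.uniform(1, 5), mean + rng.uniform(1, 5)
            n = int(rng.integers(3, 50))
            s_star = sd_upper_confidence_limit(s, n)
            assert parametric_ooa(mean, s_star, lsl, usl) >= \
                parametric_ooa(mean, s, lsl, usl)

    def test_parametric_matches_empirical_fraction(self):
        # pass-through chain, noise-free: DS is exactly normal
        rng = np.random.default_rng(42)
        n = 1_000_000
        vals = rng.normal(10.0, 1.0, size=n)
        lsl, usl = 8.0, 12.0
        emp = 100.0 * np.mean((vals <= lsl) | (vals >= usl))
        para = ooa_probability(vals, lsl=lsl, usl=usl)
        p = emp / 100
        se = 100.0 * np.sqrt(p * (1 - p) / n)
        assert abs(para - emp) < 3 * se + 0.05  # tiny slack for s* inflation


class TestRunIPM:
    def test_noise_free_collapse(self):
        chain = fixed_chain([0.5, 0.8], start_mean=10.0, start_sd=0.0)
        sim = run_ipm(chain, n=50, rng_seed=0)
        expected = propagate(chain, {}, {"imp1": 10.0}).ds["imp1"]
        assert np.allclose(sim.ds_values["imp1"], expected)
        assert sim.ds_values["imp1"].nunique() == 1

    def test_passthrough_ooa_near_closed_form(self):
        mu, sigma = 50.0, 2.0
        chain = passthrough_chain(n_uos=2, start_mean=mu, start_sd=sigma,
                                  lsl=mu - 2 * sigma, usl=mu + 2 * sigma)
        sim = run_ipm(chain, n=200_000, rng_seed=5)
        expected = 100.0 * 2 * stats.norm.sf(2.0)  # 4.55%
        assert sim.ooa["imp1"] == pytest.approx(expected, abs=0.35)

    def test_same_seed_bit_identical(self, doe_uo_chain):
        a = run_ipm(doe_uo_chain, n=500, rng_seed=11)
        b = run_ipm(doe_uo_chain, n=500, rng_seed=11)
        assert (a.ds_values.to_numpy() == b.ds_values.to_numpy()).all()
        assert a.ooa == b.ooa

    def test_ooa_bounds_and_shape(self, doe_uo_chain):
        sim = run_ipm(doe_uo_chain, n=200, rng_seed=1)
        assert sim.ds_values.shape == (200, 1)
        assert all(0.0 <= v <= 100.0 for v in sim.ooa.values())
        assert sim.pool_conc.shape == (200, 2, 1)

    def test_empty_chain_rejected(self):
        cqa = make_cqa()
        chain = ProcessChain(unit_operations=[], parameters=[], cqas=[cqa])
        with pytest.raises(ConfigurationError):
            run_ipm(chain, n=10)


class TestPlausibilityReport:
    def test_self_consistency(self, doe_uo_chain):
        sim = run_ipm(doe_uo_chain, n=20_000, rng_seed=3)
        obs = generate_manufacturing_runs(doe_uo_chain, n=2000, rng_seed=4)
        rep = plausibility_report(sim, obs)
        for _, row in rep.pool_stats.iterrows():
            assert row["sim_mean"] == pytest.approx(row["obs_mean"], rel=0.02)

    def test_observed_ooa_uses_small_n_inflation(self, doe_uo_chain):
        sim = run_ipm(doe_uo_chain, n=1000, rng_seed=3)
        obs = generate_manufacturing_runs(doe_uo_chain, n=5, rng_seed=4)
        rep = plausibility_report(sim, obs)
        row = rep.ooa_comparison.iloc[0]
        ds = obs[(obs["uo"] == "U2") & (obs["cqa"] == "imp1")]["conc"]
        cqa = doe_uo_chain.cqas[0]
        mean, s = ds.mean(), ds.std(ddof=1)
        s_star = sd_upper_confidence_limit(s, 5)
        expected = parametric_ooa(mean, s_star, cqa.lsl, cqa.usl)
        assert row["obs_ooa"] == pytest.approx(expected, rel=1e-9)
        assert row["n_obs"] == 5

    def test_empty_table_rejected(self, doe_uo_chain):
        sim = run_ipm(doe_uo_chain, n=100, rng_seed=0)
        with pytest.raises(ConfigurationError):
            plausibility_report(sim, pd.DataFrame())

    def test_unknown_cqa_rejected(self, doe_uo_chain):
        sim = run_ipm(doe_uo_chain, n=100, rng_seed=0)
        obs = pd.DataFrame({"run": [0], "uo": ["U2"], "cqa": ["ghost"],
                            "conc": [1.0]})
        with pytest.raises(ConfigurationError):
            plausibility_report(sim, obs)
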