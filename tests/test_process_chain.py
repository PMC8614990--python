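import numpy as np
import pytest

from ipm.errors import ConfigurationError, DomainError
from ipm.process_chain import (DoEModel, FixedClearance, ProcessChain,
                               ProcessParameter, QualityAttribute,
                               UnitOperation, predict_clearance, propagate)

from conftest import fixed_chain, make_cqa, make_param, passthrough_chain


class TestInvariants:
    def test_parameter_ordering_violation(self):
        with pytest.raises(ConfigurationError):
            ProcessParameter(name="p", uo="U", set_point=5.0,
                             nor_low=4.0, nor_high=6.0, sr_low=4.5, sr_high=7.0)

    def test_parameter_zero_screening_width(self):
        with pytest.raises(ConfigurationError):
            ProcessParameter(name="p", uo="U", set_point=5.0,
                             nor_low=5.0, nor_high=5.0, sr_low=5.0, sr_high=5.0)

    def test_cqa_needs_a_limit(self):
        with pytest.raises(ConfigurationError):
            QualityAttribute(name="c", kind="impurity", lsl=None, usl=None,
                             start_mean=1.0)

    def test_cqa_limit_order(self):
        with pytest.raises(ConfigurationError):
            QualityAttribute(name="c", kind="impurity", lsl=5.0, usl=2.0,
                             start_mean=1.0)

    def test_doe_model_needs_runs(self):
        with pytest.raises(ConfigurationError):
            DoEModel(uo="U", cqa="c", terms=("a",), beta=(1.0,), beta0=0.0,
                     rmse=0.1, n_runs=1, n_params=1)

    def test_chain_orders_contiguous(self):
        cqa = make_cqa()
        uos = [UnitOperation(name="A", order=1),
               UnitOperation(name="B", order=3)]
        with pytest.raises(ConfigurationError):
            ProcessChain(unit_operations=uos, parameters=[], cqas=[cqa])

    def test_doe_term_must_resolve(self):
        cqa = make_cqa()
        doe = DoEModel(uo="A", cqa="imp1", terms=("ghost",), beta=(1.0,),
                       beta0=0.0, rmse=0.1, n_runs=5, n_params=1)
        uos = [UnitOperation(name="A", order=1, models={"imp1": doe})]
        with pytest.raises(ConfigurationError):
            ProcessChain(unit_operations=uos, parameters=[], cqas=[cqa])

    def test_doe_term_wrong_uo(self):
        cqa = make_cqa()
        p = make_param("B_x", uo="B")
        doe = DoEModel(uo="A", cqa="imp1", terms=("B_x",), beta=(1.0,),
                       beta0=0.0, rmse=0.1, n_runs=5, n_params=1)
        uos = [UnitOperation(name="A", order=1, models={"imp1": doe}),
               UnitOperation(name="B", order=2)]
        with pytest.raises(ConfigurationError):
            ProcessChain(unit_operations=uos, parameters=[p], cqas=[cqa])


class TestPredictClearance:
    def test_both_model_identity_at_mean_slc(self, both_model_uo):
        # load correction is exactly 1 when slc equals the DoE mean
        settings = {"U1_a": 2.0}
        got = predict_clearance(both_model_uo, "imp1", settings, slc=4.0)
        doe_only = 0.5 + 0.1 * 2.0
        assert got == pytest.approx(doe_only, abs=1e-15)

    def test_intercept_only(self):
        doe = DoEModel(uo="U1", cqa="imp1", terms=("U1_a",), beta=(0.0,),
                       beta0=0.8, rmse=0.0, n_runs=6, n_params=1)
        uo = UnitOperation(name="U1", order=1, models={"imp1": doe})
        assert predict_clearance(uo, "imp1", {"U1_a": 123.0}) == 0.8

    def test_combined_hand_value(self, both_model_uo):
        # DoE 0.7, load(8)=0.8, load(4)=0.6 -> 0.7 * 0.8/0.6
        got = predict_clearance(both_model_uo, "imp1", {"U1_a": 2.0}, slc=8.0)
        assert got == pytest.approx(0.7 * (0.8 / 0.6), rel=1e-12)

    def test_absent_model_is_passthrough(self):
        uo = UnitOperation(name="U1", order=1, models={})
        assert predict_clearance(uo, "imp1", {}) == 1.0

    def test_fixed_model(self):
        uo = UnitOperation(name="U1", order=1, models={
            "imp1": FixedClearance(uo="U1", cqa="imp1", sc_mean=0.42,
                                   sc_sd=0.01)})
        assert predict_clearance(uo, "imp1", {}) == 0.42

    def test_missing_setting_names_term(self):
        doe = DoEModel(uo="U1", cqa="imp1", terms=("U1_a",), beta=(0.1,),
                       beta0=0.5, rmse=0.0, n_runs=6, n_params=1)
        uo = UnitOperation(name="U1", order=1, models={"imp1": doe})
        with pytest.raises(ConfigurationError, match="U1_a"):
            predict_clearance(uo, "imp1", {})

    def test_nonpositive_slc_rejected(self, both_model_uo):
        with pytest.raises(DomainError):
            predict_clearance(both_model_uo, "imp1", {"U1_a": 2.0}, slc=0.0)
        with pytest.raises(DomainError):
            predict_clearance(both_model_uo, "imp1", {"U1_a": 2.0}, slc=None)

    def test_interaction_and_quadratic_terms(self):
        doe = DoEModel(uo="U1", cqa="imp1", terms=("U1_a", "U1_a*U1_b",
                                                   "U1_b*U1_b"),
                       beta=(0.1, 0.02, -0.01), beta0=0.3, rmse=0.0,
                       n_runs=10, n_params=3)
        uo = UnitOperation(name="U1", order=1, models={"imp1": doe})
        got = predict_clearance(uo, "imp1", {"U1_a": 2.0, "U1_b": 3.0})
        assert got == pytest.approx(0.3 + 0.2 + 0.02 * 6 - 0.01 * 9, rel=1e-12)


class TestPropagate:
    def test_single_uo(self):
        chain = fixed_chain([0.5], start_mean=10.0)
        res = propagate(chain, {}, {"imp1": 10.0})
        assert res.ds["imp1"] == pytest.approx(5.0)

    def test_identity_chain(self):
        chain = passthrough_chain(n_uos=4)
        res = propagate(chain, {}, {"imp1": 10.0})
        assert res.ds["imp1"] == 10.0
        assert (res.pools["imp1"] == 10.0).all()

    def test_three_uo_product(self):
        chain = fixed_chain([0.5, 0.4, 0.9], start_mean=100.0)
        res = propagate(chain, {}, {"imp1": 100.0})
        assert res.ds["imp1"] == pytest.approx(18.0)

    def test_deterministic_equals_clearance_product(self, rng):
        scs = rng.uniform(0.2, 1.1, size=5)
        chain = fixed_chain(list(scs), start_mean=7.0)
        res = propagate(chain, {}, {"imp1": 7.0})
        assert res.ds["imp1"] == pytest.approx(7.0 * np.prod(scs), rel=1e-12)

    def test_noise_draws_applied_per_cell(self):
        chain = fixed_chain([0.5, 0.5], start_mean=10.0)
        res = propagate(chain, {}, {"imp1": 10.0},
                        noise_draws={("U1", "imp1"): 0.1,
                                     ("U2", "imp1"): -0.1})
        assert res.ds["imp1"] == pytest.approx(10.0 * 0.6 * 0.4)

    def test_negative_factor_clamped_and_flagged(self):
        chain = fixed_chain([0.5], start_mean=10.0)
        res = propagate(chain, {}, {"imp1": 10.0},
                        noise_draws={("U1", "imp1"): -0.9})
        assert res.ds["imp1"] == 0.0
        assert res.clamp_count == 1

    def test_empty_chain_rejected(self):
        cqa = make_cqa()
        chain = ProcessChain(unit_operations=[], parameters=[], cqas=[cqa])
        with pytest.raises(ConfigurationError):
            propagate(chain, {}, {"imp1": 10.0})

    def test_nonpositive_start_rejected(self):
        chain = passthrough_chain()
        with pytest.raises(DomainError):
            propagate(chain, {}, {"imp1": 0.0})

    def test_slc_linkage_uses_previous_pool(self, both_model_uo):
        # chain: fixed 0.5 then a both-model UO; its SLC must be 10*0.5
        from ipm.process_chain import LoadModel
        p = make_param("U2_a", "U2", sp=2.0, nor_half=0.1, sr_half=1.0)
        doe = DoEModel(uo="U2", cqa="imp1", terms=("U2_a",), beta=(0.1,),
                       beta0=0.5, rmse=0.0, n_runs=6, n_params=1)
        load = LoadModel(uo="U2", cqa="imp1", beta_slc=0.05, beta0=0.4,
                         rmse=0.0, mean_slc_doe=4.0)
        cqa = make_cqa(usl=100.0)
        uos = [UnitOperation(name="U1", order=1,
                             models={"imp1": FixedClearance(
                                 uo="U1", cqa="imp1", sc_mean=0.5,
                                 sc_sd=0.0)}),
               UnitOperation(name="U2", order=2, models={"imp1": (doe, load)})]
        chain = ProcessChain(unit_operations=uos, parameters=[p], cqas=[cqa])
        res = propagate(chain, {"U2_a": 2.0}, {"imp1": 10.0})
        slc = 5.0
        expected_sc = 0.7 * ((0.4 + 0.05 * slc) / 0.6)
        assert res.ds["imp1"] == pytest.approx(5.0 * expected_sc, rel=1e-12)

    def test_parameter_storage_order_irrelevant(self, doe_uo_chain):
        settings = {"U1_a": 4.2, "U1_b": 5.9}
        res1 = propagate(doe_uo_chain, settings, {"imp1": 10.0})
        flipped = ProcessChain(
            unit_operations=doe_uo_chain.unit_operations,
            parameters=list(reversed(doe_uo_chain.parameters)),
            cqas=doe_uo_chain.cqas)
        res2 = propagate(flipped, settings, {"imp1": 10.0})
        assert res1.ds == res2.ds
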