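import numpy as np
import pandas as pd
import pytest

from ipm.process_chain import (DoEModel, FixedClearance, LoadModel,
                               ProcessChain, ProcessParameter,
                               QualityAttribute, UnitOperation)
from ipm.psa import PSACurve


def make_param(name="p1", uo="U1", sp=5.0, nor_half=0.5, sr_half=2.0):
    return ProcessParameter(name=name, uo=uo, set_point=sp,
                            nor_low=sp - nor_half, nor_high=sp + nor_half,
                            sr_low=sp - sr_half, sr_high=sp + sr_half)


def make_cqa(name="imp1", kind="impurity", lsl=None, usl=100.0,
             start_mean=10.0, start_sd=0.0):
    return QualityAttribute(name=name, kind=kind, lsl=lsl, usl=usl,
                            start_mean=start_mean, start_sd=start_sd)


def fixed_chain(clearances, usl=100.0, start_mean=10.0, start_sd=0.0,
                sc_sd=0.0):
    """Chain of UOs with fixed clearances for a single impurity CQA."""
    cqa = make_cqa(usl=usl, start_mean=start_mean, start_sd=start_sd)
    uos = [UnitOperation(name=f"U{k + 1}", order=k + 1,
                         models={"imp1": FixedClearance(
                             uo=f"U{k + 1}", cqa="imp1", sc_mean=sc,
                             sc_sd=sc_sd)})
           for k, sc in enumerate(clearances)]
    return ProcessChain(unit_operations=uos, parameters=[], cqas=[cqa])


def passthrough_chain(n_uos=3, usl=100.0, lsl=None, start_mean=10.0,
                      start_sd=0.0):
    cqa = make_cqa(usl=usl, lsl=lsl, start_mean=start_mean, start_sd=start_sd)
    uos = [UnitOperation(name=f"U{k + 1}", order=k + 1, models={})
           for k in range(n_uos)]
    return ProcessChain(unit_operations=uos, parameters=[], cqas=[cqa])


def make_curve(ooa_by_cqa, sp_ooa, sp=5.0, sr_low=3.0, sr_high=7.0,
               grid=None, n_per_point=1000, seed=0):
    """Hand-built PSA curve: ooa_by_cqa maps cqa -> per-grid-point %OOA."""
    p = ProcessParameter(name="p", uo="U1", set_point=sp,
                         nor_low=sp, nor_high=sp,
                         sr_low=sr_low, sr_high=sr_high)
    any_vals = next(iter(ooa_by_cqa.values()))
    if grid is None:
        grid = np.linspace(sr_low, sr_high, len(any_vals))
    ooa = pd.DataFrame({c: np.asarray(v, float)
                        for c, v in ooa_by_cqa.items()}, index=grid)
    return PSACurve(parameter="p", param=p, grid=np.asarray(grid, float),
                    ooa=ooa, set_point_ooa=dict(sp_ooa),
                    n_per_point=n_per_point, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def doe_uo_chain():
    """One DoE-modelled UO with two parameters plus a pass-through UO."""
    p1 = make_param("U1_a", "U1", sp=4.0, nor_half=0.2, sr_half=1.0)
    p2 = make_param("U1_b", "U1", sp=6.0, nor_half=0.3, sr_half=1.5)
    doe = DoEModel(uo="U1", cqa="imp1", terms=("U1_a", "U1_b"),
                   beta=(0.05, -0.02), beta0=0.5, rmse=0.01,
                   n_runs=8, n_params=2)
    cqa = make_cqa(usl=8.0, start_mean=10.0, start_sd=0.3)
    uos = [UnitOperation(name="U1", order=1, models={"imp1": doe}),
           UnitOperation(name="U2", order=2, models={})]
    return ProcessChain(unit_operations=uos, parameters=[p1, p2], cqas=[cqa])


@pytest.fixture
def both_model_uo():
    doe = DoEModel(uo="U1", cqa="imp1", terms=("U1_a",), beta=(0.1,),
                   beta0=0.5, rmse=0.0, n_runs=6, n_params=1)
    load = LoadModel(uo="U1", cqa="imp1", beta_slc=0.05, beta0=0.4,
                     rmse=0.0, mean_slc_doe=4.0)
    return UnitOperation(name="U1", order=1, models={"imp1": (doe, load)})
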