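"""OLS fitting of DoE and load models with AIC selection and diagnostics.

The selection procedure fits every candidate term set by ordinary least
squares and keeps the one with the lowest AIC.  Diagnostics reported per
fitted model: adjusted R², Q² (leave-one-out PRESS via the hat matrix),
residual standard error (n − p − 1 denominator), two-sided partial t-test
p-values per coefficient, AIC and raw residuals.

CSV header convention for DoE datasets: parameter columns carry their
chain-wide names (conventionally prefixed by the UO name, e.g. ``AT_pH``);
measured specific clearance columns are ``SC_<cqa>`` and specific load
concentration columns are ``SLC_<cqa>``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, EstimationError
from .process_chain import (DoEModel, FixedClearance, LoadModel, ProcessChain,
                            UnitOperation, _term_factors)

__all__ = [
    "DoEDataset",
    "ModelDiagnostics",
    "fit_doe_model",
    "fit_load_model",
    "fit_process_chain",
    "load_table_from_runs",
]


@dataclass
class DoEDataset:
    """One UO's experimental runs: parameter settings, SLC and SC columns."""

    uo: str
    runs: pd.DataFrame

    def parameter_columns(self) -> list[str]:
        return [c for c in self.runs.columns
                if not (c.startswith("SC_") or c.startswith("SLC_")
                        or c == "run")]


@dataclass
class ModelDiagnostics:
    r2_adj: float
    q2: float
    rmse: float
    partial_p: dict[str, float]
    aic: float
    residuals: np.ndarray = field(repr=False, default=None)


def _design_matrix(runs: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = []
    for term in terms:
        x = np.ones(len(runs))
        for factor in _term_factors(term):
            if factor not in runs.columns:
                raise DataError(f"dataset has no column for term factor {factor!r}")
            x = x * runs[factor].to_numpy(float)
        cols.append(x)
    X = np.column_stack(cols) if cols else np.empty((len(runs), 0))
    return sm.add_constant(X, has_constant="add")


def _press_q2(res, y: np.ndarray) -> float:
    """Q² = 1 − PRESS/SS_total with PRESS from the hat-matrix identity."""
    h = res.get_influence().hat_matrix_diag
    e = res.resid
    with np.errstate(divide="ignore", invalid="ignore"):
        press = float(np.sum((e / (1.0 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return -np.inf
    return 1.0 - press / ss_tot


def _fit_ols(runs: pd.DataFrame, y: np.ndarray, terms: tuple[str, ...]):
    X = _design_matrix(runs, terms)
    n, p1 = X.shape
    if n < p1 + 1:
        raise DataError(
            f"{n} runs are too few to fit {p1 - 1} terms (need >= {p1 + 1})")
    if np.linalg.matrix_rank(X) < p1:
        raise EstimationError(
            f"design matrix is rank deficient for terms {list(terms)}")
    return sm.OLS(y, X).fit()


def _diagnostics(res, y: np.ndarray, terms: tuple[str, ...]) -> ModelDiagnostics:
    partial = {t: float(p) for t, p in zip(terms, res.pvalues[1:])}
    return ModelDiagnostics(
        r2_adj=float(res.rsquared_adj),
        q2=_press_q2(res, y),
        rmse=float(np.sqrt(res.mse_resid)),
        partial_p=partial,
        aic=float(res.aic),
        residuals=np.asarray(res.resid),
    )


def default_candidates(main_effects: list[str],
                       max_terms: int | None = None,
                       interactions: list[str] | None = None,
                       ) -> list[tuple[str, ...]]:
    """All subsets of the main effects (up to ``max_terms``) plus, for each,
    the declared interaction terms whose factors are all present."""
    if max_terms is None:
        max_terms = len(main_effects)
    cands: list[tuple[str, ...]] = []
    for k in range(0, max_terms + 1):
        for combo in itertools.combinations(main_effects, k):
            cands.append(combo)
            for inter in interactions or []:
                if all(f in combo for f in _term_factors(inter)):
                    cands.append(combo + (inter,))
    return cands


def fit_doe_model(data: DoEDataset, cqa: str,
                  candidate_terms: list[tuple[str, ...]] | None = None,
                  max_terms: int | None = None,
                  ) -> tuple[DoEModel, ModelDiagnostics]:
    """Fit all candidate term sets by OLS and return the AIC-minimal one."""
    ycol = f"SC_{cqa}"
    if ycol not in data.runs.columns:
        raise DataError(f"dataset for {data.uo} has no response column {ycol!r}")
    if candidate_terms is None:
        candidate_terms = default_candidates(data.parameter_columns(), max_terms)
    if not candidate_terms:
        raise DataError("no candidate term sets supplied")

    y = data.runs[ycol].to_numpy(float)
    if np.isnan(y).any():
        raise DataError(f"missing values in response column {ycol!r}")

    # numerically perfect fits make the AIC comparison degenerate; rank them
    # as -inf and break ties by parsimony
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    best = None
    for terms in candidate_terms:
        terms = tuple(terms)
        res = _fit_ols(data.runs, y, terms)
        aic = float(res.aic)
        if res.ssr <= max(1e-12 * ss_tot, 1e-24):
            aic = -np.inf
        key = (aic, len(terms))
        if best is None or key < best[0]:
            best = (key, terms, res)
    _, terms, res = best
    model = DoEModel(
        uo=data.uo, cqa=cqa, terms=terms,
        beta=tuple(res.params[1:]), beta0=float(res.params[0]),
        rmse=float(np.sqrt(res.mse_resid)),
        n_runs=int(res.nobs), n_params=max(len(terms), 1),
    )
    return model, _diagnostics(res, y, terms)


def fit_load_model(data: DoEDataset | pd.DataFrame, cqa: str,
                   ) -> tuple[LoadModel, ModelDiagnostics]:
    """Single-predictor OLS of specific clearance on specific load concentration."""
    runs = data.runs if isinstance(data, DoEDataset) else data
    uo = data.uo if isinstance(data, DoEDataset) else str(runs.attrs.get("uo", ""))
    xcol, ycol = f"SLC_{cqa}", f"SC_{cqa}"
    for col in (xcol, ycol):
        if col not in runs.columns:
            raise DataError(f"load-model table has no column {col!r}")
    slc = runs[xcol].to_numpy(float)
    y = runs[ycol].to_numpy(float)
    if len(runs) < 3 or len(np.unique(slc)) < 3:
        raise DataError(
            "load model needs >= 3 rows with >= 3 distinct SLC values")
    X = sm.add_constant(slc)
    res = sm.OLS(y, X).fit()
    model = LoadModel(
        uo=uo, cqa=cqa,
        beta_slc=float(res.params[1]), beta0=float(res.params[0]),
        rmse=float(np.sqrt(res.mse_resid)),
        mean_slc_doe=float(slc.mean()),
    )
    return model, _diagnostics(res, y, ("SLC",))


def load_table_from_runs(runs: pd.DataFrame, chain: ProcessChain,
                         uo: str) -> pd.DataFrame:
    """Build a load-model table (SLC/SC per CQA) for one UO from a long-format
    manufacturing-run table (columns run, uo, cqa, conc; the starting
    concentration rows carry ``uo == "_start"``)."""
    order = ["_start"] + chain.uo_names()
    k = order.index(uo)
    prev = order[k - 1]
    out: dict[str, list[float]] = {}
    run_ids = sorted(runs["run"].unique())
    for cqa in chain.cqa_names:
        slc_vals, sc_vals = [], []
        for rid in run_ids:
            sub = runs[runs["run"] == rid].set_index(["uo", "cqa"])["conc"]
            load = float(sub.loc[(prev, cqa)])
            pool = float(sub.loc[(uo, cqa)])
            slc_vals.append(load)
            sc_vals.append(pool / load if load > 0 else np.nan)
        out[f"SLC_{cqa}"] = slc_vals
        out[f"SC_{cqa}"] = sc_vals
    table = pd.DataFrame(out)
    table.attrs["uo"] = uo
    return table


def fit_process_chain(structure: ProcessChain,
                      doe_data: dict[str, DoEDataset],
                      mfg_runs: pd.DataFrame | None = None,
                      max_terms: int | None = None,
                      ) -> tuple[ProcessChain, dict[tuple[str, str], ModelDiagnostics]]:
    """Refit every modelled cell of ``structure`` from data.

    The model kinds of ``structure`` define which cells are DoE / load /
    both / fixed; its parameter and CQA catalogues are reused.  DoE cells are
    fitted from ``doe_data[uo]``, load and fixed cells from the long-format
    manufacturing-run table.
    """
    diags: dict[tuple[str, str], ModelDiagnostics] = {}
    new_uos = []
    for uo in structure.ordered_uos():
        models = {}
        for cqa_name in structure.cqa_names:
            kind = uo.model_kind(cqa_name)
            if kind == "none":
                continue
            if kind in ("doe", "both"):
                if uo.name not in doe_data:
                    raise DataError(f"no DoE dataset supplied for UO {uo.name!r}")
                doe_m, d = fit_doe_model(doe_data[uo.name], cqa_name,
                                         max_terms=max_terms)
                diags[(uo.name, cqa_name)] = d
            if kind in ("load", "both"):
                if mfg_runs is None:
                    raise DataError(
                        f"load model at {uo.name}/{cqa_name} needs manufacturing runs")
                table = load_table_from_runs(mfg_runs, structure, uo.name)
                load_m, d2 = fit_load_model(table, cqa_name)
                diags.setdefault((uo.name, cqa_name), d2)
            if kind == "doe":
                models[cqa_name] = doe_m
            elif kind == "load":
                models[cqa_name] = load_m
            elif kind == "both":
                models[cqa_name] = (doe_m, load_m)
            elif kind == "fixed":
                if mfg_runs is None:
                    raise DataError(
                        f"fixed clearance at {uo.name}/{cqa_name} needs "
                        f"manufacturing runs")
                table = load_table_from_runs(mfg_runs, structure, uo.name)
                sc = table[f"SC_{cqa_name}"].to_numpy(float)
                if len(sc) < 2:
                    raise DataError(
                        f"fixed clearance at {uo.name}/{cqa_name} needs >= 2 runs")
                models[cqa_name] = FixedClearance(
                    uo=uo.name, cqa=cqa_name,
                    sc_mean=float(sc.mean()), sc_sd=float(sc.std(ddof=1)))
        new_uos.append(UnitOperation(name=uo.name, order=uo.order, models=models))
    fitted = ProcessChain(unit_operations=new_uos,
                          parameters=list(structure.parameters),
                          cqas=list(structure.cqas))
    return fitted, diags
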