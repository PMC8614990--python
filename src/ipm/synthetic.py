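"""Synthetic process chains with known ground truth.

Generates in-silico processes — by default 8 downstream unit operations and
4 CQAs (three impurities, one product attribute) with a per-cell
model-availability pattern covering every model kind (DoE-only, load-only,
both, fixed, absent) — together with simulated DoE datasets and set-point
manufacturing runs, so the full fit → simulate → PSA → FMEA → PAR pipeline
can be exercised and checked against the generating coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .process_chain import (DoEModel, FixedClearance, LoadModel, ProcessChain,
                            ProcessParameter, QualityAttribute, UnitOperation,
                            propagate)
from .regression import DoEDataset
from .simulation import sample_parameters

__all__ = ["SyntheticSpec", "GroundTruth", "make_chain",
           "generate_doe_data", "generate_manufacturing_runs",
           "DEFAULT_AVAILABILITY"]

_UO_NAMES = ("CAP", "AT", "DF", "AEX", "CEX", "VF", "UFDF", "DS")
_CQA_KINDS = {"imp1": "impurity", "imp2": "impurity",
              "imp3": "impurity", "prod1": "product"}

# default UO×CQA availability: mirrors a typical mAb downstream pattern with
# DoE models on the chromatography/treatment steps, load models on
# filtration steps, set-point-only estimates at drug substance and several
# untouched (pass-through) cells
DEFAULT_AVAILABILITY: dict[str, dict[str, str]] = {
    "CAP": {"imp1": "doe", "imp2": "doe", "prod1": "doe"},
    "AT": {"imp1": "both", "imp2": "doe", "imp3": "doe", "prod1": "doe"},
    "DF": {"imp3": "load"},
    "AEX": {"imp1": "doe", "imp2": "both", "imp3": "both", "prod1": "doe"},
    "CEX": {"imp1": "both", "imp2": "doe", "imp3": "doe", "prod1": "doe"},
    "VF": {},
    "UFDF": {"imp1": "load", "imp2": "load"},
    "DS": {"imp1": "fixed", "imp2": "fixed", "imp3": "fixed", "prod1": "fixed"},
}


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic process generator."""

    uo_names: tuple[str, ...] = _UO_NAMES
    cqa_kinds: dict[str, str] = field(default_factory=lambda: dict(_CQA_KINDS))
    availability: dict[str, dict[str, str]] = field(
        default_factory=lambda: {u: dict(c) for u, c in
                                 DEFAULT_AVAILABILITY.items()})
    params_per_doe_uo: int = 2
    sc_impurity: tuple[float, float] = (0.35, 0.75)
    sc_product: tuple[float, float] = (0.90, 0.99)
    effect_scale: float = 0.12    # max |effect| across a half screening range,
                                  # relative to the set-point clearance
    load_effect_scale: float = 0.05
    rmse_rel: tuple[float, float] = (0.005, 0.02)  # RMSE relative to clearance
    sr_rel_halfwidth: tuple[float, float] = (0.2, 0.4)  # vs. set point
    nor_rel_halfwidth: float = 0.15  # NOR half-width as fraction of SR half
    start_mean_impurity: tuple[float, float] = (50.0, 200.0)
    start_mean_product: tuple[float, float] = (80.0, 120.0)
    start_cv: float = 0.03
    limit_z: float = 2.5  # acceptance limit distance in predicted DS SDs
    rng_seed: int = 0

    @property
    def n_uos(self) -> int:
        return len(self.uo_names)

    @property
    def n_cqas(self) -> int:
        return len(self.cqa_kinds)

    def validate(self) -> None:
        for uo in self.availability:
            if uo not in self.uo_names:
                raise ConfigurationError(f"availability names unknown UO {uo!r}")
            for cqa, kind in self.availability[uo].items():
                if cqa not in self.cqa_kinds:
                    raise ConfigurationError(
                        f"availability names unknown CQA {cqa!r}")
                if kind not in ("doe", "load", "both", "fixed", "none"):
                    raise ConfigurationError(f"unknown model kind {kind!r}")
        for cqa in self.cqa_kinds:
            kinds = [self.availability.get(u, {}).get(cqa, "none")
                     for u in self.uo_names]
            if all(k == "none" for k in kinds):
                raise ConfigurationError(
                    f"CQA {cqa!r} is unmodelled at every unit operation")


@dataclass
class GroundTruth:
    """What the generator knows that the fitting pipeline must recover."""

    chain: ProcessChain              # carries the true coefficients and RMSEs
    ds_mean: dict[str, float]        # deterministic DS concentration at set point
    ds_rel_sd: dict[str, float]      # first-order relative SD of DS at set point
    spec: SyntheticSpec


def _uniform(rng, lo_hi):
    return float(rng.uniform(lo_hi[0], lo_hi[1]))


def make_chain(spec: SyntheticSpec | None = None,
               ) -> tuple[ProcessChain, GroundTruth]:
    """Generate a process chain with known coefficients, reproducibly."""
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    doe_uos = [u for u in spec.uo_names
               if any(k in ("doe", "both")
                      for k in spec.availability.get(u, {}).values())]
    parameters: list[ProcessParameter] = []
    by_uo: dict[str, list[ProcessParameter]] = {}
    for uo in doe_uos:
        plist = []
        for i in range(spec.params_per_doe_uo):
            sp = float(rng.uniform(2.0, 8.0))
            sr_half = _uniform(rng, spec.sr_rel_halfwidth) * sp
            nor_half = spec.nor_rel_halfwidth * sr_half
            plist.append(ProcessParameter(
                name=f"{uo}_p{i + 1}", uo=uo, set_point=sp,
                nor_low=sp - nor_half, nor_high=sp + nor_half,
                sr_low=sp - sr_half, sr_high=sp + sr_half))
        by_uo[uo] = plist
        parameters.extend(plist)

    cqas: list[QualityAttribute] = []
    start_mean: dict[str, float] = {}
    for name, kind in spec.cqa_kinds.items():
        rng_range = (spec.start_mean_impurity if kind == "impurity"
                     else spec.start_mean_product)
        mean = _uniform(rng, rng_range)
        start_mean[name] = mean
        # limits are attached after the clearances are known
        cqas.append((name, kind, mean))

    conc = dict(start_mean)  # running set-point concentration per CQA
    rel_var = {name: spec.start_cv ** 2 for name in start_mean}
    uos: list[UnitOperation] = []
    for order, uo_name in enumerate(spec.uo_names, start=1):
        models = {}
        for cqa_name, kind_cqa in spec.cqa_kinds.items():
            kind = spec.availability.get(uo_name, {}).get(cqa_name, "none")
            if kind == "none":
                continue
            sc_sp = _uniform(rng, spec.sc_impurity if kind_cqa == "impurity"
                             else spec.sc_product)
            rmse = _uniform(rng, spec.rmse_rel) * sc_sp
            doe_m = load_m = None
            if kind in ("doe", "both"):
                terms, beta = [], []
                for p in by_uo[uo_name]:
                    sr_half = (p.sr_high - p.sr_low) / 2.0
                    eff = float(rng.uniform(-1.0, 1.0)) * spec.effect_scale * sc_sp
                    terms.append(p.name)
                    beta.append(eff / sr_half)
                    rel_var[cqa_name] += (beta[-1] * p.nor_sd / sc_sp) ** 2
                beta0 = sc_sp - float(np.dot(
                    beta, [p.set_point for p in by_uo[uo_name]]))
                doe_m = DoEModel(uo=uo_name, cqa=cqa_name, terms=tuple(terms),
                                 beta=tuple(beta), beta0=beta0, rmse=rmse,
                                 n_runs=2 ** len(terms) + 2,
                                 n_params=len(terms))
            if kind in ("load", "both"):
                mean_slc = conc[cqa_name]
                rel = float(rng.uniform(-1.0, 1.0)) * spec.load_effect_scale
                beta_slc = rel * sc_sp / mean_slc
                load_m = LoadModel(uo=uo_name, cqa=cqa_name,
                                   beta_slc=beta_slc,
                                   beta0=sc_sp - beta_slc * mean_slc,
                                   rmse=rmse, mean_slc_doe=mean_slc)
            if kind == "doe":
                models[cqa_name] = doe_m
            elif kind == "load":
                models[cqa_name] = load_m
            elif kind == "both":
                models[cqa_name] = (doe_m, load_m)
            else:  # fixed
                models[cqa_name] = FixedClearance(
                    uo=uo_name, cqa=cqa_name, sc_mean=sc_sp, sc_sd=rmse)
            rel_var[cqa_name] += (rmse / sc_sp) ** 2
            conc[cqa_name] = conc[cqa_name] * sc_sp
        uos.append(UnitOperation(name=uo_name, order=order, models=models))

    final_cqas = []
    for name, kind, mean in cqas:
        ds = conc[name]
        rel_sd = float(np.sqrt(rel_var[name]))
        # floor keeps limits strictly away from the mean for noise-free specs
        margin = max(spec.limit_z * rel_sd, 1e-6)
        if kind == "impurity":
            lsl, usl = None, ds * (1.0 + margin)
        else:
            lsl, usl = ds * (1.0 - margin), ds * (1.0 + margin)
        final_cqas.append(QualityAttribute(
            name=name, kind=kind, lsl=lsl, usl=usl,
            start_mean=mean, start_sd=spec.start_cv * mean))

    chain = ProcessChain(unit_operations=uos, parameters=parameters,
                         cqas=final_cqas)
    truth = GroundTruth(chain=chain, ds_mean=dict(conc),
                        ds_rel_sd={k: float(np.sqrt(v))
                                   for k, v in rel_var.items()},
                        spec=spec)
    return chain, truth


def _setpoint_slc(chain: ProcessChain) -> pd.DataFrame:
    """Deterministic incoming concentration per UO×CQA at set point."""
    settings = {p.name: p.set_point for p in chain.parameters}
    starts = {c.name: c.start_mean for c in chain.cqas}
    res = propagate(chain, settings, starts)
    incoming = res.pools.shift(1)
    incoming.iloc[0] = pd.Series(starts)
    return incoming


def generate_doe_data(chain: ProcessChain, replicates: int = 1,
                      center_points: int = 2, noise_scale: float = 1.0,
                      rng_seed: int = 0) -> dict[str, DoEDataset]:
    """Two-level full-factorial DoE datasets (plus centre points) per UO.

    Factor levels are the screening-range bounds; responses are the true
    model predictions plus N(0, rmse·noise_scale) noise; SLC columns hold the
    deterministic upstream set-point concentration.
    """
    if replicates < 1:
        raise DataError("replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    slc = _setpoint_slc(chain)
    out: dict[str, DoEDataset] = {}
    for uo in chain.ordered_uos():
        params = [p for p in chain.parameters if p.uo == uo.name]
        cell_kinds = {c: uo.model_kind(c) for c in chain.cqa_names}
        if not any(k in ("doe", "both") for k in cell_kinds.values()):
            continue
        if not params:
            raise DataError(f"UO {uo.name!r} has DoE models but no parameters")
        levels = [(p.sr_low, p.sr_high) for p in params]
        rows = list(itertools.product(*levels)) * replicates
        rows += [tuple(p.set_point for p in params)] * center_points
        if len(rows) < len(params) + 2:
            raise DataError(
                f"design for {uo.name!r} has {len(rows)} runs for "
                f"{len(params)} parameters (need >= {len(params) + 2})")
        df = pd.DataFrame(rows, columns=[p.name for p in params])
        settings = {p.name: df[p.name].to_numpy() for p in params}
        for cqa in chain.cqa_names:
            kind = cell_kinds[cqa]
            if kind not in ("doe", "both"):
                continue
            spec = uo.models[cqa]
            doe_m = spec[0] if isinstance(spec, tuple) else spec
            slc_val = float(slc.loc[uo.name, cqa])
            pred = np.asarray(doe_m.predict(settings), float)
            if isinstance(spec, tuple):
                load_m = spec[1]
                pred = pred * (load_m.predict(slc_val)
                               / load_m.predict(load_m.mean_slc_doe))
            noise = rng.normal(0.0, doe_m.rmse * noise_scale, size=len(df))
            df[f"SLC_{cqa}"] = slc_val
            df[f"SC_{cqa}"] = pred + noise
        out[uo.name] = DoEDataset(uo=uo.name, runs=df)
    return out


def generate_manufacturing_runs(chain: ProcessChain, n: int = 5,
                                rng_seed: int = 0, noise_scale: float = 1.0,
                                ) -> pd.DataFrame:
    """Full stochastic set-point runs, long format (run, uo, cqa, conc).

    Starting concentrations are included as rows with ``uo == "_start"`` so
    load models can be fitted against the true incoming concentration.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    uos = chain.ordered_uos()
    rows = []
    for run in range(n):
        settings = sample_parameters(chain, 1, rng_seed=rng).iloc[0].to_dict()
        starts = {c.name: float(rng.normal(c.start_mean, c.start_sd))
                  if c.start_sd > 0 else c.start_mean for c in chain.cqas}
        noise = {}
        for uo in uos:
            for c in chain.cqas:
                sd = uo.noise_sd(c.name)
                if sd > 0:
                    noise[(uo.name, c.name)] = float(
                        rng.normal(0.0, sd * noise_scale))
        res = propagate(chain, settings, starts, noise)
        for c in chain.cqas:
            rows.append({"run": run, "uo": "_start", "cqa": c.name,
                         "conc": starts[c.name]})
        for uo in uos:
            for c in chain.cqas:
                rows.append({"run": run, "uo": uo.name, "cqa": c.name,
                             "conc": float(res.pools.loc[uo.name, c.name])})
    return pd.DataFrame(rows)
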