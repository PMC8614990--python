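"""Process-chain data model and deterministic clearance propagation.

A process chain is an ordered list of unit operations (UOs).  Each UO may
carry, per critical quality attribute (CQA), a clearance model of one of
four kinds:

* a multifactorial *DoE model* — specific clearance as a linear function of
  the UO's process-parameter settings,
* a unifactorial *load model* — specific clearance as a linear function of
  the specific load concentration (SLC) entering the UO,
* *both* — the DoE prediction multiplicatively corrected by the load model's
  relative response at the current SLC,
* a *fixed* clearance estimated from set-point manufacturing runs.

A UO×CQA cell with no model is pass-through (clearance exactly 1, no noise).
Specific clearance is dimensionless and multiplicative: the pool specific
concentration leaving a UO is the incoming concentration times the
clearance, and the pool of UO k feeds UO k+1 until drug substance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, SimulationError

__all__ = [
    "ProcessParameter",
    "QualityAttribute",
    "DoEModel",
    "LoadModel",
    "FixedClearance",
    "UnitOperation",
    "ProcessChain",
    "PropagationResult",
    "predict_clearance",
    "propagate",
]


@dataclass(frozen=True)
class ProcessParameter:
    """A process parameter with set point, NOR and screening range (native units)."""

    name: str
    uo: str
    set_point: float
    nor_low: float
    nor_high: float
    sr_low: float
    sr_high: float

    def __post_init__(self) -> None:
        if not (self.sr_low <= self.nor_low <= self.set_point
                <= self.nor_high <= self.sr_high):
            raise ConfigurationError(
                f"parameter {self.name!r}: require "
                f"sr_low <= nor_low <= set_point <= nor_high <= sr_high, got "
                f"{self.sr_low}, {self.nor_low}, {self.set_point}, "
                f"{self.nor_high}, {self.sr_high}")
        if not self.sr_low < self.sr_high:
            raise ConfigurationError(
                f"parameter {self.name!r}: screening range has zero width")

    @property
    def nor_sd(self) -> float:
        """Sampling SD implied by NOR = mean ± 3 SD."""
        return (self.nor_high - self.nor_low) / 6.0


@dataclass(frozen=True)
class QualityAttribute:
    """A CQA with drug-substance acceptance limits and a starting distribution."""

    name: str
    kind: str  # "impurity" or "product"
    lsl: float | None = None
    usl: float | None = None
    start_mean: float = 1.0
    start_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("impurity", "product"):
            raise ConfigurationError(
                f"CQA {self.name!r}: kind must be 'impurity' or 'product'")
        lsl_ok = self.lsl is not None and math.isfinite(self.lsl)
        usl_ok = self.usl is not None and math.isfinite(self.usl)
        if not (lsl_ok or usl_ok):
            raise ConfigurationError(
                f"CQA {self.name!r}: at least one finite acceptance limit required")
        if lsl_ok and usl_ok and not self.lsl < self.usl:
            raise ConfigurationError(f"CQA {self.name!r}: lsl must be < usl")
        if self.start_sd < 0:
            raise ConfigurationError(f"CQA {self.name!r}: start_sd must be >= 0")
        if self.start_mean <= 0:
            raise ConfigurationError(f"CQA {self.name!r}: start_mean must be > 0")


def _term_factors(term: str) -> list[str]:
    """Split a term label into its parameter factors ('a*b' -> ['a', 'b'])."""
    return [f.strip() for f in term.split("*")]


@dataclass(frozen=True)
class DoEModel:
    """Linear model of specific clearance vs. process-parameter settings.

    ``terms`` are parameter names; interaction/quadratic terms are written as
    products of parameter names joined by '*' (e.g. ``"AT_pH*AT_cond"``).
    """

    uo: str
    cqa: str
    terms: tuple[str, ...]
    beta: tuple[float, ...]
    beta0: float
    rmse: float
    n_runs: int
    n_params: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if len(self.terms) != len(self.beta):
            raise ConfigurationError(
                f"DoE model {self.uo}/{self.cqa}: terms and beta length differ")
        if self.rmse < 0:
            raise ConfigurationError(
                f"DoE model {self.uo}/{self.cqa}: rmse must be >= 0")
        if not self.n_runs > self.n_params >= 1:
            raise ConfigurationError(
                f"DoE model {self.uo}/{self.cqa}: need n_runs > n_params >= 1")

    def predict(self, settings: Mapping[str, float | np.ndarray]):
        """Expected clearance at the given settings (scalar or vectorised)."""
        val = self.beta0
        for term, b in zip(self.terms, self.beta):
            x = 1.0
            for factor in _term_factors(term):
                if factor not in settings:
                    raise ConfigurationError(
                        f"DoE model {self.uo}/{self.cqa}: no setting supplied "
                        f"for term factor {factor!r}")
                x = x * settings[factor]
            val = val + b * x
        return val


@dataclass(frozen=True)
class LoadModel:
    """Unifactorial model of specific clearance vs. specific load concentration."""

    uo: str
    cqa: str
    beta_slc: float
    beta0: float
    rmse: float
    mean_slc_doe: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ConfigurationError(
                f"load model {self.uo}/{self.cqa}: rmse must be >= 0")
        if not self.mean_slc_doe > 0:
            raise ConfigurationError(
                f"load model {self.uo}/{self.cqa}: mean_slc_doe must be > 0")

    def predict(self, slc):
        return self.beta0 + self.beta_slc * slc


@dataclass(frozen=True)
class FixedClearance:
    """Set-point clearance (mean and SD) estimated from manufacturing runs."""

    uo: str
    cqa: str
    sc_mean: float
    sc_sd: float

    def __post_init__(self) -> None:
        if self.sc_sd < 0:
            raise ConfigurationError(
                f"fixed clearance {self.uo}/{self.cqa}: sc_sd must be >= 0")


# a UO×CQA model cell: one model, a (DoE, load) pair, or absent (pass-through)
ModelSpec = DoEModel | LoadModel | FixedClearance | tuple[DoEModel, LoadModel]


@dataclass
class UnitOperation:
    """One processing step, with per-CQA clearance models."""

    name: str
    order: int
    models: dict[str, ModelSpec] = field(default_factory=dict)

    def model_kind(self, cqa: str) -> str:
        spec = self.models.get(cqa)
        if spec is None:
            return "none"
        if isinstance(spec, tuple):
            return "both"
        if isinstance(spec, DoEModel):
            return "doe"
        if isinstance(spec, LoadModel):
            return "load"
        return "fixed"

    def noise_sd(self, cqa: str) -> float:
        """SD of the clearance noise for this cell (0 for pass-through)."""
        spec = self.models.get(cqa)
        if spec is None:
            return 0.0
        if isinstance(spec, tuple):
            return spec[0].rmse
        if isinstance(spec, FixedClearance):
            return spec.sc_sd
        return spec.rmse


@dataclass
class ProcessChain:
    """Ordered unit operations plus the parameter and CQA catalogues."""

    unit_operations: list[UnitOperation]
    parameters: list[ProcessParameter]
    cqas: list[QualityAttribute]

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    def parameter(self, name: str) -> ProcessParameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise ConfigurationError(f"unknown parameter {name!r}")

    def cqa(self, name: str) -> QualityAttribute:
        for c in self.cqas:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown CQA {name!r}")

    @property
    def cqa_names(self) -> list[str]:
        return [c.name for c in self.cqas]

    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def uo_names(self) -> list[str]:
        return [u.name for u in self.ordered_uos()]

    def ordered_uos(self) -> list[UnitOperation]:
        return sorted(self.unit_operations, key=lambda u: u.order)

    def doe_parameters(self) -> list[str]:
        """Names of parameters appearing in at least one DoE model term."""
        used: set[str] = set()
        for uo in self.unit_operations:
            for spec in uo.models.values():
                doe = spec[0] if isinstance(spec, tuple) else spec
                if isinstance(doe, DoEModel):
                    for term in doe.terms:
                        used.update(_term_factors(term))
        return [p.name for p in self.parameters if p.name in used]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        orders = sorted(u.order for u in self.unit_operations)
        if orders != list(range(1, len(self.unit_operations) + 1)):
            raise ConfigurationError(
                f"unit-operation orders must be a contiguous 1..K permutation, "
                f"got {orders}")
        pnames = [p.name for p in self.parameters]
        if len(set(pnames)) != len(pnames):
            raise ConfigurationError("duplicate parameter names")
        cnames = [c.name for c in self.cqas]
        if len(set(cnames)) != len(cnames):
            raise ConfigurationError("duplicate CQA names")
        by_uo = {p.name: p.uo for p in self.parameters}
        for uo in self.unit_operations:
            for cqa_name, spec in uo.models.items():
                if cqa_name not in cnames:
                    raise ConfigurationError(
                        f"model at {uo.name} references unknown CQA {cqa_name!r}")
                doe = spec[0] if isinstance(spec, tuple) else spec
                if isinstance(doe, DoEModel):
                    for term in doe.terms:
                        for factor in _term_factors(term):
                            if factor not in by_uo:
                                raise ConfigurationError(
                                    f"DoE term {term!r} at {uo.name}/{cqa_name} "
                                    f"references unknown parameter {factor!r}")
                            if by_uo[factor] != uo.name:
                                raise ConfigurationError(
                                    f"DoE term {term!r} at {uo.name}/{cqa_name} "
                                    f"uses parameter {factor!r} of UO "
                                    f"{by_uo[factor]!r}")


def _predict_cell(spec: ModelSpec | None, settings, slc):
    """Deterministic mean clearance of one UO×CQA cell (scalar or vectorised)."""
    if spec is None:
        return 1.0
    if isinstance(spec, FixedClearance):
        return spec.sc_mean
    if isinstance(spec, DoEModel):
        return spec.predict(settings)
    if isinstance(spec, LoadModel):
        return spec.predict(slc)
    doe, load = spec
    ref = load.predict(load.mean_slc_doe)
    if ref == 0:
        raise SimulationError(
            f"load model {load.uo}/{load.cqa}: zero predicted clearance at "
            f"mean DoE load concentration")
    return doe.predict(settings) * (load.predict(slc) / ref)


def predict_clearance(uo: UnitOperation, cqa: str,
                      pp_settings: Mapping[str, float],
                      slc: float | None = None) -> float:
    """Expected specific clearance of one unit operation for one CQA.

    DoE-only cells evaluate the linear model at ``pp_settings``; load-only
    cells evaluate at ``slc``; 'both' cells multiply the DoE prediction by
    the load model's response at ``slc`` relative to its response at the
    mean DoE load concentration; fixed cells return their set-point mean and
    absent cells return 1.
    """
    spec = uo.models.get(cqa)
    needs_slc = isinstance(spec, (LoadModel, tuple))
    if needs_slc:
        if slc is None or not slc > 0:
            raise DomainError(
                f"{uo.name}/{cqa}: a load model is present, slc must be > 0")
    return float(_predict_cell(spec, pp_settings, slc))


@dataclass
class PropagationResult:
    """Per-UO pool concentrations, drug-substance values and clamp count."""

    pools: pd.DataFrame           # index = UO names in order, columns = CQAs
    ds: dict[str, float]          # drug-substance concentration per CQA
    clamp_count: int


def propagate(chain: ProcessChain,
              pp_settings: Mapping[str, float],
              start_conc: Mapping[str, float],
              noise_draws: Mapping[tuple[str, str], float] | None = None,
              ) -> PropagationResult:
    """Propagate starting concentrations through the chain to drug substance.

    For each UO in order the pool concentration is the incoming concentration
    times (predicted clearance + noise draw); the pool of UO k is the load of
    UO k+1 and the last pool is the drug-substance value.  A negative factor
    is clamped to 0 and counted.
    """
    if not chain.unit_operations:
        raise ConfigurationError("process chain has no unit operations")
    for cqa in chain.cqas:
        if cqa.name not in start_conc or not start_conc[cqa.name] > 0:
            raise DomainError(
                f"start concentration for CQA {cqa.name!r} must be > 0")
    noise = dict(noise_draws or {})
    uos = chain.ordered_uos()
    settings = dict(pp_settings)
    conc = {c.name: float(start_conc[c.name]) for c in chain.cqas}
    rows = []
    clamps = 0
    for uo in uos:
        row = {}
        for cqa in chain.cqas:
            spec = uo.models.get(cqa.name)
            sc = _predict_cell(spec, settings, conc[cqa.name])
            factor = sc + noise.get((uo.name, cqa.name), 0.0)
            if factor < 0:
                factor = 0.0
                clamps += 1
            conc[cqa.name] *= factor
            if not math.isfinite(conc[cqa.name]):
                raise SimulationError(
                    f"non-finite concentration at {uo.name}/{cqa.name}")
            row[cqa.name] = conc[cqa.name]
        rows.append(row)
    pools = pd.DataFrame(rows, index=[u.name for u in uos])
    return PropagationResult(pools=pools, ds=dict(conc), clamp_count=clamps)
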