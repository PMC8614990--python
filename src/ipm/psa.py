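"""Grid-based one-at-a-time parameter sensitivity analysis.

The investigated parameter is fixed in turn at each of ``grid_size``
equidistant points spanning its screening range (endpoints inclusive) while
all other parameters vary inside their normal operating ranges; each grid
point runs a full Monte-Carlo simulation and records the per-CQA OOA at drug
substance.  The set point is always evaluated as an extra point because the
severity slopes are anchored there exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .process_chain import ProcessChain, ProcessParameter
from .simulation import run_ipm

__all__ = ["PSACurve", "run_psa", "relative_screening_range", "run_psa_all"]


@dataclass
class PSACurve:
    """%OOA at drug substance per CQA across one parameter's screening range."""

    parameter: str
    param: ProcessParameter = field(repr=False)
    grid: np.ndarray                      # strictly increasing, sr_low..sr_high
    ooa: pd.DataFrame = field(repr=False)  # grid points × CQAs, percent
    set_point_ooa: dict[str, float]
    n_per_point: int
    seed: int
    warnings: list[str] = field(default_factory=list)

    @property
    def cqa_names(self) -> list[str]:
        return list(self.ooa.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long format: parameter, grid_value, coded_value, cqa, ooa_percent,
        is_set_point — plus the parameter geometry needed to rebuild the curve."""
        rows = []
        for i, x in enumerate(self.grid):
            for cqa in self.cqa_names:
                rows.append((float(x), cqa, float(self.ooa.iloc[i][cqa]), False))
        for cqa in self.cqa_names:
            rows.append((float(self.param.set_point), cqa,
                         float(self.set_point_ooa[cqa]), True))
        df = pd.DataFrame(rows, columns=["grid_value", "cqa", "ooa_percent",
                                         "is_set_point"])
        df.insert(0, "parameter", self.parameter)
        df["coded_value"] = [
            relative_screening_range(x, self.param) for x in df["grid_value"]]
        df["set_point"] = self.param.set_point
        df["sr_low"] = self.param.sr_low
        df["sr_high"] = self.param.sr_high
        df["n_per_point"] = self.n_per_point
        df["seed"] = self.seed
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PSACurve":
        """Rebuild a curve from its ``to_frame`` export (one parameter)."""
        params = df["parameter"].unique()
        if len(params) != 1:
            raise ConfigurationError(
                f"expected a single parameter per curve frame, got {list(params)}")
        sp = float(df["set_point"].iloc[0])
        p = ProcessParameter(
            name=str(params[0]), uo="", set_point=sp,
            nor_low=sp, nor_high=sp,
            sr_low=float(df["sr_low"].iloc[0]),
            sr_high=float(df["sr_high"].iloc[0]))
        grid_df = df[~df["is_set_point"]].pivot_table(
            index="grid_value", columns="cqa", values="ooa_percent")
        sp_df = df[df["is_set_point"]]
        sp_ooa = dict(zip(sp_df["cqa"], sp_df["ooa_percent"].astype(float)))
        return cls(parameter=p.name, param=p,
                   grid=grid_df.index.to_numpy(float),
                   ooa=grid_df,
                   set_point_ooa=sp_ooa,
                   n_per_point=int(df["n_per_point"].iloc[0]),
                   seed=int(df["seed"].iloc[0]))


def relative_screening_range(x: float, p: ProcessParameter) -> float:
    """Code ``x`` onto the set-point-centred screening-range scale.

    (x − set point) / (screening width / 2); the set point maps to 0 and the
    image is a sub-interval of [−2, 2].
    """
    half = (p.sr_high - p.sr_low) / 2.0
    if half <= 0:
        raise DomainError(f"parameter {p.name!r}: zero-width screening range")
    if not (p.sr_low - 1e-12 <= x <= p.sr_high + 1e-12):
        raise DomainError(
            f"value {x} outside screening range [{p.sr_low}, {p.sr_high}] "
            f"of {p.name!r}")
    return (x - p.set_point) / half


def _point_seed(master_seed: int, parameter: str, index: int) -> int:
    """Deterministic per-grid-point seed from (master seed, parameter, index)."""
    tag = zlib.crc32(parameter.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), int(tag), int(index)])
    return int(ss.generate_state(1)[0])


def run_psa(chain: ProcessChain, parameter: str,
            grid_size: int = 10, n: int = 1000,
            rng_seed: int = 0, gamma: float = 0.95) -> PSACurve:
    """One-at-a-time PSA of ``parameter`` across its screening range."""
    if grid_size < 2:
        raise ConfigurationError("grid_size must be >= 2")
    p = chain.parameter(parameter)
    warnings = []
    if parameter not in chain.doe_parameters():
        warnings.append(
            f"parameter {parameter!r} appears in no DoE model; the OOA curve "
            f"is flat by construction")
    grid = np.linspace(p.sr_low, p.sr_high, grid_size)
    rows = []
    for i, x in enumerate(grid):
        sim = run_ipm(chain, n=n, fixed=(parameter, float(x)),
                      rng_seed=_point_seed(rng_seed, parameter, i), gamma=gamma)
        rows.append(sim.ooa)
    sp_sim = run_ipm(chain, n=n, fixed=(parameter, p.set_point),
                     rng_seed=_point_seed(rng_seed, parameter, grid_size),
                     gamma=gamma)
    ooa = pd.DataFrame(rows, index=grid)
    return PSACurve(parameter=parameter, param=p, grid=grid, ooa=ooa,
                    set_point_ooa=dict(sp_sim.ooa), n_per_point=n,
                    seed=int(rng_seed), warnings=warnings)


def run_psa_all(chain: ProcessChain, grid_size: int = 10, n: int = 1000,
                rng_seed: int = 0, gamma: float = 0.95,
                parameters: list[str] | None = None) -> dict[str, PSACurve]:
    """PSA curves for every (or the given) parameters, one shared master seed."""
    names = parameters if parameters is not None else chain.parameter_names
    return {name: run_psa(chain, name, grid_size=grid_size, n=n,
                          rng_seed=rng_seed, gamma=gamma)
            for name in names}
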