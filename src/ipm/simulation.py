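"""Monte-Carlo engine: parameter sampling, chain propagation and OOA.

Each simulation cycle draws every process parameter from an independent
normal distribution centred at its set point with the normal operating range
spanning ±3 standard deviations, draws each CQA's starting concentration
from its configured normal distribution, adds mean-zero Gaussian clearance
noise scaled to each model's RMSE, and propagates through the chain to drug
substance.  The out-of-acceptance (OOA) probability of the resulting sample
is evaluated parametrically with the sample SD replaced by its upper
one-sided confidence limit s* = s·sqrt((n−1)/χ²(1−γ, n−1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, DomainError, SimulationError
from .process_chain import ProcessChain, _predict_cell

__all__ = [
    "SimulationResult",
    "sample_parameters",
    "run_ipm",
    "ooa_probability",
    "parametric_ooa",
    "sd_upper_confidence_limit",
    "plausibility_report",
    "PlausibilityReport",
]


def sd_upper_confidence_limit(s: float, n: int, gamma: float = 0.95) -> float:
    """Upper one-sided confidence limit of the standard deviation.

    s* = s·sqrt((n−1)/χ²_{1−γ, n−1}) with the χ² quantile taken at the lower
    tail so that s* ≥ s.
    """
    if n < 2:
        raise DataError("s* needs a sample of at least 2 values")
    q = stats.chi2.ppf(1.0 - gamma, n - 1)
    return float(s * np.sqrt((n - 1) / q))


def parametric_ooa(mean: float, sd: float,
                   lsl: float | None = None, usl: float | None = None,
                   n: int | None = None, gamma: float = 0.95) -> float:
    """Normal-tail OOA percentage for N(mean, sd²) against the given limits.

    With finite ``n`` the SD is first inflated to its upper one-sided
    confidence limit; ``n=None`` is the large-sample limit (no inflation).
    """
    if lsl is None and usl is None:
        raise DataError("at least one acceptance limit is required")
    if sd < 0:
        raise DomainError("sd must be >= 0")
    if sd == 0:
        out = (lsl is not None and mean <= lsl) or \
              (usl is not None and mean >= usl)
        return 100.0 if out else 0.0
    s_star = sd if n is None else sd_upper_confidence_limit(sd, n, gamma)
    p = 0.0
    if lsl is not None:
        p += stats.norm.cdf((lsl - mean) / s_star)
    if usl is not None:
        p += stats.norm.sf((usl - mean) / s_star)
    return float(100.0 * p)


def ooa_probability(values, lsl: float | None = None, usl: float | None = None,
                    gamma: float = 0.95) -> float:
    """OOA percentage of a drug-substance sample via the inflated-SD normal fit."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise DataError("OOA needs at least 2 values")
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    return parametric_ooa(mean, s, lsl, usl, n=int(x.size), gamma=gamma)


def sample_parameters(chain: ProcessChain, n: int,
                      fixed: tuple[str, float] | None = None,
                      rng_seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw ``n`` i.i.d. settings per parameter: N(set point, (NOR width/6)²).

    ``fixed=(name, value)`` pins one parameter to a constant grid value,
    which must lie inside its screening range.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if fixed is not None:
        p = chain.parameter(fixed[0])
        if not (p.sr_low <= fixed[1] <= p.sr_high):
            raise DomainError(
                f"fixed value {fixed[1]} outside screening range "
                f"[{p.sr_low}, {p.sr_high}] of {p.name!r}")
    cols = {}
    for p in chain.parameters:
        if fixed is not None and p.name == fixed[0]:
            cols[p.name] = np.full(n, float(fixed[1]))
        elif p.nor_sd == 0:
            cols[p.name] = np.full(n, p.set_point)
        else:
            cols[p.name] = rng.normal(p.set_point, p.nor_sd, size=n)
    return pd.DataFrame(cols)


@dataclass
class SimulationResult:
    """Outcome of one Monte-Carlo simulation of the full chain."""

    n_cycles: int
    uo_names: list[str]
    cqa_names: list[str]
    pool_conc: np.ndarray = field(repr=False)   # (n_cycles, n_uos, n_cqas)
    ds_values: pd.DataFrame = field(repr=False)  # n_cycles × CQAs
    ooa: dict[str, float]
    seed: int
    clamp_count: int
    chain: ProcessChain = field(repr=False, default=None)

    def to_long_frame(self) -> pd.DataFrame:
        """Cycles × UO × CQA pool concentrations in long format."""
        n, k, c = self.pool_conc.shape
        idx = pd.MultiIndex.from_product(
            [range(n), self.uo_names, self.cqa_names],
            names=["cycle", "uo", "cqa"])
        return pd.DataFrame(
            {"conc": self.pool_conc.reshape(-1)}, index=idx).reset_index()

    def summary(self) -> dict:
        return {"n_cycles": self.n_cycles, "seed": self.seed,
                "clamp_count": self.clamp_count, "ooa_percent": dict(self.ooa)}


def run_ipm(chain: ProcessChain, n: int = 1000,
            fixed: tuple[str, float] | None = None,
            rng_seed: int = 0, gamma: float = 0.95) -> SimulationResult:
    """Run ``n`` Monte-Carlo cycles of the full chain and report per-CQA OOA."""
    if not chain.unit_operations:
        raise ConfigurationError("process chain has no unit operations")
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    rng = np.random.default_rng(rng_seed)
    settings_df = sample_parameters(chain, n, fixed=fixed, rng_seed=rng)
    settings = {name: settings_df[name].to_numpy() for name in settings_df}
    uos = chain.ordered_uos()
    n_uo, n_cqa = len(uos), len(chain.cqas)

    starts = np.empty((n, n_cqa))
    for j, cqa in enumerate(chain.cqas):
        starts[:, j] = (np.full(n, cqa.start_mean) if cqa.start_sd == 0
                        else rng.normal(cqa.start_mean, cqa.start_sd, size=n))
    # draw order is fixed (UO-major, CQA-minor) so runs are seed-reproducible
    noise = {}
    for uo in uos:
        for cqa in chain.cqas:
            sd = uo.noise_sd(cqa.name)
            noise[(uo.name, cqa.name)] = (
                rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)

    pools = np.empty((n, n_uo, n_cqa))
    conc = starts.copy()
    clamps = 0
    for k, uo in enumerate(uos):
        for j, cqa in enumerate(chain.cqas):
            spec = uo.models.get(cqa.name)
            sc = _predict_cell(spec, settings, conc[:, j])
            factor = np.asarray(sc + noise[(uo.name, cqa.name)], float)
            if factor.ndim == 0:
                factor = np.full(n, float(factor))
            neg = factor < 0
            if neg.any():
                clamps += int(np.count_nonzero(neg))
                factor = np.where(neg, 0.0, factor)
            conc[:, j] = conc[:, j] * factor
            if not np.isfinite(conc[:, j]).all():
                bad = int(np.flatnonzero(~np.isfinite(conc[:, j]))[0])
                raise SimulationError(
                    f"non-finite prediction at cycle {bad}, UO {uo.name!r}, "
                    f"CQA {cqa.name!r}")
            pools[:, k, j] = conc[:, j]

    ds = pd.DataFrame(pools[:, -1, :], columns=chain.cqa_names)
    ooa = {cqa.name: ooa_probability(ds[cqa.name].to_numpy(),
                                     lsl=cqa.lsl, usl=cqa.usl, gamma=gamma)
           for cqa in chain.cqas}
    return SimulationResult(
        n_cycles=n, uo_names=[u.name for u in uos], cqa_names=chain.cqa_names,
        pool_conc=pools, ds_values=ds, ooa=ooa,
        seed=int(rng_seed), clamp_count=clamps, chain=chain)


@dataclass
class PlausibilityReport:
    """Simulated vs. observed pool statistics and OOA comparison."""

    pool_stats: pd.DataFrame   # uo, cqa, sim_mean, sim_sd, obs_mean, obs_sd
    ooa_comparison: pd.DataFrame  # cqa, sim_ooa, obs_ooa, n_obs


def plausibility_report(sim: SimulationResult,
                        observed: pd.DataFrame,
                        gamma: float = 0.95) -> PlausibilityReport:
    """Compare a simulation against observed manufacturing runs.

    ``observed`` is long format (run, uo, cqa, conc).  Observed OOA is
    computed with the same inflated-SD formula at n = number of observed
    runs, so the s* inflation is material for sparse real data.
    """
    if observed is None or len(observed) == 0:
        raise ConfigurationError("observed run table is empty")
    chain = sim.chain
    obs_cqas = set(observed["cqa"].unique())
    unknown = obs_cqas - set(sim.cqa_names)
    if unknown:
        raise ConfigurationError(
            f"observed CQAs not present in the chain: {sorted(unknown)}")
    obs = observed[observed["uo"] != "_start"]
    rows = []
    for k, uo in enumerate(sim.uo_names):
        for j, cqa in enumerate(sim.cqa_names):
            vals = obs[(obs["uo"] == uo) & (obs["cqa"] == cqa)]["conc"]
            sim_vals = sim.pool_conc[:, k, j]
            rows.append({
                "uo": uo, "cqa": cqa,
                "sim_mean": float(sim_vals.mean()),
                "sim_sd": float(sim_vals.std(ddof=1)),
                "obs_mean": float(vals.mean()) if len(vals) else np.nan,
                "obs_sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n_obs": int(len(vals)),
            })
    last_uo = sim.uo_names[-1]
    ooa_rows = []
    for cqa_name in sim.cqa_names:
        cqa = chain.cqa(cqa_name)
        ds_obs = obs[(obs["uo"] == last_uo) & (obs["cqa"] == cqa_name)]["conc"]
        obs_ooa = (ooa_probability(ds_obs.to_numpy(), cqa.lsl, cqa.usl, gamma)
                   if len(ds_obs) >= 2 else np.nan)
        ooa_rows.append({"cqa": cqa_name, "sim_ooa": sim.ooa[cqa_name],
                         "obs_ooa": obs_ooa, "n_obs": int(len(ds_obs))})
    return PlausibilityReport(pool_stats=pd.DataFrame(rows),
                              ooa_comparison=pd.DataFrame(ooa_rows))
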