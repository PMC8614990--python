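"""Publication-style plots: trending, PSA overlays, severity bars, PAR shading."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fmea import SeverityAssessment
from .par import PARResult
from .psa import PSACurve
from .simulation import SimulationResult

__all__ = ["trending_plot", "psa_overlay_by_cqa", "psa_parameter_plot",
           "severity_bar_chart"]


def trending_plot(sim: SimulationResult, cqa: str,
                  observed: pd.DataFrame | None = None):
    """Per-UO pool distributions in process order, observed runs overlaid."""
    j = sim.cqa_names.index(cqa)
    data = [sim.pool_conc[:, k, j] for k in range(len(sim.uo_names))]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.violinplot(data, positions=range(len(sim.uo_names)), showmedians=True)
    if observed is not None and len(observed):
        obs = observed[(observed["cqa"] == cqa) & (observed["uo"] != "_start")]
        pos = {u: k for k, u in enumerate(sim.uo_names)}
        ax.scatter([pos[u] for u in obs["uo"]], obs["conc"],
                   color="k", marker="x", zorder=3, label="observed runs")
        ax.legend()
    ax.set_xticks(range(len(sim.uo_names)), sim.uo_names, rotation=45)
    ax.set_ylabel(f"{cqa} specific concentration")
    ax.set_title(f"Simulated pools per unit operation — {cqa} "
                 f"(n={sim.n_cycles})")
    fig.tight_layout()
    return fig


def psa_overlay_by_cqa(curves: dict[str, PSACurve], cqa: str,
                       critical_ooa: float = 5.0):
    """All parameters for one CQA on the set-point-centred coded axis."""
    from .psa import relative_screening_range
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, curve in curves.items():
        coded = [relative_screening_range(x, curve.param) for x in curve.grid]
        ax.plot(coded, curve.ooa[cqa], marker="o", ms=3, label=name)
    ax.axhline(critical_ooa, color="r", ls="--", lw=1,
               label=f"critical {critical_ooa:g}%")
    ax.set_xlabel("relative screening range (set point = 0)")
    ax.set_ylabel("%OOA at drug substance")
    ax.set_title(f"PSA overlay — {cqa}")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    return fig


def psa_parameter_plot(curve: PSACurve, critical_ooa: float = 5.0,
                       par: PARResult | None = None):
    """All CQAs across one parameter's screening range, PAR shaded."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for cqa in curve.cqa_names:
        ax.plot(curve.grid, curve.ooa[cqa], marker="o", ms=3, label=cqa)
    ax.axvline(curve.param.set_point, color="k", ls=":", lw=1, label="set point")
    ax.axhline(critical_ooa, color="r", ls="--", lw=1)
    if par is not None and par.par_low is not None:
        ax.axvspan(par.par_low, par.par_high, color="grey", alpha=0.25,
                   label="PAR")
    ax.set_xlabel(curve.parameter)
    ax.set_ylabel("%OOA at drug substance")
    ax.set_title(f"PSA — {curve.parameter}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def severity_bar_chart(assessments: dict[str, SeverityAssessment]):
    """Grouped bars: per-CQA severity ranking for each parameter."""
    params = list(assessments)
    cqas = list(next(iter(assessments.values())).per_cqa)
    width = 0.8 / max(len(cqas), 1)
    fig, ax = plt.subplots(figsize=(max(6, len(params)), 4))
    x = np.arange(len(params))
    for i, cqa in enumerate(cqas):
        vals = [assessments[p].per_cqa[cqa].ranking for p in params]
        ax.bar(x + i * width, vals, width=width, label=cqa)
    ax.set_xticks(x + 0.4 - width / 2, params, rotation=45, ha="right")
    ax.set_ylabel("FMEA severity ranking")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
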