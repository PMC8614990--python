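"""Proven-acceptable-range (PAR) derivation from PSA curves.

Per CQA and per side of the set point, the first grid interval (moving
outward from the set point) whose endpoints straddle the critical OOA level
is located and the crossing is linearly interpolated inside it.  The PAR is
the contiguous sub-interval containing the set point on which every CQA's
OOA stays at or below the critical level; the most restrictive crossing per
side sets the final limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .psa import PSACurve

__all__ = ["PARResult", "find_par", "par_table"]


@dataclass
class PARResult:
    """Most-restrictive proven acceptable range for one parameter."""

    parameter: str
    crossings: dict[str, tuple[float | None, float | None]]  # cqa -> (low, high)
    par_low: float | None
    par_high: float | None
    classification: str  # full range acceptable / restriction low / restriction
                         # high / restriction both / undefined
    impacted_cqas: list[str] = field(default_factory=list)
    critical_ooa: float = 5.0

    def to_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "par_low": self.par_low, "par_high": self.par_high,
            "classification": self.classification,
            "impacted_cqas": ";".join(self.impacted_cqas),
            "critical_ooa": self.critical_ooa,
        }


def _side_points(curve: PSACurve, cqa: str, side: str,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Ordered (x, ooa) walking outward from the set point on one side.

    Starts at the dedicated set-point evaluation, then the grid nodes beyond
    it (grid nodes coinciding with the set point are skipped)."""
    sp = curve.param.set_point
    xs = [sp]
    ys = [float(curve.set_point_ooa[cqa])]
    grid = curve.grid
    vals = curve.ooa[cqa].to_numpy(float)
    if side == "high":
        sel = grid > sp
        order = np.argsort(grid[sel])
    else:
        sel = grid < sp
        order = np.argsort(grid[sel])[::-1]
    xs.extend(grid[sel][order])
    ys.extend(vals[sel][order])
    return np.asarray(xs, float), np.asarray(ys, float)


def _crossing(curve: PSACurve, cqa: str, side: str,
              critical_ooa: float) -> float | None:
    """Interpolated crossing of the critical level nearest the set point.

    None when the curve stays at or below the level out to the screening
    edge on that side."""
    xs, ys = _side_points(curve, cqa, side)
    for i in range(len(xs) - 1):
        if ys[i] <= critical_ooa < ys[i + 1]:
            t = (critical_ooa - ys[i]) / (ys[i + 1] - ys[i])
            return float(xs[i] + t * (xs[i + 1] - xs[i]))
    return None


def find_par(curve: PSACurve, critical_ooa: float = 5.0) -> PARResult:
    """Derive the PAR of one parameter from its PSA curve (all CQAs).

    If any CQA's set-point OOA already exceeds the critical level the PAR is
    undefined.  Otherwise each side's limit is the crossing closest to the
    set point over all CQAs, defaulting to the screening edge when no CQA
    crosses; the CQAs whose crossings set a final limit are recorded.
    """
    if curve is None or not curve.cqa_names:
        raise ConfigurationError("no PSA curves supplied")
    p = curve.param
    sp = p.set_point
    over = [c for c in curve.cqa_names
            if curve.set_point_ooa[c] > critical_ooa]
    if over:
        return PARResult(
            parameter=curve.parameter,
            crossings={c: (None, None) for c in curve.cqa_names},
            par_low=None, par_high=None, classification="undefined",
            impacted_cqas=sorted(over), critical_ooa=critical_ooa)

    crossings: dict[str, tuple[float | None, float | None]] = {}
    for cqa in curve.cqa_names:
        lo = _crossing(curve, cqa, "low", critical_ooa)
        hi = _crossing(curve, cqa, "high", critical_ooa)
        crossings[cqa] = (lo, hi)

    low_cands = {c: x for c, (x, _) in crossings.items() if x is not None}
    high_cands = {c: x for c, (_, x) in crossings.items() if x is not None}
    par_low = max(low_cands.values()) if low_cands else p.sr_low
    par_high = min(high_cands.values()) if high_cands else p.sr_high
    impacted = sorted(
        {c for c, x in low_cands.items() if x == par_low}
        | {c for c, x in high_cands.items() if x == par_high})

    if not low_cands and not high_cands:
        cls = "full range acceptable"
    elif low_cands and high_cands:
        cls = "restriction both"
    elif low_cands:
        cls = "restriction low"
    else:
        cls = "restriction high"
    # numeric guard: the PAR must contain the set point
    par_low = min(par_low, sp)
    par_high = max(par_high, sp)
    return PARResult(parameter=curve.parameter, crossings=crossings,
                     par_low=par_low, par_high=par_high, classification=cls,
                     impacted_cqas=impacted, critical_ooa=critical_ooa)


def par_table(results: dict[str, PARResult],
              uo_by_parameter: dict[str, str] | None = None) -> pd.DataFrame:
    """Summary table: unit operation, parameter, control range, justification."""
    rows = []
    for res in results.values():
        row = res.to_row()
        row["uo"] = (uo_by_parameter or {}).get(res.parameter, "")
        rows.append(row)
    cols = ["uo", "parameter", "par_low", "par_high", "classification",
            "impacted_cqas", "critical_ooa"]
    return pd.DataFrame(rows)[cols]
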