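"""Automated FMEA severity ranking from PSA curves.

For each parameter×CQA the procedure compares two slopes on each side of the
set point:

* the *critical slope* — from the set-point OOA up to the predefined critical
  OOA level (default 5%) at the screening-range edge: the maximum allowable
  effect per native unit,
* the *CQA slope* — from the set-point OOA to the simulated OOA at the
  screening-range edge: the effect the model actually predicts.

Their ratio (worst case of the two sides, beneficial directions floored at
0) is mapped through a rubric to a severity rank.  A ratio ≥ the top band —
i.e. a predicted effect at least as steep as the maximum allowable one —
classifies the parameter as a CPP.  If the set-point OOA already meets or
exceeds the critical level the top rank is assigned by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import AssessmentError, ConfigurationError
from .psa import PSACurve

__all__ = [
    "RankingRubric",
    "DEFAULT_RUBRIC",
    "critical_slope",
    "cqa_slope",
    "assign_ranking",
    "assess_parameter",
    "SeverityAssessment",
    "severity_table",
]


@dataclass(frozen=True)
class RankingRubric:
    """Ordered (lower-bound, rank) bands on the slope ratio.

    Bands are lower-bound inclusive, upper-bound exclusive; the highest band
    is unbounded above.  The default reproduces the published rubric:
    ratio ≥ 0.8 → 10, [0.5, 0.8) → 7, [0.3, 0.5) → 3, [0, 0.3) → 1.
    """

    bands: tuple[tuple[float, int], ...] = ((0.8, 10), (0.5, 7), (0.3, 3), (0.0, 1))

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("rubric needs at least one band")
        lows = [b[0] for b in self.bands]
        if lows != sorted(lows, reverse=True) or len(set(lows)) != len(lows):
            raise ConfigurationError(
                f"rubric bands must have strictly decreasing lower bounds "
                f"(non-overlapping), got {lows}")
        if lows[-1] != 0.0:
            raise ConfigurationError("lowest rubric band must start at 0")

    @property
    def top_rank(self) -> int:
        return self.bands[0][1]

    def rank(self, ratio: float) -> int:
        if ratio < 0:
            ratio = 0.0
        if math.isinf(ratio):
            return self.top_rank
        for low, rank in self.bands:
            if ratio >= low:
                return rank
        return self.bands[-1][1]  # unreachable: last band starts at 0


DEFAULT_RUBRIC = RankingRubric()


def _side_edge(curve: PSACurve, side: str) -> float:
    if side == "low":
        return curve.param.sr_low
    if side == "high":
        return curve.param.sr_high
    raise ConfigurationError(f"side must be 'low' or 'high', got {side!r}")


def side_applicable(curve: PSACurve, side: str) -> bool:
    """A side is inapplicable when the set point sits on that screening edge."""
    return _side_edge(curve, side) != curve.param.set_point


def critical_slope(curve: PSACurve, cqa: str, side: str,
                   critical_ooa: float = 5.0) -> float | None:
    """Maximum allowable OOA slope: (critical level − set-point OOA) over the
    half screening range on the given side.  None when the side is degenerate."""
    if not side_applicable(curve, side):
        return None
    edge = _side_edge(curve, side)
    return (critical_ooa - curve.set_point_ooa[cqa]) / (edge - curve.param.set_point)


def cqa_slope(curve: PSACurve, cqa: str, side: str) -> float | None:
    """Simulated OOA slope: (edge OOA − set-point OOA) over the half range."""
    if not side_applicable(curve, side):
        return None
    edge = _side_edge(curve, side)
    idx = 0 if side == "low" else len(curve.grid) - 1
    ooa_edge = float(curve.ooa.iloc[idx][cqa])
    return (ooa_edge - curve.set_point_ooa[cqa]) / (edge - curve.param.set_point)


def _side_ratio(m_cqa: float | None, m_crit: float | None, side: str,
                ) -> float | None:
    """Slope ratio on one side; inf flags the by-design top rank.

    On the high side harm means positive slopes, on the low side negative
    ones (the denominator set point → edge is negative).  A critical slope of
    the wrong sign (or zero) means the set-point OOA already meets or exceeds
    the critical level, which forces the top rank.  Beneficial CQA slopes
    floor at 0.
    """
    if m_cqa is None or m_crit is None:
        return None
    harm_sign = 1.0 if side == "high" else -1.0
    if m_crit * harm_sign <= 0:
        return math.inf
    ratio = m_cqa / m_crit
    return max(ratio, 0.0)


def assign_ranking(m_cqa_low: float | None, m_cqa_high: float | None,
                   m_crit_low: float | None, m_crit_high: float | None,
                   rubric: RankingRubric = DEFAULT_RUBRIC,
                   ) -> tuple[float, str, int]:
    """Worst-case slope ratio of the two sides and its rubric rank.

    Returns (ratio, worst side, rank).  Pass None for an inapplicable side;
    both sides None is an error.
    """
    ratios = {"low": _side_ratio(m_cqa_low, m_crit_low, "low"),
              "high": _side_ratio(m_cqa_high, m_crit_high, "high")}
    applicable = {s: r for s, r in ratios.items() if r is not None}
    if not applicable:
        raise AssessmentError("no applicable side for ranking")
    worst_side = max(applicable, key=lambda s: applicable[s])
    ratio = applicable[worst_side]
    return ratio, worst_side, rubric.rank(ratio)


@dataclass
class CQASeverity:
    """Per-CQA severity record of one parameter."""

    cqa: str
    m_critical_low: float | None
    m_critical_high: float | None
    m_cqa_low: float | None
    m_cqa_high: float | None
    pct_ref_low: float | None
    pct_ref_high: float | None
    worst_side: str
    pct_ref: float
    ranking: int


@dataclass
class SeverityAssessment:
    """Severity ranking of one parameter across all CQAs."""

    parameter: str
    per_cqa: dict[str, CQASeverity]
    final_ranking: int
    is_cpp: bool
    critical_ooa: float = 5.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.per_cqa.values():
            rows.append({
                "parameter": self.parameter, "cqa": rec.cqa,
                "ratio_low": rec.pct_ref_low, "ratio_high": rec.pct_ref_high,
                "worst_side": rec.worst_side, "worst_ratio": rec.pct_ref,
                "ranking": rec.ranking,
                "final_ranking": self.final_ranking, "is_cpp": self.is_cpp,
            })
        return pd.DataFrame(rows)


def assess_parameter(curve: PSACurve, critical_ooa: float = 5.0,
                     rubric: RankingRubric = DEFAULT_RUBRIC,
                     ) -> SeverityAssessment:
    """Severity assessment of one parameter from its PSA curve (all CQAs).

    The final ranking is the worst (maximum) ranking over the CQAs; the
    parameter is a CPP iff the final ranking is the rubric's top rank.
    """
    per_cqa: dict[str, CQASeverity] = {}
    for cqa in curve.cqa_names:
        mc_lo = critical_slope(curve, cqa, "low", critical_ooa)
        mc_hi = critical_slope(curve, cqa, "high", critical_ooa)
        mq_lo = cqa_slope(curve, cqa, "low")
        mq_hi = cqa_slope(curve, cqa, "high")
        ratio, worst_side, rank = assign_ranking(mq_lo, mq_hi, mc_lo, mc_hi,
                                                 rubric)
        per_cqa[cqa] = CQASeverity(
            cqa=cqa,
            m_critical_low=mc_lo, m_critical_high=mc_hi,
            m_cqa_low=mq_lo, m_cqa_high=mq_hi,
            pct_ref_low=_side_ratio(mq_lo, mc_lo, "low"),
            pct_ref_high=_side_ratio(mq_hi, mc_hi, "high"),
            worst_side=worst_side, pct_ref=ratio, ranking=rank)
    final = max(rec.ranking for rec in per_cqa.values())
    return SeverityAssessment(
        parameter=curve.parameter, per_cqa=per_cqa, final_ranking=final,
        is_cpp=(final == rubric.top_rank), critical_ooa=critical_ooa)


def severity_table(assessments: dict[str, SeverityAssessment]) -> pd.DataFrame:
    """Concatenate per-parameter severity frames into one report table."""
    if not assessments:
        raise AssessmentError("no assessments supplied")
    return pd.concat([a.to_frame() for a in assessments.values()],
                     ignore_index=True)
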