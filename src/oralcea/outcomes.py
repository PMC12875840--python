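"""Economic outcomes: totals per strategy, the incremental cost-utility ladder,
net monetary benefit, survival summaries and currency conversion.

Strategies are ranked in ascending order of effectiveness (QALYs) and each is
compared with its predecessor.  A strategy that is cheaper and more effective
than its predecessor dominates it; its incremental cost-utility ratio (ICUR)
is reported as a dominance flag rather than a (sign-ambiguous) negative
number.  The incremental net monetary benefit (INMB) at willingness-to-pay
lambda is lambda * dQALY - dCost; positive INMB means cost-effective at that
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTrace, run_cohort
from .parameters import ParameterSet
from .stratify import GROUPS

__all__ = [
    "GroupResult",
    "ComparisonResult",
    "discount_factor",
    "group_result",
    "run_group",
    "base_case",
    "icur_ladder",
    "inmb",
    "survival_summary",
    "currency_convert",
    "results_table",
]


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value factor 1/(1+rate)^cycle."""
    if rate < 0 or cycle < 0:
        raise ValueError("rate and cycle must be non-negative")
    return (1 + rate) ** -cycle


@dataclass
class GroupResult:
    """Discounted lifetime totals and survival curves for one strategy."""

    group: str
    total_cost: float
    total_ly: float
    total_qaly: float
    os_curve: np.ndarray
    dfs_curve: np.ndarray

    @classmethod
    def from_trace(cls, trace: CohortTrace) -> "GroupResult":
        return cls(group=trace.group, total_cost=trace.total_cost,
                   total_ly=trace.total_ly, total_qaly=trace.total_qaly,
                   os_curve=trace.os_curve, dfs_curve=trace.dfs_curve)


def group_result(trace: CohortTrace) -> GroupResult:
    return GroupResult.from_trace(trace)


def run_group(group: str, params: ParameterSet,
              horizon_years: int | str | None = None, **kw) -> GroupResult:
    """Convenience: run the cohort model and summarise one strategy."""
    return GroupResult.from_trace(run_cohort(group, params, horizon_years, **kw))


def base_case(params: ParameterSet,
              horizon_years: int | str | None = None) -> dict[str, GroupResult]:
    """All three strategies under one parameter set."""
    return {g: run_group(g, params, horizon_years) for g in GROUPS}


@dataclass
class ComparisonResult:
    """Incremental comparison of one strategy against a reference."""

    reference_group: str
    comparator_group: str
    delta_cost: float
    delta_qaly: float
    icur: float | None          # None when flagged dominant/dominated
    inmb: float
    dominance: str              # none | dominant | dominated
    qaly_tie: bool = False


def inmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit: wtp * dQALY - dCost."""
    return wtp * delta_qaly - delta_cost


def _compare(ref: GroupResult, comp: GroupResult, wtp: float) -> ComparisonResult:
    dc = comp.total_cost - ref.total_cost
    dq = comp.total_qaly - ref.total_qaly
    tie = dq == 0
    if dc < 0 and dq > 0:
        dominance = "dominant"
    elif dc > 0 and dq < 0:
        dominance = "dominated"
    else:
        dominance = "none"
    icur = dc / dq if (dq != 0 and dominance == "none") else None
    return ComparisonResult(reference_group=ref.group, comparator_group=comp.group,
                            delta_cost=dc, delta_qaly=dq, icur=icur,
                            inmb=inmb(dc, dq, wtp), dominance=dominance, qaly_tie=tie)


def icur_ladder(results: list[GroupResult], wtp: float) -> list[ComparisonResult]:
    """Dominance-ordered incremental ladder.

    Results are sorted ascending by QALYs (ties broken on cost, flagged) and
    each strategy is compared with its predecessor; input order is irrelevant.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies to compare")
    ordered = sorted(results, key=lambda r: (r.total_qaly, -r.total_cost))
    return [_compare(a, b, wtp) for a, b in zip(ordered[:-1], ordered[1:])]


def survival_summary(trace: CohortTrace, year: int) -> tuple[float, float]:
    """(overall survival, disease-free survival) fractions at the end of a year."""
    if year > trace.horizon:
        raise ValueError(f"year {year} beyond trace horizon {trace.horizon}")
    return float(trace.os_curve[year]), float(trace.dfs_curve[year])


def currency_convert(amount_inr: float, params: ParameterSet) -> float:
    """INR to US dollars at the configured average exchange rate."""
    return amount_inr / params.config.inr_per_usd


def results_table(results: dict[str, GroupResult], params: ParameterSet) -> pd.DataFrame:
    """Publication-style summary: per-strategy totals plus the incremental
    ladder (costs dual-reported in INR and USD; internal arithmetic unrounded,
    display rounded to whole currency units)."""
    wtp = params.config.wtp_threshold
    ladder = icur_ladder(list(results.values()), wtp)
    by_comp = {c.comparator_group: c for c in ladder}
    ordered = sorted(results.values(), key=lambda r: (r.total_qaly, -r.total_cost))
    rows = []
    for r in ordered:
        c = by_comp.get(r.group)
        rows.append({
            "group": r.group,
            "cost_inr": round(r.total_cost),
            "cost_usd": round(currency_convert(r.total_cost, params)),
            "ly": r.total_ly,
            "qaly": r.total_qaly,
            "incremental_cost_inr": round(c.delta_cost) if c else None,
            "incremental_qaly": c.delta_qaly if c else None,
            "icur_inr_per_qaly": (round(c.icur) if c and c.icur is not None
                                  else (c.dominance if c else None)),
            "inmb_inr": round(c.inmb) if c else None,
            "dominance": c.dominance if c else None,
        })
    return pd.DataFrame(rows)
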