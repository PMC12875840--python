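"""Discrete-time Markov cohort engine over six health states.

States: disease-free survival (DFS), loco-regional recurrence (LRR), salvage
after recurrence (SALVAGE), distant metastasis (DM), death from oral cancer
(DEATH_CANCER) and death from other causes (DEATH_OTHER).  The cohort enters
fully disease-free, distributed across the decision-tree strata of the chosen
strategy; each annual cycle applies competing exit probabilities (cancer
transitions plus age-banded all-cause mortality), accrues costs and
quality-adjusted time, and discounts both at the configured annual rate.

Half-cycle correction comes in two flavours, selected by
``config.half_cycle``:

``mid_cycle_discount``
    End-of-cycle state occupancy, discounted at mid-cycle ((1+r)^-(t-1/2)).
    This is the convention of the published analysis and the default.

``trapezoid``
    Life-table rule: per-cycle accrual uses the mean of start- and
    end-of-cycle occupancy, discounted at end-of-cycle.

Upfront surgical and adjuvant costs are charged at model entry (cycle 0),
undiscounted and outside the half-cycle correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet, TransitionTable
from .stratify import PathwayProfile, pathway_profiles

__all__ = [
    "STATES",
    "ModelState",
    "CohortTrace",
    "annual_from_cumulative",
    "annual_from_median_survival",
    "mortality_lookup",
    "transition_row",
    "run_cohort",
]

log = logging.getLogger(__name__)

STATES = ("DFS", "LRR", "SALVAGE", "DM", "DEATH_CANCER", "DEATH_OTHER")
_IDX = {s: i for i, s in enumerate(STATES)}
_N = len(STATES)


def annual_from_cumulative(cumulative_prob: float, years: float) -> float:
    """Annual transition probability from a cumulative probability over a period,
    assuming a constant hazard: 1 - (1 - P)^(1/years)."""
    if not (0 <= cumulative_prob < 1):
        raise ValueError(f"cumulative probability {cumulative_prob} must be in [0, 1)")
    if years <= 0:
        raise ValueError(f"years={years} must be > 0")
    return 1 - (1 - cumulative_prob) ** (1 / years)


def annual_from_median_survival(median_months: float) -> float:
    """Annual death probability implied by a median survival in months under an
    exponential survival assumption: 1 - 0.5^(12/median)."""
    if median_months <= 0:
        raise ValueError(f"median survival {median_months} months must be > 0")
    return 1 - 0.5 ** (12.0 / median_months)


_BAND_EDGES = ((55, "51-55"), (60, "56-60"), (65, "61-65"),
               (70, "66-70"), (75, "71-75"), (80, "76-80"))


def mortality_lookup(age: float, table: TransitionTable) -> float:
    """Annual all-cause mortality for an age, from the 5-year band table.

    Ages at or below the first band's lower edge use the first band; ages above
    80 use the open-ended band.  The published band values are used exactly as
    printed even where non-monotone in age.
    """
    if age < 0:
        raise ValueError(f"age={age} must be >= 0")
    for hi, band in _BAND_EDGES:
        if age <= hi:
            return table.all_cause_mortality[band]
    return table.all_cause_mortality["80+"]


@dataclass(frozen=True)
class ModelState:
    """Expanded model state: clinical state x pathway track x time in model."""

    clinical_state: str
    track: PathwayProfile
    years_in_model: int = 0


def transition_row(state: ModelState, params: ParameterSet) -> dict[str, float]:
    """One-cycle transition distribution out of an expanded state.

    Competing exits are additive; if cancer exits plus background mortality
    exceed 1 the row is renormalised (a warning is logged), which can only
    happen for extreme sampled parameter draws.
    """
    t = params.transitions
    age = params.config.median_age + state.years_in_model
    m = mortality_lookup(age, t)
    cs = state.clinical_state
    dis = state.track.dissected
    risk = state.track.recurrence_risk_class

    if cs in ("DEATH_CANCER", "DEATH_OTHER"):
        return {cs: 1.0}
    if cs == "DFS":
        lrr = t.dfs_to_lrr_node_pos if risk == "node_pos" else t.dfs_to_lrr_node_neg
        dm = t.dfs_to_dm_node_pos if risk == "node_pos" else t.dfs_to_dm_node_neg
        row = {"LRR": lrr, "DM": dm, "DEATH_OTHER": m}
    elif cs == "LRR":
        salv = t.lrr_to_salvage_dissected if dis else t.lrr_to_salvage_undissected
        row = {"DM": t.lrr_to_dm, "SALVAGE": salv,
               "DEATH_CANCER": t.lrr_to_death_cancer, "DEATH_OTHER": m}
    elif cs == "SALVAGE":
        lrr = t.salvage_to_lrr_dissected if dis else t.salvage_to_lrr_undissected
        dm = t.salvage_to_dm_dissected if dis else t.salvage_to_dm_undissected
        row = {"LRR": lrr, "DM": dm, "DEATH_OTHER": m}
    elif cs == "DM":
        row = {"DEATH_CANCER": annual_from_median_survival(t.dm_median_survival_months),
               "DEATH_OTHER": m}
    else:
        raise ValueError(f"unknown clinical state {cs!r}")

    total_exit = sum(row.values())
    if total_exit > 1:
        log.warning("exit probabilities from %s sum to %.4f > 1; renormalising", cs, total_exit)
        row = {k: v / total_exit for k, v in row.items()}
        total_exit = 1.0
    row[cs] = 1.0 - total_exit
    assert abs(sum(row.values()) - 1.0) < 1e-12
    return row


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted accruals for one strategy.

    ``membership`` has shape (n_strata, horizon+1, 6); per-cycle fractions are
    cohort-weighted across strata in ``occupancy``.  Accrual arrays are indexed
    by cycle (index 0 holds the upfront cost).
    """

    group: str
    strata: list[PathwayProfile]
    membership: np.ndarray
    accrued_cost: np.ndarray
    accrued_qaly: np.ndarray
    accrued_ly: np.ndarray
    half_cycle: str = "mid_cycle_discount"
    clip_events: int = 0

    @property
    def horizon(self) -> int:
        return self.membership.shape[1] - 1

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.strata])

    @property
    def occupancy(self) -> np.ndarray:
        """Cohort-level state occupancy, shape (horizon+1, 6)."""
        return np.einsum("s,stk->tk", self.weights, self.membership)

    @property
    def os_curve(self) -> np.ndarray:
        occ = self.occupancy
        return 1.0 - occ[:, _IDX["DEATH_CANCER"]] - occ[:, _IDX["DEATH_OTHER"]]

    @property
    def dfs_curve(self) -> np.ndarray:
        return self.occupancy[:, _IDX["DFS"]]

    @property
    def total_cost(self) -> float:
        return float(self.accrued_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.accrued_qaly.sum())

    @property
    def total_ly(self) -> float:
        return float(self.accrued_ly.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format trace: cycle, state, track, fraction, discounted accruals."""
        rows = []
        for s, prof in enumerate(self.strata):
            for t in range(self.horizon + 1):
                for k, st in enumerate(STATES):
                    frac = self.membership[s, t, k]
                    if frac > 0:
                        rows.append({"cycle": t, "state": st,
                                     "track": f"{prof.group}/{prof.stratum}",
                                     "fraction": prof.weight * frac})
        df = pd.DataFrame(rows)
        acc = pd.DataFrame({"cycle": np.arange(self.horizon + 1),
                            "discounted_cost": self.accrued_cost,
                            "discounted_qaly": self.accrued_qaly,
                            "discounted_ly": self.accrued_ly})
        return df.merge(acc, on="cycle")


def _state_utility(prof: PathwayProfile, params: ParameterSet, year: int) -> np.ndarray:
    """Utility vector over clinical states for one track in one model year."""
    u = params.utilities
    if prof.utility_track == "primary_resection_only":
        dfs_u = u.dfs_primary_resection
    elif year <= u.utility_window_years:
        dfs_u = u.mixed(prof.utility_track)
    else:
        dfs_u = u.dfs_after_neck_dissection
    return np.array([dfs_u, u.lrr, u.salvaged, u.dm, 0.0, 0.0])


def run_cohort(group: str, params: ParameterSet,
               horizon_years: int | str | None = None, *,
               prevalence: float | None = None,
               stratification: str = "npv") -> CohortTrace:
    """Run the cohort model for one strategy and return its trace.

    The cohort starts fully disease-free, split across the strategy's
    decision-tree strata.  Per cycle: state transitions (with age-updated
    background mortality), then accrual of life-years, utilities, state costs
    (follow-up investigation panels in DFS, supportive care in DM) and
    event costs (recurrence treatment on entry to LRR, salvage surgery on
    entry to SALVAGE), discounted per the half-cycle convention.
    """
    cfg = params.config
    if horizon_years is None:
        horizon = cfg.horizon_cycles()
    elif horizon_years == "lifetime":
        horizon = int(round(cfg.max_age - cfg.median_age))
    else:
        horizon = int(horizon_years)
    if horizon < 1:
        raise ValueError(f"horizon {horizon} must be >= 1")

    profiles = pathway_profiles(group, params, prevalence=prevalence,
                                stratification=stratification)
    n_s = len(profiles)
    rate = cfg.discount_rate
    c = params.costs
    lrr_cost = c.lrr_treatment()
    panel = c.followup_panel()
    trapezoid = cfg.half_cycle == "trapezoid"

    membership = np.zeros((n_s, horizon + 1, _N))
    cost = np.zeros(horizon + 1)
    qaly = np.zeros(horizon + 1)
    ly = np.zeros(horizon + 1)

    for s, prof in enumerate(profiles):
        membership[s, 0, _IDX["DFS"]] = 1.0
        cost[0] += prof.weight * prof.upfront_cost
        m = membership[s, 0].copy()
        for t in range(1, horizon + 1):
            rows = {cs: transition_row(ModelState(cs, prof, t - 1), params)
                    for cs in STATES[:4]}
            n = np.zeros(_N)
            for cs in STATES[:4]:
                for dest, p_ in rows[cs].items():
                    n[_IDX[dest]] += m[_IDX[cs]] * p_
            n[_IDX["DEATH_CANCER"]] += m[_IDX["DEATH_CANCER"]]
            n[_IDX["DEATH_OTHER"]] += m[_IDX["DEATH_OTHER"]]
            assert abs(n.sum() - 1.0) < 1e-10, "cohort mass not conserved"

            lrr_inflow = (m[_IDX["DFS"]] * rows["DFS"].get("LRR", 0.0)
                          + m[_IDX["SALVAGE"]] * rows["SALVAGE"].get("LRR", 0.0))
            salv_inflow = m[_IDX["LRR"]] * rows["LRR"].get("SALVAGE", 0.0)
            dm_inflow = sum(m[_IDX[cs]] * rows[cs].get("DM", 0.0) for cs in STATES[:3])

            if trapezoid:
                disc = (1 + rate) ** -t
                occ = (m + n) / 2
            else:
                disc = (1 + rate) ** -(t - 0.5)
                occ = n

            alive = occ[:4].sum()
            u_vec = _state_utility(prof, params, t)
            visits = c.followup_visits(t)
            state_cost = panel * visits * occ[_IDX["DFS"]]
            if cfg.dm_cost_per_cycle:
                state_cost += c.basic_supportive_care * occ[_IDX["DM"]]
            event_cost = lrr_cost * lrr_inflow + c.salvage_surgery * salv_inflow
            if not cfg.dm_cost_per_cycle:
                event_cost += c.basic_supportive_care * dm_inflow

            w = prof.weight
            ly[t] += w * disc * alive
            qaly[t] += w * disc * float(u_vec @ occ)
            cost[t] += w * disc * (state_cost + event_cost)

            membership[s, t] = n
            m = n

    return CohortTrace(group=group, strata=profiles, membership=membership,
                       accrued_cost=cost, accrued_qaly=qaly, accrued_ly=ly,
                       half_cycle=cfg.half_cycle)
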