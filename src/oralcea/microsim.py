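"""Individual-level Monte Carlo simulator used as a brute-force oracle for the
cohort engine, plus a randomised valid-parameter fixture generator.

The simulator draws each patient into a decision-tree stratum, then steps them
through the same annual transition structure as the cohort model, accruing
costs, life-years and QALYs per patient.  Transition assembly and accrual are
re-implemented here on purpose — sharing that code with the cohort engine
would make oracle-equivalence tests vacuous.  Only the parameter containers
and the decision-tree stratification (the common problem definition) are
shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (AnalysisConfig, CostTable, DiagnosticAccuracy,
                         DistributionSpec, ParameterSet, TransitionTable,
                         UtilityTable, table1_defaults, validate)
from .stratify import pathway_profiles, stratify_from_sens_npv

__all__ = ["MicrosimSummary", "simulate_patients", "random_parameter_fixture"]

# state codes (local to the microsim on purpose)
DFS, LRR, SALV, DM, DEAD_CA, DEAD_OTH = range(6)


@dataclass
class MicrosimSummary:
    """Per-patient means and Monte Carlo standard errors."""

    group: str
    n: int
    mean_cost: float
    mean_ly: float
    mean_qaly: float
    se_cost: float
    se_ly: float
    se_qaly: float
    occupancy: np.ndarray  # (horizon+1, 6) empirical state fractions


def _mortality(age: float, t: TransitionTable) -> float:
    for hi, band in ((55, "51-55"), (60, "56-60"), (65, "61-65"),
                     (70, "66-70"), (75, "71-75"), (80, "76-80")):
        if age <= hi:
            return t.all_cause_mortality[band]
    return t.all_cause_mortality["80+"]


def simulate_patients(group: str, params: ParameterSet, n: int, seed: int,
                      horizon_years: int | str | None = None) -> MicrosimSummary:
    """Simulate ``n`` individual patients through one strategy.

    Accrual mirrors the configured half-cycle convention: under the life-table
    rule each cycle credits the mean of the start- and end-of-cycle alive/state
    indicators (half credit in the transition cycle); under mid-cycle
    discounting the end-of-cycle state is credited at the mid-cycle discount
    factor.  Same seed, same summary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = params.config
    tr = params.transitions
    c = params.costs
    u = params.utilities
    if horizon_years is None:
        horizon = cfg.horizon_cycles()
    elif horizon_years == "lifetime":
        horizon = int(round(cfg.max_age - cfg.median_age))
    else:
        horizon = int(horizon_years)
    trapezoid = cfg.half_cycle == "trapezoid"
    rate = cfg.discount_rate

    profiles = pathway_profiles(group, params)
    weights = np.array([p.weight for p in profiles])
    strata = rng.choice(len(profiles), size=n, p=weights / weights.sum())

    dm_death = 1 - 0.5 ** (12.0 / tr.dm_median_survival_months)
    lrr_cost = c.lrr_treatment()
    panel = c.followup_panel()

    cost = np.array([profiles[s].upfront_cost for s in strata], dtype=float)
    ly = np.zeros(n)
    qaly = np.zeros(n)
    state = np.full(n, DFS, dtype=np.int8)
    occupancy = np.zeros((horizon + 1, 6))
    occupancy[0, DFS] = 1.0

    # per-stratum static attributes
    dissected = np.array([p.dissected for p in profiles])[strata]
    node_pos = np.array([p.recurrence_risk_class == "node_pos" for p in profiles])[strata]
    track = np.array([{"primary_resection_only": 0, "snd": 1, "mnd": 2}[p.utility_track]
                      for p in profiles])[strata]
    u_snd = u.mixed("snd")
    u_mnd = u.mixed("mnd")

    for t in range(1, horizon + 1):
        age = cfg.median_age + (t - 1)
        mort = _mortality(age, tr)
        prev = state.copy()
        draw = rng.random(n)

        def _scale(*probs: float) -> list[float]:
            # same guard as the cohort engine: proportional renormalisation
            total = sum(probs)
            return [p_ / total for p_ in probs] if total > 1 else list(probs)

        new = prev.copy()
        # DFS exits: recurrence, metastasis, background death
        for pos in (True, False):
            mask = (prev == DFS) & (node_pos == pos)
            p_lrr = tr.dfs_to_lrr_node_pos if pos else tr.dfs_to_lrr_node_neg
            p_dm = tr.dfs_to_dm_node_pos if pos else tr.dfs_to_dm_node_neg
            p_lrr, p_dm, m_ = _scale(p_lrr, p_dm, mort)
            d = draw[mask]
            dest = np.full(d.shape, DFS, dtype=np.int8)
            dest[d < p_lrr] = LRR
            dest[(d >= p_lrr) & (d < p_lrr + p_dm)] = DM
            dest[(d >= p_lrr + p_dm) & (d < p_lrr + p_dm + m_)] = DEAD_OTH
            new[mask] = dest
        for dis in (True, False):
            # LRR exits: metastasis, salvage surgery, cancer death, background death
            mask = (prev == LRR) & (dissected == dis)
            p_salv = tr.lrr_to_salvage_dissected if dis else tr.lrr_to_salvage_undissected
            edges = np.cumsum(_scale(tr.lrr_to_dm, p_salv, tr.lrr_to_death_cancer, mort))
            d = draw[mask]
            dest = np.full(d.shape, LRR, dtype=np.int8)
            dest[d < edges[0]] = DM
            dest[(d >= edges[0]) & (d < edges[1])] = SALV
            dest[(d >= edges[1]) & (d < edges[2])] = DEAD_CA
            dest[(d >= edges[2]) & (d < edges[3])] = DEAD_OTH
            new[mask] = dest
            # salvage exits: re-recurrence, metastasis, background death
            mask = (prev == SALV) & (dissected == dis)
            p_lrr = tr.salvage_to_lrr_dissected if dis else tr.salvage_to_lrr_undissected
            p_dm = tr.salvage_to_dm_dissected if dis else tr.salvage_to_dm_undissected
            p_lrr, p_dm, m_ = _scale(p_lrr, p_dm, mort)
            d = draw[mask]
            dest = np.full(d.shape, SALV, dtype=np.int8)
            dest[d < p_lrr] = LRR
            dest[(d >= p_lrr) & (d < p_lrr + p_dm)] = DM
            dest[(d >= p_lrr + p_dm) & (d < p_lrr + p_dm + m_)] = DEAD_OTH
            new[mask] = dest
        mask = prev == DM
        p_ca, m_ = _scale(dm_death, mort)
        d = draw[mask]
        dest = np.full(d.shape, DM, dtype=np.int8)
        dest[d < p_ca] = DEAD_CA
        dest[(d >= p_ca) & (d < p_ca + m_)] = DEAD_OTH
        new[mask] = dest

        state = new
        counts = np.bincount(state, minlength=6)
        occupancy[t] = counts / n

        # accrual
        if trapezoid:
            disc = (1 + rate) ** -t
            w_prev, w_new = 0.5, 0.5
        else:
            disc = (1 + rate) ** -(t - 0.5)
            w_prev, w_new = 0.0, 1.0

        if t <= u.utility_window_years:
            dfs_u = np.choose(track, [u.dfs_primary_resection, u_snd, u_mnd])
        else:
            dfs_u = np.where(track == 0, u.dfs_primary_resection, u.dfs_after_neck_dissection)
        util = np.zeros((n, 6))
        util[:, DFS] = dfs_u
        util[:, LRR] = u.lrr
        util[:, SALV] = u.salvaged
        util[:, DM] = u.dm
        idx = np.arange(n)
        qaly += disc * (w_prev * util[idx, prev] + w_new * util[idx, state])
        ly += disc * (w_prev * (prev < DEAD_CA) + w_new * (state < DEAD_CA))

        visits = c.followup_visits(t)
        state_cost = (panel * visits * (w_prev * (prev == DFS) + w_new * (state == DFS)))
        if cfg.dm_cost_per_cycle:
            state_cost = state_cost + c.basic_supportive_care * (
                w_prev * (prev == DM) + w_new * (state == DM))
        entered_lrr = (state == LRR) & (prev != LRR)
        entered_salv = (state == SALV) & (prev != SALV)
        event_cost = lrr_cost * entered_lrr + c.salvage_surgery * entered_salv
        if not cfg.dm_cost_per_cycle:
            event_cost = event_cost + c.basic_supportive_care * ((state == DM) & (prev != DM))
        cost += disc * (state_cost + event_cost)

    def mse(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    (mc, sc), (ml, sl), (mq, sq) = mse(cost), mse(ly), mse(qaly)
    return MicrosimSummary(group=group, n=n, mean_cost=mc, mean_ly=ml,
                           mean_qaly=mq, se_cost=sc, se_ly=sl, se_qaly=sq,
                           occupancy=occupancy)


def random_parameter_fixture(seed: int) -> ParameterSet:
    """A randomised but internally valid parameter set for property tests.

    Probabilities land in [0.01, 0.6] with row sums leaving room to stay,
    utilities keep the with-morbidity <= without-morbidity ordering, costs are
    positive, and the diagnostic triple is feasible (resampled otherwise).
    Every sampled parameter keeps a distribution spec (+/-20% bounds around
    the drawn mean) so sensitivity analyses run on fixtures too.
    """
    rng = np.random.default_rng(seed)

    def p(lo: float = 0.01, hi: float = 0.6) -> float:
        return float(rng.uniform(lo, hi))

    for _ in range(100):
        prevalence = p(0.05, 0.5)
        se = p(0.6, 0.95)
        npv = p(0.7, 0.99)
        try:
            stratify_from_sens_npv(prevalence, se, npv)
            break
        except ValueError:
            continue

    snd_wo = p(0.6, 0.95)
    mnd_wo = p(0.55, snd_wo)
    utilities = UtilityTable(
        dfs_primary_resection=p(snd_wo, 0.98),
        dfs_after_neck_dissection=p(0.55, snd_wo),
        snd_without_morbidity=snd_wo,
        snd_with_morbidity=snd_wo - p(0.02, 0.15),
        mnd_without_morbidity=mnd_wo,
        mnd_with_morbidity=mnd_wo - p(0.02, 0.15),
        lrr=p(0.4, 0.7),
        dm=p(0.3, 0.6),
        salvaged=p(0.2, 0.5),
        morbidity_weight=p(0.05, 0.4),
    )

    def row(k: int, budget: float = 0.8) -> list[float]:
        # k exit probabilities summing well below 1 so that adding background
        # mortality (capped at 0.1 below) never overflows the row
        raw = rng.uniform(0.01, 0.6, size=k)
        return list(raw * budget * rng.uniform(0.3, 1.0) / raw.sum())

    dfs_pos = row(2)
    dfs_neg = row(2)
    lrr_d = row(3)
    lrr_u_salv = p(0.02, 0.8 - lrr_d[0] - lrr_d[2])
    salv_d = row(2)
    salv_u = row(2)
    transitions = TransitionTable(
        dfs_to_lrr_node_pos=dfs_pos[0], dfs_to_dm_node_pos=dfs_pos[1],
        dfs_to_lrr_node_neg=dfs_neg[0], dfs_to_dm_node_neg=dfs_neg[1],
        lrr_to_dm=lrr_d[0], lrr_to_salvage_dissected=lrr_d[1],
        lrr_to_salvage_undissected=lrr_u_salv, lrr_to_death_cancer=lrr_d[2],
        salvage_to_lrr_dissected=salv_d[0], salvage_to_dm_dissected=salv_d[1],
        salvage_to_lrr_undissected=salv_u[0], salvage_to_dm_undissected=salv_u[1],
        dm_median_survival_months=float(rng.uniform(6, 24)),
        all_cause_mortality={band: p(0.005, 0.1) for band in
                             ("51-55", "56-60", "61-65", "66-70", "71-75", "76-80", "80+")},
    )

    def cost(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    costs = CostTable(
        slnb=cost(5e3, 5e4), mnd=cost(1e4, 6e4), snd=cost(1e4, 5e4),
        salvage_surgery=cost(2e4, 1e5), frozen_section=cost(1e3, 2e4),
        rt_2d=cost(5e3, 3e4), rt_3dcrt=cost(1e4, 5e4), rt_imrt=cost(3e4, 1.5e5),
        cisplatin_weekly=cost(1e3, 6e3), cisplatin_high=cost(5e3, 2e4),
        paclitaxel=cost(5e3, 3e4), paclitaxel_carboplatin=cost(5e3, 3e4),
        basic_supportive_care=cost(3e3, 2e4), high_end_radiology=cost(1e3, 1e4),
        cbc=cost(50, 500), lft=cost(50, 500), rft=cost(50, 500),
        electrolytes=cost(50, 800), tsh=cost(50, 300),
        adjuvant_chemo_fraction=p(0.1, 0.9),
        rt_modality_weights=tuple((w := rng.dirichlet([2, 2, 2])).tolist()),
        lrr_salvage_fraction=p(0.1, 0.9),
    )
    config = AnalysisConfig(
        occult_metastasis_rate=prevalence,
        discount_rate=float(rng.uniform(0.0, 0.05)),
        half_cycle=str(rng.choice(["mid_cycle_discount", "trapezoid"])),
    )
    base = table1_defaults()
    fixture = ParameterSet(
        accuracy_slnb=DiagnosticAccuracy(sensitivity=se, npv=npv),
        accuracy_endfs=DiagnosticAccuracy(sensitivity=p(0.6, 0.95), npv=npv),
        utilities=utilities,
        transitions=transitions,
        costs=costs,
        config=config,
        distributions={},
    )
    dists: dict[str, DistributionSpec] = {}
    for name, spec in base.distributions.items():
        mean = fixture.get_path(name)
        if spec.family == "fixed":
            dists[name] = DistributionSpec("fixed", mean)
            continue
        lo, hi = mean * 0.8, mean * 1.2
        if spec.family in ("beta", "dirichlet"):
            hi = min(hi, 1.0)
        dists[name] = DistributionSpec(spec.family, mean, lo, hi)
    fixture.distributions = dists
    violations = validate(fixture)
    assert not violations, f"fixture generator produced violations: {violations}"
    return fixture
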