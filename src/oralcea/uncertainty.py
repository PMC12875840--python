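"""Sensitivity analyses: one-way deterministic (tornado), probabilistic
(Monte Carlo over the parameter distributions), cost-effectiveness
acceptability curves, and threshold analysis on the occult-metastasis rate.

Distribution fitting is method-of-moments with the standard deviation taken
from the 95% interval as (high - low)/3.92 (normal-theory interval).  Beta and
gamma parameters follow from matching mean and sd; transition rows are drawn
jointly from a Dirichlet whose concentration is proportional to the row means,
scaled so the marginal standard deviations match the interval-implied ones on
average.  Parameters are otherwise sampled independently (no cost-utility
correlation is imposed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outcomes import run_group
from .parameters import DistributionSpec, ParameterSet
from .stratify import GROUPS

__all__ = [
    "TornadoEntry",
    "ThresholdResult",
    "fit_distribution",
    "fit_dirichlet_row",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "one_way_dsa",
    "threshold_sweep",
    "DIRICHLET_ROWS",
]

log = logging.getLogger(__name__)

Z95 = 3.92  # width of a normal-theory 95% interval in standard deviations

#: Transition rows sampled jointly (components share a Dirichlet with the
#: implicit stay-probability remainder).  The loco-regional recurrence rows for
#: dissected and undissected necks share the progression and cancer-death
#: components; the undissected row contributes only its salvage rate.
DIRICHLET_ROWS: dict[str, list[str]] = {
    "dfs_node_pos": ["transitions.dfs_to_lrr_node_pos", "transitions.dfs_to_dm_node_pos"],
    "dfs_node_neg": ["transitions.dfs_to_lrr_node_neg", "transitions.dfs_to_dm_node_neg"],
    "lrr_dissected": ["transitions.lrr_to_dm", "transitions.lrr_to_salvage_dissected",
                      "transitions.lrr_to_death_cancer"],
    "lrr_undissected": ["transitions.lrr_to_salvage_undissected"],
    "salvage_dissected": ["transitions.salvage_to_lrr_dissected",
                          "transitions.salvage_to_dm_dissected"],
    "salvage_undissected": ["transitions.salvage_to_lrr_undissected",
                            "transitions.salvage_to_dm_undissected"],
}


def _ci_sd(spec: DistributionSpec) -> float:
    if spec.low is None or spec.high is None:
        raise ValueError(f"distribution {spec} has no interval bounds")
    sd = (spec.high - spec.low) / Z95
    if sd <= 0:
        raise ValueError(f"non-positive sd implied by bounds ({spec.low}, {spec.high})")
    return sd


class Sampler:
    """A fitted marginal distribution; call ``draw`` with a Generator.

    The method-of-moments fit is exposed in ``fitted`` (e.g. alpha/beta for a
    beta, shape/scale for a gamma, mean/sd for a normal).
    """

    def __init__(self, spec: DistributionSpec):
        self.spec = spec
        fam, m = spec.family, spec.mean
        if fam == "fixed":
            self.fitted = {"value": m}
            self.draw = lambda rng: m
            return
        sd = _ci_sd(spec)
        if fam in ("beta", "dirichlet"):
            # marginal of a Dirichlet cell is beta; standalone fit is the same
            if not (0 < m < 1):
                raise ValueError(f"beta mean {m} outside (0, 1)")
            nu = m * (1 - m) / sd**2 - 1
            if nu <= 0:
                raise ValueError(f"interval too wide for a beta at mean {m}")
            a, b = m * nu, (1 - m) * nu
            self.fitted = {"alpha": a, "beta": b, "sd": sd}
            self.draw = lambda rng: float(rng.beta(a, b))
        elif fam == "gamma":
            shape = (m / sd) ** 2
            scale = sd**2 / m
            self.fitted = {"shape": shape, "scale": scale, "sd": sd}
            self.draw = lambda rng: float(rng.gamma(shape, scale))
        elif fam == "normal":
            self.fitted = {"mean": m, "sd": sd}
            self.draw = lambda rng: float(rng.normal(m, sd))
        else:
            raise ValueError(f"unknown family {fam!r}")


def fit_distribution(spec: DistributionSpec) -> Sampler:
    """Method-of-moments sampler for a distribution spec (sd = CI width / 3.92)."""
    return Sampler(spec)


def fit_dirichlet_row(means: list[float], sds: list[float]) -> np.ndarray:
    """Dirichlet concentration for a transition row.

    Cells are the listed exit probabilities plus the stay remainder; the
    common concentration scale is the average of the per-cell scales
    m(1-m)/sd^2 - 1 implied by the interval bounds.
    """
    means = np.asarray(means, dtype=float)
    rem = 1.0 - means.sum()
    if rem < 0:
        raise ValueError(f"row means sum to {means.sum()} > 1")
    # marginal sd of cell i is sqrt(m_i (1-m_i) / (c+1)); choose c so the
    # cell-average marginal sd equals the cell-average interval-implied sd
    target = float(np.mean(sds))
    spread = float(np.mean(np.sqrt(means * (1 - means))))
    c = (spread / target) ** 2 - 1
    if c <= 0:
        raise ValueError("interval widths too large for a Dirichlet fit")
    return c * np.append(means, rem)


def sample_parameter_set(params: ParameterSet, seed: int | np.random.Generator) -> ParameterSet:
    """One joint draw of all uncertain parameters.

    Fixed parameters never vary; transition rows are drawn jointly per
    Dirichlet row; all other parameters are drawn independently from their
    fitted distributions.  Draws falling outside [0, 1] (probabilities) or
    below 0 (costs) are clipped with a logged count.  Identical seeds yield
    identical parameter sets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = params.copy()
    clipped = 0
    in_rows = {path for paths in DIRICHLET_ROWS.values() for path in paths}

    for name in sorted(params.distributions):
        spec = params.distributions[name]
        if spec.family == "fixed" or name in in_rows:
            continue
        val = fit_distribution(spec).draw(rng)
        if spec.family in ("beta", "dirichlet"):
            newval = min(max(val, 0.0), 1.0)
        else:
            newval = max(val, 0.0)
        if newval != val:
            clipped += 1
        out.set_path(name, newval)

    for row_name in sorted(DIRICHLET_ROWS):
        paths = DIRICHLET_ROWS[row_name]
        specs = [params.distributions[p] for p in paths]
        if any(s.family == "fixed" for s in specs):
            continue  # degenerate row: stays at its means
        alpha = fit_dirichlet_row([s.mean for s in specs], [_ci_sd(s) for s in specs])
        draw = rng.dirichlet(alpha)
        for path, val in zip(paths, draw[:-1]):
            out.set_path(path, float(val))

    if clipped:
        log.info("clipped %d out-of-range parameter draws", clipped)
    return out


def run_psa(params: ParameterSet, comparisons: list[tuple[str, str]],
            n_iterations: int, seed: int,
            horizon_years: int | str | None = None) -> pd.DataFrame:
    """Probabilistic sensitivity analysis.

    Each iteration redraws the full parameter set, re-runs all three
    strategies (with re-stratification under the sampled prevalence and
    accuracies) and records the incremental cost and QALYs for every requested
    (reference, comparator) pair.  Reproducible under ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    groups_needed = sorted({g for pair in comparisons for g in pair})
    children = np.random.SeedSequence(seed).spawn(n_iterations)
    records = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        drawn = sample_parameter_set(params, rng)
        results = {g: run_group(g, drawn, horizon_years) for g in groups_needed}
        for ref, comp in comparisons:
            records.append({
                "iteration": i,
                "comparison": f"{comp} vs {ref}",
                "delta_cost": results[comp].total_cost - results[ref].total_cost,
                "delta_qaly": results[comp].total_qaly - results[ref].total_qaly,
            })
    return pd.DataFrame(records)


def ceac(points: pd.DataFrame, wtp_grid: list[float] | np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve(s) from a PSA point cloud.

    At each willingness-to-pay the probability of cost-effectiveness is the
    fraction of iterations with positive incremental net monetary benefit.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if len(points) == 0:
        raise ValueError("empty PSA point cloud")
    rows = []
    for comp, sub in points.groupby("comparison", sort=True):
        dq = sub["delta_qaly"].to_numpy()
        dc = sub["delta_cost"].to_numpy()
        for w in wtp_grid:
            rows.append({"comparison": comp, "wtp": w,
                         "probability_cost_effective": float(np.mean(w * dq - dc > 0))})
    return pd.DataFrame(rows)


@dataclass
class TornadoEntry:
    parameter: str
    low_icur: float
    high_icur: float

    @property
    def spread(self) -> float:
        return abs(self.high_icur - self.low_icur)


def _raw_icer(params: ParameterSet, comparison: tuple[str, str],
              horizon_years: int | str | None = None) -> float:
    ref, comp = comparison
    a = run_group(ref, params, horizon_years)
    b = run_group(comp, params, horizon_years)
    dq = b.total_qaly - a.total_qaly
    dc = b.total_cost - a.total_cost
    return dc / dq if dq != 0 else math.inf


def one_way_dsa(params: ParameterSet, comparison: tuple[str, str] = ("III", "I"),
                horizon_years: int | str | None = None) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis.

    Each uncertain parameter is set in turn to its interval bounds (all others
    at base) and the ICUR of the comparison recomputed; entries are returned
    sorted by spread, largest first (tornado order).  Ratios are reported raw
    (they may cross zero for draws that flip the incremental ordering).
    """
    entries = []
    for name in sorted(params.distributions):
        spec = params.distributions[name]
        if spec.family == "fixed":
            continue
        low = spec.low if spec.low is not None else spec.mean * 0.8
        high = spec.high if spec.high is not None else spec.mean * 1.2
        icurs = []
        for bound in (low, high):
            varied = params.copy()
            varied.set_path(name, bound)
            icurs.append(_raw_icer(varied, comparison, horizon_years))
        entries.append(TornadoEntry(parameter=name, low_icur=icurs[0], high_icur=icurs[1]))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


@dataclass
class ThresholdResult:
    parameter: str
    comparison: tuple[str, str]
    wtp: float
    breakpoint: float | None     # None = never cost-effective on the grid
    grid_step: float
    curve: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        bp = "none on grid" if self.breakpoint is None else f"{self.breakpoint:.2f}"
        return (f"threshold({self.parameter}, {self.comparison[1]} vs "
                f"{self.comparison[0]}, wtp={self.wtp:.0f}): breakpoint {bp} "
                f"(grid step {self.grid_step:g})")


def threshold_sweep(params: ParameterSet, parameter_name: str,
                    grid: np.ndarray | list[float],
                    comparison: tuple[str, str] = ("III", "I"),
                    wtp: float | None = None,
                    horizon_years: int | str | None = None,
                    stratification: str = "specificity") -> ThresholdResult:
    """Largest parameter value at which the comparator remains cost-effective.

    For ``occult_metastasis_rate`` the diagnostic 2x2 tables are re-derived at
    every grid value.  Holding the published sensitivity and NPV fixed across
    prevalence makes the table infeasible above a moderate rate (NPV falls
    with prevalence for any fixed test), so the sweep instead holds sensitivity
    and the base-case implied specificity (``stratification="specificity"``,
    the default); ``"npv"`` reproduces the fixed-NPV variant with the implied
    true-negative fraction capped at feasibility.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if wtp is None:
        wtp = params.config.wtp_threshold
    ref, comp = comparison
    is_prevalence = parameter_name in ("occult_metastasis_rate",
                                       "config.occult_metastasis_rate")
    rows = []
    breakpoint_ = None
    for value in grid:
        if is_prevalence:
            kw = dict(prevalence=float(value), stratification=stratification)
            a = run_group(ref, params, horizon_years, **kw)
            b = run_group(comp, params, horizon_years, **kw)
        else:
            varied = params.copy()
            varied.set_path(parameter_name, float(value))
            a = run_group(ref, varied, horizon_years)
            b = run_group(comp, varied, horizon_years)
        dq = b.total_qaly - a.total_qaly
        dc = b.total_cost - a.total_cost
        icur = dc / dq if dq != 0 else math.inf
        ce = dq > 0 and (dc <= 0 or icur <= wtp)
        if ce:
            breakpoint_ = float(value)
        rows.append({"value": float(value), "delta_cost": dc, "delta_qaly": dq,
                     "icur": icur, "cost_effective": ce})
    step = float(np.min(np.diff(grid))) if grid.size > 1 else 0.0
    return ThresholdResult(parameter=parameter_name, comparison=comparison,
                           wtp=float(wtp), breakpoint=breakpoint_,
                           grid_step=step, curve=pd.DataFrame(rows))
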