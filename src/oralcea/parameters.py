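"""Model parameter space: types, canonical defaults, validation, and (de)serialisation.

The model is parameterised by four blocks — diagnostic accuracy of the two
intraoperative tests, health-state utilities, annual transition probabilities,
and payer-perspective costs in Indian rupees (INR) — plus an analysis
configuration (discount rate, horizon, willingness-to-pay threshold, etc.).
Every uncertain parameter carries a distribution specification (family and
95% interval bounds) used by the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

__all__ = [
    "DistributionSpec",
    "DiagnosticAccuracy",
    "UtilityTable",
    "TransitionTable",
    "CostTable",
    "AnalysisConfig",
    "ParameterSet",
    "Violation",
    "ParameterValidationError",
    "table1_defaults",
    "load_parameter_set",
    "save_parameter_set",
    "validate",
]

FAMILIES = ("beta", "gamma", "normal", "dirichlet", "fixed")

#: Age bands of the all-cause mortality table (band label -> inclusive upper age).
MORTALITY_BANDS = ("51-55", "56-60", "61-65", "66-70", "71-75", "76-80", "80+")


@dataclass
class DistributionSpec:
    """Distribution family with base estimate and 95% interval bounds."""

    family: str
    mean: float
    low: float | None = None
    high: float | None = None
    #: bounds as originally published, when the working bounds were repaired
    printed_bounds: tuple[float, float] | None = None

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"family": self.family, "mean": self.mean}
        if self.low is not None:
            d["low"] = self.low
        if self.high is not None:
            d["high"] = self.high
        if self.printed_bounds is not None:
            d["printed_bounds"] = list(self.printed_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DistributionSpec":
        pb = d.get("printed_bounds")
        return cls(
            family=d["family"],
            mean=d["mean"],
            low=d.get("low"),
            high=d.get("high"),
            printed_bounds=tuple(pb) if pb is not None else None,
        )


@dataclass
class DiagnosticAccuracy:
    """Sensitivity and negative predictive value of an intraoperative nodal test."""

    sensitivity: float
    npv: float


@dataclass
class UtilityTable:
    """Health-state utility weights (EQ-5D-5L scale, anchored 0=dead, 1=full health).

    Patients spared a neck dissection keep the post-resection utility; dissected
    patients carry a procedure-specific utility (selective vs modified neck
    dissection, mixed between the with- and without-shoulder-morbidity values by
    ``morbidity_weight``) for ``utility_window_years`` years, after which the
    generic post-neck-dissection utility applies.
    """

    dfs_primary_resection: float
    dfs_after_neck_dissection: float
    snd_without_morbidity: float
    snd_with_morbidity: float
    mnd_without_morbidity: float
    mnd_with_morbidity: float
    lrr: float
    dm: float
    salvaged: float
    morbidity_weight: float = 0.17
    utility_window_years: int = 5

    def mixed(self, procedure: str) -> float:
        """Morbidity-weighted utility for 'snd' or 'mnd'."""
        w = self.morbidity_weight
        if procedure == "snd":
            return w * self.snd_with_morbidity + (1 - w) * self.snd_without_morbidity
        if procedure == "mnd":
            return w * self.mnd_with_morbidity + (1 - w) * self.mnd_without_morbidity
        raise ValueError(f"unknown procedure {procedure!r}")


@dataclass
class TransitionTable:
    """Annual transition probabilities between the six health states.

    Recurrence hazards from disease-free survival depend on final nodal status
    (``node_pos``/``node_neg``); loco-regional recurrence and salvage dynamics
    depend on whether the neck was dissected at primary treatment.  All-cause
    mortality is an age-band lookup added to every alive state.
    """

    dfs_to_lrr_node_pos: float
    dfs_to_lrr_node_neg: float
    dfs_to_dm_node_pos: float
    dfs_to_dm_node_neg: float
    lrr_to_dm: float
    lrr_to_salvage_dissected: float
    lrr_to_salvage_undissected: float
    lrr_to_death_cancer: float
    salvage_to_lrr_dissected: float
    salvage_to_lrr_undissected: float
    salvage_to_dm_dissected: float
    salvage_to_dm_undissected: float
    dm_median_survival_months: float
    all_cause_mortality: dict[str, float] = field(default_factory=dict)


@dataclass
class CostTable:
    """Procedure and investigation costs (INR) plus treatment-mix weights.

    The mix weights are not published inputs; they are calibration knobs that
    allocate adjuvant/recurrence treatment between modalities and set the
    follow-up investigation schedule (panel-visits per year while disease-free).
    """

    slnb: float
    mnd: float
    snd: float
    salvage_surgery: float
    frozen_section: float
    rt_2d: float
    rt_3dcrt: float
    rt_imrt: float
    cisplatin_weekly: float
    cisplatin_high: float
    paclitaxel: float
    paclitaxel_carboplatin: float
    basic_supportive_care: float
    high_end_radiology: float
    cbc: float
    lft: float
    rft: float
    electrolytes: float
    tsh: float
    # treatment-mix calibration knobs
    adjuvant_chemo_fraction: float = 0.5
    chemo_cycles: int = 6
    rt_modality_weights: tuple[float, float, float] = (0.1, 0.6, 0.3)
    lrr_salvage_fraction: float = 0.5
    #: follow-up panel-visits per model year: year 1, years 2-5, thereafter
    followup_visits_year1: int = 3
    followup_visits_years2_5: int = 2
    followup_visits_after: int = 1

    def rt_bundle(self) -> float:
        """Cost of one radiotherapy course averaged over delivery modalities."""
        w2d, w3d, wimrt = self.rt_modality_weights
        return w2d * self.rt_2d + w3d * self.rt_3dcrt + wimrt * self.rt_imrt

    def adjuvant_bundle(self) -> float:
        """Radiotherapy with-or-without concurrent weekly cisplatin."""
        return self.rt_bundle() + self.adjuvant_chemo_fraction * self.cisplatin_weekly * self.chemo_cycles

    def lrr_treatment(self) -> float:
        """Expected cost on entering loco-regional recurrence: salvage surgery
        or (chemo)radiation, mixed by ``lrr_salvage_fraction``."""
        return (self.lrr_salvage_fraction * self.salvage_surgery
                + (1 - self.lrr_salvage_fraction) * self.adjuvant_bundle())

    def followup_panel(self) -> float:
        """One follow-up investigation panel: CBC, LFT, RFT, electrolytes, TSH
        and a high-end radiological investigation."""
        return self.cbc + self.lft + self.rft + self.electrolytes + self.tsh + self.high_end_radiology

    def followup_visits(self, year: int) -> int:
        if year <= 1:
            return self.followup_visits_year1
        if year <= 5:
            return self.followup_visits_years2_5
        return self.followup_visits_after


@dataclass
class AnalysisConfig:
    """Analysis-level settings (payer perspective, annual cycles)."""

    median_age: float = 50.0
    occult_metastasis_rate: float = 0.23
    discount_rate: float = 0.03
    horizon_years: int | str = "lifetime"
    wtp_threshold: float = 211_725.0
    psa_iterations: int = 1000
    rng_seed: int = 20_24
    inr_per_usd: float = 83.68
    cycle_length_years: float = 1.0
    max_age: float = 100.0
    #: half-cycle correction variant: 'mid_cycle_discount' counts end-of-cycle
    #: occupancy discounted at mid-cycle; 'trapezoid' is the life-table rule.
    half_cycle: str = "mid_cycle_discount"
    #: completion modified neck dissection for occult-positive patients who had
    #: only a selective dissection upfront (second admission)
    group2_completion_mnd: bool = True
    #: whether frozen-section false negatives in the elective-dissection-with-FS
    #: arm return for completion modified neck dissection
    group3_fn_completion_mnd: bool = False
    #: supportive care in distant metastasis: per-cycle if True, one-off if False
    dm_cost_per_cycle: bool = True

    def horizon_cycles(self) -> int:
        if self.horizon_years == "lifetime":
            return int(round(self.max_age - self.median_age))
        return int(self.horizon_years)


@dataclass
class ParameterSet:
    """Full parameter space for one analysis."""

    accuracy_slnb: DiagnosticAccuracy
    accuracy_endfs: DiagnosticAccuracy
    utilities: UtilityTable
    transitions: TransitionTable
    costs: CostTable
    config: AnalysisConfig
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    # -- attribute-path access used by sampling and one-way sensitivity
    #    analysis; dict entries addressed as "transitions.all_cause_mortality[80+]"
    def get_path(self, path: str) -> float:
        path, key = _split_key(path)
        obj: Any = self
        for part in path.split("."):
            obj = getattr(obj, part)
        return obj[key] if key is not None else obj

    def set_path(self, path: str, value: float) -> None:
        path, key = _split_key(path)
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            obj = getattr(obj, part)
        if key is not None:
            getattr(obj, parts[-1])[key] = value
        else:
            setattr(obj, parts[-1], value)

    def copy(self) -> "ParameterSet":
        import copy as _copy

        return _copy.deepcopy(self)

    def to_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "accuracy": {
                "slnb": enc(self.accuracy_slnb),
                "endfs": enc(self.accuracy_endfs),
            },
            "utilities": enc(self.utilities),
            "transitions": enc(self.transitions),
            "costs": enc(self.costs),
            "config": enc(self.config),
            "distributions": {k: v.to_dict() for k, v in self.distributions.items()},
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ParameterSet":
        top_keys = {"accuracy", "utilities", "transitions", "costs", "config", "distributions"}
        unknown = set(data) - top_keys
        if unknown:
            raise ParameterValidationError(
                [Violation("<top-level>", sorted(unknown), "unknown top-level keys")]
            )
        missing = top_keys - set(data)
        if missing:
            raise ParameterValidationError(
                [Violation("<top-level>", sorted(missing), "missing required sections")]
            )

        def build(klass: type, d: dict[str, Any], section: str) -> Any:
            fields = {f.name: f for f in dataclasses.fields(klass)}
            unknown = set(d) - set(fields)
            if unknown:
                raise ParameterValidationError(
                    [Violation(f"{section}.{k}", d[k], "unknown field") for k in sorted(unknown)]
                )
            required = {
                name for name, f in fields.items()
                if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING
            }
            missing = required - set(d)
            if missing:
                raise ParameterValidationError(
                    [Violation(f"{section}.{k}", None, "missing required field") for k in sorted(missing)]
                )
            kwargs = dict(d)
            for name, f in fields.items():
                if name in kwargs and isinstance(kwargs[name], list) and "tuple" in str(f.type):
                    kwargs[name] = tuple(kwargs[name])
            return klass(**kwargs)

        return cls(
            accuracy_slnb=build(DiagnosticAccuracy, data["accuracy"]["slnb"], "accuracy.slnb"),
            accuracy_endfs=build(DiagnosticAccuracy, data["accuracy"]["endfs"], "accuracy.endfs"),
            utilities=build(UtilityTable, data["utilities"], "utilities"),
            transitions=build(TransitionTable, data["transitions"], "transitions"),
            costs=build(CostTable, data["costs"], "costs"),
            config=build(AnalysisConfig, data["config"], "config"),
            distributions={k: DistributionSpec.from_dict(v) for k, v in data["distributions"].items()},
        )


def _split_key(path: str) -> tuple[str, str | None]:
    if path.endswith("]") and "[" in path:
        head, key = path[:-1].split("[", 1)
        return head, key
    return path, None


@dataclass(frozen=True)
class Violation:
    """A single invariant violation: which field, the offending value, the rule."""

    field: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r}: {self.rule}"


class ParameterValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


def _iter_probability_fields(params: ParameterSet) -> Iterator[tuple[str, float]]:
    t = params.transitions
    for name in (
        "dfs_to_lrr_node_pos", "dfs_to_lrr_node_neg", "dfs_to_dm_node_pos",
        "dfs_to_dm_node_neg", "lrr_to_dm", "lrr_to_salvage_dissected",
        "lrr_to_salvage_undissected", "lrr_to_death_cancer",
        "salvage_to_lrr_dissected", "salvage_to_lrr_undissected",
        "salvage_to_dm_dissected", "salvage_to_dm_undissected",
    ):
        yield f"transitions.{name}", getattr(t, name)
    for band, p in t.all_cause_mortality.items():
        yield f"transitions.all_cause_mortality[{band}]", p


def validate(params: ParameterSet) -> list[Violation]:
    """Check every type invariant; return violations instead of raising.

    Total on structurally well-formed input: any numeric nonsense is reported,
    never thrown.
    """
    v: list[Violation] = []

    def prob(name: str, x: float, lo_open: bool = False) -> None:
        ok = (0 < x <= 1) if lo_open else (0 <= x <= 1)
        if not ok:
            rng = "(0, 1]" if lo_open else "[0, 1]"
            v.append(Violation(name, x, f"must be in {rng}"))

    prob("accuracy_slnb.sensitivity", params.accuracy_slnb.sensitivity, lo_open=True)
    prob("accuracy_slnb.npv", params.accuracy_slnb.npv, lo_open=True)
    prob("accuracy_endfs.sensitivity", params.accuracy_endfs.sensitivity, lo_open=True)
    prob("accuracy_endfs.npv", params.accuracy_endfs.npv, lo_open=True)

    u = params.utilities
    for name in ("dfs_primary_resection", "dfs_after_neck_dissection",
                 "snd_without_morbidity", "snd_with_morbidity",
                 "mnd_without_morbidity", "mnd_with_morbidity",
                 "lrr", "dm", "salvaged", "morbidity_weight"):
        prob(f"utilities.{name}", getattr(u, name))
    if u.snd_with_morbidity > u.snd_without_morbidity:
        v.append(Violation("utilities.snd_with_morbidity", u.snd_with_morbidity,
                           f"must be <= snd_without_morbidity ({u.snd_without_morbidity})"))
    if u.mnd_with_morbidity > u.mnd_without_morbidity:
        v.append(Violation("utilities.mnd_with_morbidity", u.mnd_with_morbidity,
                           f"must be <= mnd_without_morbidity ({u.mnd_without_morbidity})"))
    if u.utility_window_years < 0:
        v.append(Violation("utilities.utility_window_years", u.utility_window_years, "must be >= 0"))

    for name, x in _iter_probability_fields(params):
        prob(name, x)
    t = params.transitions
    if t.dm_median_survival_months <= 0:
        v.append(Violation("transitions.dm_median_survival_months",
                           t.dm_median_survival_months, "must be > 0"))
    missing_bands = [b for b in MORTALITY_BANDS if b not in t.all_cause_mortality]
    for b in missing_bands:
        v.append(Violation(f"transitions.all_cause_mortality[{b}]", None, "missing age band"))
    # exit probabilities per source state must leave room for a stay probability
    rows = {
        "DFS(node_pos)": t.dfs_to_lrr_node_pos + t.dfs_to_dm_node_pos,
        "DFS(node_neg)": t.dfs_to_lrr_node_neg + t.dfs_to_dm_node_neg,
        "LRR(dissected)": t.lrr_to_dm + t.lrr_to_salvage_dissected + t.lrr_to_death_cancer,
        "LRR(undissected)": t.lrr_to_dm + t.lrr_to_salvage_undissected + t.lrr_to_death_cancer,
        "SALVAGE(dissected)": t.salvage_to_lrr_dissected + t.salvage_to_dm_dissected,
        "SALVAGE(undissected)": t.salvage_to_lrr_undissected + t.salvage_to_dm_undissected,
    }
    for row, s in rows.items():
        if s > 1 + 1e-12:
            v.append(Violation(f"transitions.{row}", s, "listed exit probabilities must sum to <= 1"))

    c = params.costs
    for f_ in dataclasses.fields(CostTable):
        if f_.name in ("adjuvant_chemo_fraction", "chemo_cycles", "rt_modality_weights",
                       "lrr_salvage_fraction", "followup_visits_year1",
                       "followup_visits_years2_5", "followup_visits_after"):
            continue
        val = getattr(c, f_.name)
        if val < 0:
            v.append(Violation(f"costs.{f_.name}", val, "cost must be >= 0"))
    prob("costs.adjuvant_chemo_fraction", c.adjuvant_chemo_fraction)
    prob("costs.lrr_salvage_fraction", c.lrr_salvage_fraction)
    for i, w in enumerate(c.rt_modality_weights):
        prob(f"costs.rt_modality_weights[{i}]", w)
    if not math.isclose(sum(c.rt_modality_weights), 1.0, abs_tol=1e-9):
        v.append(Violation("costs.rt_modality_weights", c.rt_modality_weights, "must sum to 1"))

    cfg = params.config
    if cfg.discount_rate < 0:
        v.append(Violation("config.discount_rate", cfg.discount_rate, "must be >= 0"))
    if cfg.horizon_years != "lifetime" and int(cfg.horizon_years) < 1:
        v.append(Violation("config.horizon_years", cfg.horizon_years, "must be >= 1 or 'lifetime'"))
    if cfg.wtp_threshold < 0:
        v.append(Violation("config.wtp_threshold", cfg.wtp_threshold, "must be >= 0"))
    prob("config.occult_metastasis_rate", cfg.occult_metastasis_rate, lo_open=True)
    if cfg.half_cycle not in ("mid_cycle_discount", "trapezoid"):
        v.append(Violation("config.half_cycle", cfg.half_cycle,
                           "must be 'mid_cycle_discount' or 'trapezoid'"))

    for name, spec in params.distributions.items():
        if spec.family not in FAMILIES:
            v.append(Violation(f"distributions[{name}].family", spec.family,
                               f"must be one of {FAMILIES}"))
            continue
        if spec.family == "fixed":
            continue
        if spec.low is None or spec.high is None:
            v.append(Violation(f"distributions[{name}]", spec, "non-fixed family requires bounds"))
            continue
        if not (spec.low <= spec.mean <= spec.high):
            v.append(Violation(f"distributions[{name}]", (spec.low, spec.mean, spec.high),
                               "requires low <= mean <= high"))
        if spec.family == "beta" and not (0 <= spec.low and spec.high <= 1 and 0 < spec.mean < 1):
            v.append(Violation(f"distributions[{name}]", (spec.low, spec.mean, spec.high),
                               "beta requires mean, low, high in [0, 1]"))
        if spec.family in ("gamma", "normal") and spec.mean <= 0:
            v.append(Violation(f"distributions[{name}].mean", spec.mean,
                               f"{spec.family} cost parameter requires mean > 0"))
    return v


def table1_defaults() -> ParameterSet:
    """The canonical published input set: base estimates, interval bounds, and
    distribution families for every model parameter.

    The sentinel-node biopsy package cost is published with identical lower and
    upper limits (25,900/25,900) — treated as a printing error; the working
    bounds are +/-20% of the base estimate and the printed pair is kept in the
    spec's ``printed_bounds`` metadata.
    """
    d: dict[str, DistributionSpec] = {}

    def beta(path: str, mean: float, low: float, high: float) -> float:
        d[path] = DistributionSpec("beta", mean, low, high)
        return mean

    def diri(path: str, mean: float, low: float, high: float) -> float:
        d[path] = DistributionSpec("dirichlet", mean, low, high)
        return mean

    def gamma(path: str, mean: float, low: float, high: float,
              printed: tuple[float, float] | None = None) -> float:
        d[path] = DistributionSpec("gamma", mean, low, high, printed_bounds=printed)
        return mean

    def norm(path: str, mean: float, low: float, high: float) -> float:
        d[path] = DistributionSpec("normal", mean, low, high)
        return mean

    def fixed(path: str, mean: float) -> float:
        d[path] = DistributionSpec("fixed", mean)
        return mean

    accuracy_slnb = DiagnosticAccuracy(
        sensitivity=beta("accuracy_slnb.sensitivity", 0.81, 0.77, 0.85),
        npv=beta("accuracy_slnb.npv", 0.93, 0.88, 0.98),
    )
    accuracy_endfs = DiagnosticAccuracy(
        sensitivity=beta("accuracy_endfs.sensitivity", 0.84, 0.80, 0.88),
        npv=beta("accuracy_endfs.npv", 0.93, 0.88, 1.00),
    )
    utilities = UtilityTable(
        snd_without_morbidity=beta("utilities.snd_without_morbidity", 0.862, 0.82, 0.91),
        snd_with_morbidity=beta("utilities.snd_with_morbidity", 0.747, 0.71, 0.78),
        mnd_without_morbidity=beta("utilities.mnd_without_morbidity", 0.821, 0.78, 0.86),
        mnd_with_morbidity=beta("utilities.mnd_with_morbidity", 0.711, 0.68, 0.75),
        dfs_primary_resection=beta("utilities.dfs_primary_resection", 0.891, 0.85, 0.94),
        dfs_after_neck_dissection=beta("utilities.dfs_after_neck_dissection", 0.819, 0.78, 0.86),
        lrr=beta("utilities.lrr", 0.659, 0.63, 0.69),
        dm=beta("utilities.dm", 0.508, 0.48, 0.53),
        salvaged=beta("utilities.salvaged", 0.264, 0.25, 0.28),
    )
    transitions = TransitionTable(
        dfs_to_lrr_node_pos=diri("transitions.dfs_to_lrr_node_pos", 0.065, 0.062, 0.069),
        dfs_to_lrr_node_neg=diri("transitions.dfs_to_lrr_node_neg", 0.043, 0.041, 0.045),
        dfs_to_dm_node_pos=diri("transitions.dfs_to_dm_node_pos", 0.0136, 0.013, 0.014),
        dfs_to_dm_node_neg=diri("transitions.dfs_to_dm_node_neg", 0.004, 0.004, 0.005),
        lrr_to_dm=diri("transitions.lrr_to_dm", 0.076, 0.072, 0.08),
        lrr_to_salvage_dissected=diri("transitions.lrr_to_salvage_dissected", 0.083, 0.079, 0.087),
        lrr_to_salvage_undissected=diri("transitions.lrr_to_salvage_undissected", 0.146, 0.139, 0.154),
        lrr_to_death_cancer=diri("transitions.lrr_to_death_cancer", 0.613, 0.582, 0.643),
        salvage_to_lrr_dissected=diri("transitions.salvage_to_lrr_dissected", 0.136, 0.129, 0.143),
        salvage_to_lrr_undissected=diri("transitions.salvage_to_lrr_undissected", 0.115, 0.109, 0.121),
        salvage_to_dm_dissected=diri("transitions.salvage_to_dm_dissected", 0.032, 0.030, 0.033),
        salvage_to_dm_undissected=diri("transitions.salvage_to_dm_undissected", 0.030, 0.029, 0.032),
        dm_median_survival_months=fixed("transitions.dm_median_survival_months", 7.5),
        all_cause_mortality={
            "51-55": fixed("transitions.all_cause_mortality[51-55]", 0.008),
            "56-60": fixed("transitions.all_cause_mortality[56-60]", 0.013),
            "61-65": fixed("transitions.all_cause_mortality[61-65]", 0.019),
            "66-70": fixed("transitions.all_cause_mortality[66-70]", 0.029),
            "71-75": fixed("transitions.all_cause_mortality[71-75]", 0.151),
            "76-80": fixed("transitions.all_cause_mortality[76-80]", 0.066),
            "80+": fixed("transitions.all_cause_mortality[80+]", 0.103),
        },
    )
    costs = CostTable(
        cbc=norm("costs.cbc", 155, 124, 186),
        lft=norm("costs.lft", 259, 207, 311),
        rft=norm("costs.rft", 259, 207, 311),
        electrolytes=norm("costs.electrolytes", 460, 368, 552),
        tsh=norm("costs.tsh", 104, 83, 125),
        cisplatin_weekly=gamma("costs.cisplatin_weekly", 2_900, 2_600, 3_100),
        cisplatin_high=gamma("costs.cisplatin_high", 11_950, 10_800, 12_800),
        rt_2d=gamma("costs.rt_2d", 13_390, 12_100, 14_300),
        rt_3dcrt=gamma("costs.rt_3dcrt", 25_540, 23_100, 27_300),
        rt_imrt=gamma("costs.rt_imrt", 85_050, 77_000, 91_000),
        high_end_radiology=gamma("costs.high_end_radiology", 5_560, 5_000, 5_800),
        paclitaxel=gamma("costs.paclitaxel", 14_380, 13_000, 15_400),
        paclitaxel_carboplatin=gamma("costs.paclitaxel_carboplatin", 17_540, 16_000, 18_200),
        basic_supportive_care=gamma("costs.basic_supportive_care", 10_215, 9_900, 10_350),
        slnb=gamma("costs.slnb", 28_670, 28_670 * 0.8, 28_670 * 1.2, printed=(25_900, 25_900)),
        mnd=gamma("costs.mnd", 36_870, 33_300, 39_900),
        snd=gamma("costs.snd", 26_040, 23_500, 28_200),
        salvage_surgery=gamma("costs.salvage_surgery", 60_550, 54_600, 65_600),
        frozen_section=gamma("costs.frozen_section", 8_500, 5_000, 12_000),
    )
    config = AnalysisConfig(
        median_age=fixed("config.median_age", 50),
        occult_metastasis_rate=beta("config.occult_metastasis_rate", 0.23, 0.2, 0.3),
    )
    return ParameterSet(
        accuracy_slnb=accuracy_slnb,
        accuracy_endfs=accuracy_endfs,
        utilities=utilities,
        transitions=transitions,
        costs=costs,
        config=config,
        distributions=d,
    )


def save_parameter_set(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True))


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a parameter file (JSON). Raises
    :class:`ParameterValidationError` naming the offending fields on schema or
    range violations."""
    data = json.loads(Path(path).read_text())
    params = ParameterSet.from_dict(data)
    violations = validate(params)
    if violations:
        raise ParameterValidationError(violations)
    return params
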