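"""Decision-tree stratification of the cohort by diagnostic test result.

Three neck-management strategies are compared for clinically node-negative
early oral squamous cell carcinoma, all following excision of the primary
tumour:

* Group I  — sentinel lymph node biopsy (SLNB) with intraoperative frozen
  section; test-positive patients receive a modified neck dissection (MND),
  test-negative patients no further surgery.  Patients negative on frozen
  section but positive on final histopathology (false negatives) are
  re-admitted within a month for MND.
* Group II — elective selective neck dissection (SND, levels I–III) for all.
* Group III — elective neck dissection with frozen section of the specimen;
  frozen-section-positive patients are upgraded to MND, the rest keep SND.

Prevalence of occult nodal metastasis plus the test's sensitivity and negative
predictive value (NPV) determine the true/false positive/negative fractions.
Final histopathology — not the intraoperative test result — drives adjuvant
therapy eligibility and the recurrence risk class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .parameters import ParameterSet

__all__ = [
    "StratumFractions",
    "PathwayProfile",
    "InfeasibleAccuracyError",
    "stratify_from_sens_npv",
    "stratify_from_sens_spec",
    "implied_specificity",
    "pathway_profiles",
    "profiles_table",
    "GROUPS",
]

GROUPS = ("I", "II", "III")


class InfeasibleAccuracyError(ValueError):
    """The (prevalence, sensitivity, NPV) triple admits no valid 2x2 table."""


@dataclass(frozen=True)
class StratumFractions:
    """Cohort proportions of the diagnostic 2x2 table; sums to 1."""

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def prevalence(self) -> float:
        return self.tp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def stratify_from_sens_npv(prevalence: float, sensitivity: float, npv: float,
                           *, clip: bool = False) -> StratumFractions:
    """Solve the 2x2 table from prevalence, sensitivity and NPV.

    tp = p*se and fn = p*(1-se) directly; the NPV constraint
    tn/(tn+fn) = npv fixes tn, and fp is the remainder.  The triple can be
    mutually inconsistent (the implied tn exceeding the non-diseased fraction);
    with ``clip=True`` tn is capped at 1-p (fp = 0), otherwise an
    :class:`InfeasibleAccuracyError` is raised.
    """
    for name, x in (("prevalence", prevalence), ("sensitivity", sensitivity), ("npv", npv)):
        if not (0 < x <= 1):
            raise ValueError(f"{name}={x} outside (0, 1]")
    tp = prevalence * sensitivity
    fn = prevalence * (1 - sensitivity)
    if npv < 1:
        tn = npv * fn / (1 - npv)
    else:
        if fn > 0 and not clip:
            raise InfeasibleAccuracyError(
                f"npv=1 with sensitivity={sensitivity}<1 implies fn={fn:.4g}>0")
        tn = 1 - prevalence
    if tn > 1 - prevalence + 1e-12:
        if clip:
            tn = 1 - prevalence
        else:
            raise InfeasibleAccuracyError(
                f"implied tn={tn:.4f} exceeds non-diseased fraction {1 - prevalence:.4f}; "
                "prevalence, sensitivity and npv are mutually inconsistent")
    fp = 1 - tp - fn - tn
    if fp < 0:
        if clip and fp > -1e-12:
            fp = 0.0
        else:
            raise InfeasibleAccuracyError(f"implied fp={fp:.4g} < 0")
    return StratumFractions(tp=tp, fp=max(fp, 0.0), tn=tn, fn=fn)


def stratify_from_sens_spec(prevalence: float, sensitivity: float,
                            specificity: float) -> StratumFractions:
    """2x2 table from prevalence, sensitivity and specificity (always feasible)."""
    for name, x in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not (0 < x <= 1):
            raise ValueError(f"{name}={x} outside (0, 1]")
    return StratumFractions(
        tp=prevalence * sensitivity,
        fn=prevalence * (1 - sensitivity),
        tn=(1 - prevalence) * specificity,
        fp=(1 - prevalence) * (1 - specificity),
    )


def implied_specificity(prevalence: float, sensitivity: float, npv: float) -> float:
    """Specificity implied by a (prevalence, sensitivity, NPV) triple."""
    return stratify_from_sens_npv(prevalence, sensitivity, npv).specificity


@dataclass(frozen=True)
class PathwayProfile:
    """One decision-tree leaf: who these patients are and what they receive upfront."""

    group: str
    stratum: str                 # TP | FP | TN | FN | node_pos | node_neg
    weight: float                # cohort fraction within the group
    neck_dissection: str         # none | SND | MND
    receives_adjuvant: bool
    readmission: bool
    utility_track: str           # primary_resection_only | snd | mnd
    recurrence_risk_class: str   # node_pos | node_neg
    upfront_cost: float          # INR at model entry (surgery + frozen section + adjuvant)

    @property
    def dissected(self) -> bool:
        return self.neck_dissection != "none"


def pathway_profiles(group: str, params: ParameterSet, *,
                     prevalence: float | None = None,
                     stratification: str = "npv") -> list[PathwayProfile]:
    """Decision-tree leaves with weights for one strategy.

    ``stratification`` selects how the 2x2 fractions respond to prevalence:
    ``"npv"`` holds sensitivity and NPV at their published values (capping the
    implied TN at the non-diseased fraction when the triple is infeasible);
    ``"specificity"`` holds sensitivity and the base-case implied specificity,
    which keeps the table coherent across the whole prevalence range and is
    what the occult-rate threshold analysis uses.
    """
    p = params.config.occult_metastasis_rate if prevalence is None else prevalence
    c = params.costs
    adj = c.adjuvant_bundle()

    if group == "II":
        completion = params.config.group2_completion_mnd
        pos_cost = c.snd + (c.mnd if completion else 0.0) + adj
        return [
            PathwayProfile("II", "node_pos", p, "MND" if completion else "SND",
                           receives_adjuvant=True, readmission=completion,
                           utility_track="mnd" if completion else "snd",
                           recurrence_risk_class="node_pos", upfront_cost=pos_cost),
            PathwayProfile("II", "node_neg", 1 - p, "SND",
                           receives_adjuvant=False, readmission=False,
                           utility_track="snd", recurrence_risk_class="node_neg",
                           upfront_cost=c.snd),
        ]

    if group == "I":
        acc = params.accuracy_slnb
    elif group == "III":
        acc = params.accuracy_endfs
    else:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")

    if stratification == "npv":
        f = stratify_from_sens_npv(p, acc.sensitivity, acc.npv, clip=True)
    elif stratification == "specificity":
        base = stratify_from_sens_npv(params.config.occult_metastasis_rate,
                                      acc.sensitivity, acc.npv, clip=True)
        f = stratify_from_sens_spec(p, acc.sensitivity, base.specificity)
    else:
        raise ValueError(f"unknown stratification {stratification!r}")

    if group == "I":
        return [
            PathwayProfile("I", "TP", f.tp, "MND", True, False, "mnd", "node_pos",
                           c.slnb + c.mnd + adj),
            PathwayProfile("I", "FP", f.fp, "MND", False, False, "mnd", "node_neg",
                           c.slnb + c.mnd),
            PathwayProfile("I", "TN", f.tn, "none", False, False,
                           "primary_resection_only", "node_neg", c.slnb),
            # FS-negative, histopathology-positive: second admission for MND
            # (dissection package only, no repeat biopsy), then adjuvant therapy
            PathwayProfile("I", "FN", f.fn, "MND", True, True, "mnd", "node_pos",
                           c.slnb + c.mnd + adj),
        ]

    fn_completion = params.config.group3_fn_completion_mnd
    fn_cost = c.frozen_section + c.snd + (c.mnd if fn_completion else 0.0) + adj
    return [
        PathwayProfile("III", "TP", f.tp, "MND", True, False, "mnd", "node_pos",
                       c.frozen_section + c.mnd + adj),
        PathwayProfile("III", "FP", f.fp, "MND", False, False, "mnd", "node_neg",
                       c.frozen_section + c.mnd),
        PathwayProfile("III", "TN", f.tn, "SND", False, False, "snd", "node_neg",
                       c.frozen_section + c.snd),
        PathwayProfile("III", "FN", f.fn, "MND" if fn_completion else "SND",
                       True, fn_completion, "mnd" if fn_completion else "snd",
                       "node_pos", fn_cost),
    ]


def profiles_table(params: ParameterSet) -> pd.DataFrame:
    """Audit table of all decision-tree leaves across the three strategies."""
    rows = []
    for group in GROUPS:
        for prof in pathway_profiles(group, params):
            rows.append({
                "group": prof.group,
                "stratum": prof.stratum,
                "weight": prof.weight,
                "neck_dissection": prof.neck_dissection,
                "receives_adjuvant": prof.receives_adjuvant,
                "readmission": prof.readmission,
                "utility_track": prof.utility_track,
                "recurrence_risk_class": prof.recurrence_risk_class,
                "upfront_cost_inr": prof.upfront_cost,
            })
    df = pd.DataFrame(rows)
    assert all(math.isclose(g.weight.sum(), 1.0, abs_tol=1e-9)
               for _, g in df.groupby("group"))
    return df
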