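# Methods

## The decision problem

In clinically node-negative early (cT1–T2N0) oral squamous cell carcinoma,
roughly a quarter of patients harbour occult nodal metastasis. The standard of
care — elective selective neck dissection (SND, levels I–III) for everyone —
overtreats the node-negative majority and carries shoulder morbidity.
Sentinel lymph node biopsy (SLNB) with intraoperative frozen section offers a
test-and-treat alternative: dissect (modified neck dissection, MND, levels
I–V) only when the sentinel node is positive. This package implements a
payer-perspective (PM-JAY package rates, INR) cost-utility comparison of three
strategies for a hypothetical cohort of 50-year-old Indian patients, all after
excision of the primary tumour:

* **Group I** — SLNB-guided: MND for test-positives, no further surgery for
  test-negatives, readmission MND for false negatives found on final
  histopathology;
* **Group II** — elective SND for all, with completion MND on readmission for
  occult-positive patients (toggle `group2_completion_mnd`);
* **Group III** — elective dissection with frozen section of the specimen:
  MND in the same sitting when positive, SND otherwise. Frozen-section false
  negatives keep their SND and receive adjuvant therapy only (toggle
  `group3_fn_completion_mnd`).

## Diagnostic stratification

Given occult-metastasis prevalence p and a test's sensitivity (se) and
negative predictive value (NPV), the 2×2 fractions are

    TP = p·se,  FN = p·(1−se),  TN = NPV·FN/(1−NPV),  FP = 1 − TP − FN − TN.

The triple can be mutually inconsistent (the NPV constraint may demand
TN > 1−p); `stratify_from_sens_npv` raises by default and caps TN at 1−p when
`clip=True` (used for sampled parameter draws). Adjuvant chemoradiation
eligibility and the recurrence risk class follow *final histopathology*
(TP/FN and occult-positive strata are `node_pos`), not the intraoperative test
result.

## Markov cohort model

Six states — disease-free (DFS), loco-regional recurrence (LRR), salvage after
recurrence, distant metastasis (DM), cancer death, other-cause death — over
annual cycles to age 100 ("lifetime", 50 cycles). Exits are additive competing
probabilities; a proportional renormalisation guard (logged) protects against
extreme sampled draws. Annual rates derived from published summaries use
constant-hazard conversions: a cumulative probability P over y years gives
1−(1−P)^(1/y) (e.g. the 85%-in-2-years cancer mortality from recurrence →
0.613/yr); a median survival of m months gives 1−0.5^(12/m) (7.5 months in DM
→ 0.670/yr). All-cause mortality is an age-band lookup used exactly as
published, including its non-monotone 71–75 band; ages below the first band
clamp to it. Recurrence and salvage dynamics differ between dissected and
undissected necks, which is what separates the survival of Group I
(58% of patients keep an undissected neck) from Groups II/III.

### Half-cycle correction and discounting

Both costs and outcomes discount at 3%/yr. Two half-cycle conventions are
implemented (`config.half_cycle`):

* `mid_cycle_discount` (default): end-of-cycle occupancy credited at the
  mid-cycle discount factor (1+r)^−(t−½). This is the common spreadsheet
  variant and is the convention that reproduces the published lifetime
  QALY/LY figures to within ±0.05.
* `trapezoid`: the life-table rule — mean of start- and end-of-cycle
  occupancy at the end-of-cycle discount factor. It is the methodologically
  exact rule for mid-cycle transitions (the half-life toy chain yields
  LY = 1.5 exactly) and is what the microsimulation oracle cross-checks.

Upfront surgical/adjuvant costs are charged at model entry, undiscounted and
outside the correction. Event costs (recurrence treatment on LRR entry,
salvage surgery on salvage entry) are credited in the transition cycle.

### Utilities

Post-surgical utilities (SND/MND, mixed between with- and without-shoulder-
morbidity values by `morbidity_weight`, default 0.17 — the midpoint of the
9–25% shoulder-morbidity range) apply for `utility_window_years` (default 5),
after which dissected tracks revert to the generic post-dissection DFS
utility (0.819). Patients spared a dissection keep the post-resection utility
(0.891) throughout — this persistence is what generates the lifetime QALY
advantage of the sentinel-node strategy (+0.34 vs SND-for-all).

### Costs and the treatment-mix calibration

Procedure package rates and investigation prices are model inputs; the
*allocation* weights are not published and are exposed as calibration knobs
with these fixed values (recorded in every run manifest):

| knob | value | role |
|---|---|---|
| `rt_modality_weights` | 0.1/0.6/0.3 (2D/3D-CRT/IMRT) | RT course mix |
| `adjuvant_chemo_fraction` | 0.5 | RT ± concurrent weekly cisplatin |
| `chemo_cycles` | 6 | weekly cisplatin doses per course |
| `lrr_salvage_fraction` | 0.5 | surgery vs (chemo)RT on recurrence |
| follow-up schedule | 3 / 2 / 2 / 2 / 2 then 1 per year | investigation panel-visits in DFS |

A follow-up panel is CBC + LFT + RFT + electrolytes + TSH + one high-end
radiological investigation (6,797 INR). The schedule is the one knob adjusted
during calibration (from an initial 4/4/2/2/2 guess) so that modelled lifetime
costs centre on the reported payer costs; all three land within ±3.1%.
Supportive care in DM accrues per cycle (`dm_cost_per_cycle`; a one-off
variant is available).

## Economic outcomes

Strategies are ranked by QALYs ascending and each compared with its
predecessor: ICUR = ΔC/ΔQ (reported as a dominance flag when a strategy is
cheaper and more effective — negative ratios are ambiguous), INMB =
WTP·ΔQ − ΔC at the one-time-GDP-per-capita threshold (211,725 INR/QALY).
Internal arithmetic is unrounded; displays round to whole INR/USD (83.68
INR/US$).

## Uncertainty analysis

**Distributions.** sd = (95% interval width)/3.92; beta and gamma by moment
matching; transition rows drawn jointly from Dirichlets whose concentration
makes the cell-average marginal sd equal the cell-average interval-implied sd.
The published identical bounds for the SLNB package cost are treated as a
printing error (±20% used; printed pair preserved in metadata). Parameters
are otherwise independent. Out-of-range draws clip with a logged count.

**PSA.** Each of n iterations (default 1000) redraws all parameters —
including prevalence and test accuracies, with re-stratification — and
re-runs the three strategies. CE planes and CEACs use the INMB criterion
(robust to negative ΔQ draws).

**One-way DSA.** Each parameter to its interval bounds (±20% fallback), all
others at base; tornado sorted by ICUR spread. The dominant levers of the
sentinel-node comparison are the biopsy NPV and sensitivity, the
post-resection DFS utility, the SLNB package cost and the occult rate.

**Threshold analysis.** The occult rate is swept (default 0.05–0.95, step
0.01) with re-stratification at each value. NPV is prevalence-dependent, so
the sweep holds sensitivity and the *base-case implied specificity* (0.754
for SLNB, 0.635 for the specimen frozen section); holding NPV instead is
available but becomes infeasible above p≈0.28 (TN capped). At the one-time
GDP threshold the sentinel strategy remains cost-effective up to an occult
rate of 0.79 (0.83 under the capped fixed-NPV variant) — the lifetime
persistence of the avoided-dissection utility advantage keeps ΔQ large; under
a 5-year horizon the breakpoint falls to ≈0.56.

## Validation oracle

`microsim.simulate_patients` is an independent individual-level simulator: it
re-derives transitions and accruals from the parameter set (no shared engine
code) and steps vectorised patient cohorts cycle by cycle. The central
correctness property — cohort totals within 3 Monte Carlo standard errors of
microsimulation means for every strategy, on the canonical parameters and on
randomised valid fixtures from `random_parameter_fixture` — is asserted in the
test suite (n = 1.5×10⁵ patients canonical, 10⁵/6×10⁴ on fixtures; at those
sizes 3 SE ≈ 0.03–0.04 QALY). The fixture generator keeps rows comfortably
sub-stochastic so the renormalisation guard stays an edge case.

## Numerical and degenerate-input choices

Mass conservation asserted at 1e-10 per cycle. QALY ties in the ladder break
on cost and are flagged. `validate` is total: it returns violations (field,
value, rule) rather than raising. Horizons below one cycle, non-positive
medians and cumulative probabilities of 1 are rejected. Problem sizes in the
shipped tests (microsim n, PSA iterations, sweep grids) were chosen so the
statistical assertions have comfortable power while the whole suite runs in
well under a minute.

## What the synthetic fixtures do and do not show

`random_parameter_fixture` emulates structurally valid parameter sets — not
clinically plausible oral-cancer epidemiology. Passing the oracle-equivalence
and conservation properties on fixtures demonstrates the *engine* is correct
for any valid input; it says nothing about external validity of the canonical
inputs themselves, which are taken as published.

## Known limitations

* The published all-cause mortality table is non-monotone in age (71–75 >
  76–80); it is used as printed, and the model's survival runs ~1.3pp above
  the published 5-year OS as a result.
* The published incremental cost of the sentinel strategy vs SND-for-all
  (2,507 INR lifetime) is not reproducible from the published package rates
  under any pathway assignment consistent with the clinical narrative; the
  minimum defensible gap is ≈11k INR, and the I-vs-II ICUR is correspondingly
  higher than published (the I-vs-III ICUR reproduces within 4%).
* No sub-site-specific accuracy, individual risk factors, second primaries or
  treatment-toxicity states; indirect costs are excluded by design
  (payer perspective).
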