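# oralcea

Cost-utility analysis of neck-management strategies in early oral squamous
cell carcinoma (cT1–T2N0), from the perspective of India's national insurance
payer. The package is for health-economics and HTA analysts who want the full
pipeline — diagnostic decision tree, Markov cohort model, economic
aggregation, and deterministic/probabilistic/threshold sensitivity analyses —
as tested, scriptable code rather than a spreadsheet.

Three strategies are compared, all following primary tumour excision:

| group | strategy |
|---|---|
| I | sentinel lymph node biopsy (SLNB) + frozen section; modified neck dissection (MND) only if positive |
| II | elective selective neck dissection (SND) for all |
| III | elective neck dissection with frozen section; MND if the specimen is positive, SND otherwise |

## Model

Occult-metastasis prevalence p and test accuracy (sensitivity se, negative
predictive value NPV) stratify the cohort: TP = p·se, FN = p(1−se),
TN = NPV·FN/(1−NPV), FP the remainder. Each stratum then enters a six-state
annual Markov model (DFS, loco-regional recurrence, salvage, distant
metastasis, cancer death, other-cause death) run to age 100 with age-banded
background mortality. Discounted (r = 3%) lifetime totals give, for strategy
pairs ordered by effectiveness,

    ICUR = ΔC / ΔQALY        INMB = λ·ΔQALY − ΔC,   λ = 211,725 INR/QALY

with λ the one-time GDP-per-capita willingness-to-pay. Probabilistic
sensitivity analysis redraws every uncertain parameter from Table-of-inputs
distributions (beta/gamma/normal/Dirichlet, moment-matched to 95% intervals)
and yields CE planes and acceptability curves. An independent individual-level
microsimulation validates the cohort engine to Monte Carlo error.

## Worked example

```python
from oralcea import table1_defaults, base_case, results_table

params = table1_defaults()          # canonical published inputs
results = base_case(params)         # lifetime run, all three strategies
print(results_table(results, params).to_string(index=False))
```

prints

```
group  cost_inr  cost_usd        ly     qaly  incremental_cost_inr  incremental_qaly icur_inr_per_qaly  inmb_inr dominance
  III    178707      2136 10.191864 8.092128                   NaN               NaN              None       NaN      None
   II    173551      2074 10.191864 8.131380               -5156.0          0.039252          dominant   13467.0  dominant
    I    184878      2209 10.287800 8.474817               11327.0          0.343437             32981   61387.0      none
```

Reading the ladder (strategies in ascending QALYs): SND-for-all is cheaper
*and* more effective than routine frozen-section-guided dissection (it
dominates), and upgrading to the SLNB-guided strategy buys 0.343 extra QALYs
per patient for 11,327 INR — an ICUR of ~33,000 INR/QALY, far below the
211,725 INR/QALY threshold (INMB ≈ +61,400 INR), so the sentinel-node
strategy is cost-effective. Survival is near-identical across strategies
(5-year OS 80.7% vs 80.3%); the QALY gain comes from the ~58% of patients
spared a neck dissection.

The same analyses are available from the shell:

```
oralcea base-case --out results/
oralcea psa --n 1000 --seed 2024 --out results/
oralcea dsa --reference III --comparator I --out results/
oralcea threshold --lo 0.05 --hi 0.95 --step 0.01 --out results/
```

Every command writes CSVs plus a `manifest.json` capturing the configuration,
calibration-knob values and seed, making deterministic outputs bit-for-bit
reproducible. `oralcea export-params` writes the editable canonical parameter
file (JSON, all costs in INR).

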