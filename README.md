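# hbkg — hemoglobin-mass-balance quantification of surgical blood loss

Bleeding after cardiac surgery is usually monitored by chest-tube drainage
volume, but drained fluid is a mixture of blood and serous exudate, so volume
alone under- or over-states the true loss, and the same loss means different
things for a 50 kg and a 120 kg patient. `hbkg` implements a blood-loss score
that addresses both problems: the **Hb/kg index**, the hemoglobin mass lost
per kilogram of body weight,

```
Hb/kg = ( Hb_loss(intra-op) + Hb_loss(chest tubes) − Hb(transfused) ) / weight   [g/kg]
```

built from five steps:

1. **Estimated blood volume (EBV)**, Nadler polynomial:
   `EBV(L) = k1·height(m)³ + k2·weight(kg) + k3`, with sex-specific
   coefficients (men 0.3669 / 0.03219 / 0.6041, women 0.3561 / 0.03308 / 0.1833).
2. **Initial Hb mass** = EBV × Hb(T0) (g).
3. **Intraoperative Hb loss** = (Hb(T0) − Hb(T1)) × EBV, the pre/post
   concentration drop over one blood volume.
4. **Chest-tube Hb loss** = drain-fluid Hb (g/L) × 18-h drainage volume (L),
   which automatically discounts serous dilution.
5. **Transfusion correction** = PRBC units × 43 g Hb/unit (configurable).

Around the index the package provides, as importable modules with a thin CLI
(`hbkg simulate|index|stats|model|report|run`):

- `hbkg.index` — the five-step arithmetic, BMI and drainage-volume strata;
- `hbkg.simulate` — a synthetic perioperative cohort generator with known
  ground truth (195 patients, 86 candidate predictors by default);
- `hbkg.stats` — gender/BMI/surgery/drainage group comparisons (Student t,
  one-way ANOVA with η² and Scheffé post-hoc), age correlation, and Spearman
  screening of candidate predictors, plus summary-statistic entry points so
  published tables can be checked without row-level data;
- `hbkg.models` — an eight-model cross-validated comparison (linear, lasso,
  lasso-OLS refit, SVR, kNN, decision tree, XGBoost, neural net) reporting
  held-out MSE, MAPE, correlation and R² as mean ± SD;
- `hbkg.io` — schema-validated CSV I/O and the reproducible pipeline.

## Worked example

```python
from hbkg import compute_hbkg_index

record = {"sex": "male", "height_m": 1.80, "weight_kg": 80.0,
          "hb_t0": 135.0, "hb_t1": 110.0,          # g/L, pre-op and post-op
          "drain_hb": 30.0, "ctd_total_ml": 500.0,  # drain fluid
          "prbc_units": 0}
res = compute_hbkg_index(record)
print(f"EBV {res.ebv:.3f} L, intra-op loss {res.intraop_loss:.1f} g, "
      f"CTD loss {res.ctd_loss:.1f} g, index {res.index:.3f} g/kg")
```

prints

```
EBV 5.319 L, intra-op loss 133.0 g, CTD loss 15.0 g, index 1.850 g/kg
```

i.e. a 5.32 L blood volume, a 133 g intraoperative Hb loss from the 25 g/L
concentration drop, 15 g more lost through the drains, and a final loss of
1.85 g of hemoglobin per kg body weight — a mid-range value for this kind of
surgery. One PRBC unit would lower the index by exactly 43/80 ≈ 0.54 g/kg.

The analysis itself is a four-step pipeline (each script prints what it found
and writes its tables under `results/`):

```bash
python analysis/01_simulate_cohort.py --seed 1   # 195-patient synthetic cohort
python analysis/02_compute_index.py              # per-patient index
python analysis/03_cohort_statistics.py          # strata + Spearman screen
python analysis/04_model_comparison.py --seed 1  # eight-model CV comparison
```

With seed 1 the simulated cohort has index 2.08 ± 0.98 g/kg, 6.2% of patients
transfused and 58/195 draining ≥ 500 mL; men exceed women (2.27 vs 1.70,
t(193) = 3.98), the lean BMI stratum has the highest and the obese stratum the
lowest index (2.66 vs 1.65, Scheffé I-vs-III p < 0.001), and larger drainage
volume means a higher index (2.48 vs 1.91, t(193) = −3.85). The Spearman
screen retains 41 of 86 candidates — its strongest hits (pre-op Hb/RBC/Hct
positive, BMI negative, drain Hb and mid-hour drainage volumes positive)
include all four designated mechanistic drivers — and lasso regression wins
the 5-fold × 10-repeat comparison (MSE 0.027 ± 0.006, R² 0.971 ± 0.006),
ahead of the lasso-OLS refit and plain linear regression, with trees, kNN and
the neural net well behind: the index is a predominantly linear, sparse
function of the clinical columns, and the harness recovers exactly that
structure.

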