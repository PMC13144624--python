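# Methods

## The index

The Hb/kg index treats perioperative blood loss as a hemoglobin mass
balance. Circulating Hb mass is the product of blood volume and Hb
concentration; blood volume is estimated by the Nadler height/weight/sex
polynomial (`EBV = k1·h³ + k2·w + k3`, litres). Three mass terms are summed
and normalized by body weight:

- **intraoperative loss** `(Hb_T0 − Hb_T1) × EBV` — the concentration drop
  from before surgery to immediately after, over one blood volume;
- **chest-tube loss** `drain_Hb × total_drainage_volume` — the Hb mass
  actually evacuated over 18 h. Using the drain fluid's own Hb concentration
  (from a laboratory aliquot) discounts serous and irrigation dilution that
  makes raw volume misleading;
- **transfusion correction** `− units × 43 g` — Hb supplied externally must
  not be counted as retained blood. 43 g/unit is the national blood-product
  standard of the originating study; the literature value 52 g/unit is a
  config option.

The source formula for the intraoperative step as printed multiplies the
*mass* difference by EBV once more, which is dimensionally g·L and inflates
the step by a factor of EBV. The default mode `consistent` therefore
multiplies the *concentration* drop by EBV (grams); the verbatim reading is
retained behind `mode="literal"` for comparability, clearly documented as
dimensionally incoherent. The consistent reading reproduces the reported
cohort magnitude (≈1.6–2.1 g/kg); the literal one is ~5× larger.

Conventions and edge cases:

- T1 (immediately postoperative) is the post-op concentration in step 3;
  T6/T18 are predictors only.
- Negative intraoperative loss (hemoconcentration) is propagated with a
  warning, never clamped — clamping would bias the cohort mean upward.
- Drainage is recorded hourly in mL and converted to litres internally. A
  single aliquot drain-Hb applies to the whole volume; a per-interval
  concentration vector is accepted and volume-weighted.
- BMI strata use half-open WHO cuts [0,25), [25,30), [30,∞), closing the
  [24.9, 25) gap the printed strata leave; drainage strata split at 500 mL.
- Records missing a step-required field are excluded from the index stage
  and reported with the field named, never silently dropped.

## The synthetic cohort

No patient-level data are distributable, so the generator produces cohorts
with the reported marginal structure and a ground truth that is
self-consistent by construction: the stored true index is computed from the
*recorded* (rounded) fields with the same arithmetic the pipeline applies.

Defaults are the study conditions: n = 195, male fraction 134/195, age
66 ± 7, BMI strata weighted 56/67/72 (within-stratum truncated normals),
sex-specific heights and pre-op Hb (men 140 ± 15 g/L, women 130 ± 14).
Mechanism, chosen on physiological grounds, calibrated against the reported
marginals and correlations, and all config-exposed:

- **intraoperative loss is dilutional**: bypass prime, irrigation and
  surgical loss remove a per-patient *fraction* f ~ N(0.22, 0.085) of the
  Hb concentration (clipped to [0.03, 0.55]), so Hb(T1) = Hb(T0)(1 − f).
  A multiplicative mechanism — unlike an additive drop — couples the loss
  to the initial Hb, reproducing the reported positive pre-op-Hb
  correlation (ρ ≈ +0.4); with the cohort's EBV/weight distribution it
  lands the index near 2 ± 0.9 g/kg and ~6–7% transfused (women more often
  than men);
- **BMI effect**: the mean dilution fraction falls by 0.030 per SD of BMI
  above the cohort centre (obese patients bleed less, as the large CABG
  cohorts report), which together with Nadler blood volume per kg falling
  in BMI reproduces the reported negative BMI correlation (ρ ≈ −0.3…−0.4)
  and the lean > obese stratum ordering;
- **transfusion** is triggered on the T1 measurement (< 80 g/L → 1 unit,
  < 70 → 2), and each unit raises subsequent (T6/T18) Hb by ~10 g/L;
- **drainage**: 18-h total ~ LogNormal(log 350, 0.55) mL (≈26% ≥ 500 mL),
  split across hours by an exponentially decaying profile with gamma noise;
- **serous dilution**: a per-patient serous fraction ~ Beta(2.2, 1.3);
  drain Hb = post-op blood Hb × (1 − serous fraction);
- **bleeding couplings**: the standardized idiosyncratic dilution (beyond
  what BMI predicts) shifts log-drainage (+0.15/SD) and the serous fraction
  (−0.12/SD) — active bleeders drain more, and more hemorrhagic, fluid —
  and depresses fibrinogen / raises D-dimer, giving the coagulation panel
  the reported negative correlations with the index;
- **candidates**: 44 real numeric clinical columns plus 42 independent
  standard-normal noise columns = 86 screened predictors.

Because the index is a deterministic function of the recorded fields, its
minimal sufficient predictors are table columns; any purely upstream driver
is conditionally redundant and a correct sparse learner would drop it. The
four **designated true predictors** are therefore the dominant mechanistic
columns — `hb_t0`, `hb_t1`, `drain_hb`, `bmi` — and recovery tests ask that
screening retain them and the lasso support contain them. Other genuinely
informative columns (hourly volumes, height, PRBC units) are legitimately
selected too; sparse-recovery quality is judged by how few pure-noise
columns enter, not by total support size.

What the generator does **not** emulate: measurement error correlated across
timepoints, informative missingness, site effects, re-sternotomy and other
outcome processes, and any nonlinearity in the true dose–response beyond the
mass-balance products. Passing tests show the pipeline recovers the
structure this generator encodes, not that it would rank models identically
on real data.

## Statistics

Student (pooled-variance) t is the default two-group test, matching df =
n₁ + n₂ − 2; Welch is a flag. One-way ANOVA reports F on (k−1, N−k), η² =
SS_between/SS_total, and Scheffé all-pairs post-hoc p-values via the
F-projection formula (pairwise F / (k−1) referred to F(k−1, N−k)).
Summary-statistic entry points recompute t, F and η² from published
(mean, SD, n) triples; with rounded SDs these agree with printed statistics
only to ~±0.1 (t) and ~±0.5 (F), which is the tolerance the checks use.
Spearman screening uses tie-corrected ranks with the large-sample t
approximation for p (adequate at n = 195); retention is raw p < α with no
multiplicity correction by default, since the original screening reported
raw p-values across 86 candidates; Benjamini–Hochberg is an option.

## Model comparison

The cross-validation scheme is 5-fold × 10 repeats; the ± spread is the SD
across all 50 fold-level values. Non-sparse models receive only the
Spearman-retained columns; lasso and lasso-OLS see all 86 and select
internally. Standardization is fit inside each training fold (pipeline), so
held-out rows never influence preprocessing. Hyperparameters are
conventional and not tuned: lasso penalty by inner 5-fold CV over a 100-point
log path (CV-optimal by default; a one-standard-error rule gives a sparser
support); SVR with RBF kernel at C = 1; kNN k = 5; decision tree with
minimum leaf 5; XGBoost 300 depth-3 trees at learning rate 0.05; MLP with
(64, 32) hidden layers and early stopping. Lasso-OLS refits unpenalized
least squares on the selected support to remove shrinkage bias. MAPE
excludes records with |index| < 0.05 g/kg (count logged), since a relative
error against a near-zero index is uninformative. A fold whose held-out
target is constant is skipped and counted; a model failure is recorded, not
fatal.

Problem sizes throughout (195 patients, 86 candidates, 50 folds, 10⁴-screen
null calibrations) are the package's working defaults; they complete in
seconds to a couple of minutes on one CPU.

## Numerical and design notes

- Degenerate inputs (zero pooled variance, constant groups, constant
  predictors or targets) return explicit degenerate flags or NaN rather
  than raising, so batch screens never abort on one pathological column.
- The global seed fans out to per-stage seeds by fixed offsets; identical
  config + seed reproduce every artifact byte-for-byte (the config hash is
  stamped into all JSON outputs).
- BMI stratum draws are clipped at the recorded 2-decimal precision
  (24.99, 29.99) so rounding cannot move a patient across a stratum edge.
- The reported non-significant age correlation and the reported
  surgery-type comparison are treated as qualitative statements only: the
  source prints no r for the former, and the latter's printed F and p are
  mutually inconsistent, so neither is used as a numeric check.

## Known limitations

The index inherits the assumptions of the mass-balance model: a single
well-mixed blood compartment, EBV constant over the measurement window, and
an aliquot drain-Hb representative of the whole 18-h drainage. Cell-salvage
return, insensible losses and plasma-volume shifts are not modelled. The
eight-model comparison characterizes this synthetic cohort; its headline
metrics are not estimates of real-data performance.
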