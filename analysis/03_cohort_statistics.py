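"""Stratified comparisons and Spearman screening of the Hb/kg index.

Reads results/index.csv; writes results/comparisons.csv and
results/screening.csv. Reports the gender t test, the BMI-group ANOVA with
eta-squared and Scheffe post-hoc, the drainage-volume comparison, the age
correlation, and which candidate predictors the screen retains.

Usage: python analysis/03_cohort_statistics.py [--out results] [--alpha 0.05]
"""

import argparse
from pathlib import Path

import pandas as pd

from hbkg.index import CTD_HOUR_COLUMNS, classify_bmi_group, classify_ctd_group
from hbkg.simulate import TRUE_PREDICTORS, candidate_predictor_columns
from hbkg.stats import (
    compare_k_groups,
    compare_two_groups,
    correlate_age,
    screen_predictors,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    df = pd.read_csv(args.out / "index.csv")
    y = df["hbkg_index"].to_numpy()

    gender = compare_two_groups(y, df["sex"], "gender")
    bmi = compare_k_groups(y, df["bmi"].map(classify_bmi_group), "bmi_group")
    surgery = compare_k_groups(y, df["surgery_type"], "surgery_type")
    ctd_total = df[list(CTD_HOUR_COLUMNS)].sum(axis=1)
    ctd = compare_two_groups(y, ctd_total.map(classify_ctd_group), "ctd_group")
    r_age, p_age = correlate_age(y, df["age"])

    rows = []
    for c in (gender, bmi, surgery, ctd):
        rows.append({
            "stratification": c.stratification,
            "groups": "|".join(map(str, c.group_labels)),
            "ns": "|".join(map(str, c.group_ns)),
            "means": "|".join(f"{m:.3f}" for m in c.group_means),
            "sds": "|".join(f"{s:.3f}" for s in c.group_sds),
            "statistic": c.statistic, "dfs": "|".join(f"{d:g}" for d in c.dfs),
            "p_value": c.p_value, "eta_squared": c.eta_squared,
        })
    pd.DataFrame(rows).to_csv(args.out / "comparisons.csv", index=False)

    def fmt(c):
        kind = "t" if len(c.dfs) == 1 else "F"
        dfs = ", ".join(f"{d:g}" for d in c.dfs)
        extra = f", eta2 = {c.eta_squared:.3f}" if c.eta_squared is not None else ""
        means = ", ".join(f"{g}={m:.2f}" for g, m in
                          sorted(zip(c.group_labels, c.group_means)))
        return (f"{c.stratification}: {kind}({dfs}) = {c.statistic:.3f}, "
                f"p = {c.p_value:.4f}{extra}  means: {means}")

    print(fmt(gender))
    print(fmt(bmi))
    for (i, j), p in bmi.posthoc_pairs:
        print(f"  Scheffe {bmi.group_labels[i]} vs {bmi.group_labels[j]}: p = {p:.4f}")
    print(fmt(surgery))
    print(fmt(ctd))
    print(f"age: Pearson r = {r_age:.3f}, p = {p_age:.3f}")

    screening = screen_predictors(df, y, candidate_predictor_columns(df),
                                  alpha=args.alpha)
    screening.to_csv(args.out / "screening.csv", index=False)
    retained = screening[screening.retained].sort_values("rho", key=abs,
                                                         ascending=False)
    print(f"\nscreening: {len(retained)} of {len(screening)} candidates retained "
          f"at alpha = {args.alpha}")
    print("  strongest:", ", ".join(
        f"{r.predictor} (rho={r.rho:+.2f})" for r in retained.head(6).itertuples()))
    missing = [p for p in TRUE_PREDICTORS if p not in set(retained.predictor)]
    print(f"  designated true predictors retained: "
          f"{len(TRUE_PREDICTORS) - len(missing)}/{len(TRUE_PREDICTORS)}"
          + (f" (missing: {missing})" if missing else ""))
    print(f"wrote {args.out/'comparisons.csv'}, screening.csv")


if __name__ == "__main__":
    main()
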