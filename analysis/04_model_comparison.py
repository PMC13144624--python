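"""Cross-validated comparison of the eight-model suite on the Hb/kg index.

Reads results/index.csv and results/screening.csv; writes
results/model_report.csv and the predicted-vs-true pairs of the lasso-OLS
refit (results/lasso_ols_predictions.csv). Reports each model's held-out
MSE, MAPE, correlation and R^2 as mean +/- SD over 5-fold x 10-repeat CV,
ranked by MSE.

Usage: python analysis/04_model_comparison.py [--seed N] [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from hbkg.io import PipelineConfig
from hbkg.models import LassoOLS, run_comparison
from hbkg.simulate import TRUE_PREDICTORS, candidate_predictor_columns
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    df = pd.read_csv(args.out / "index.csv")
    y = df["hbkg_index"].to_numpy()
    predictors = candidate_predictor_columns(df)
    screening = pd.read_csv(args.out / "screening.csv")
    retained = screening.loc[screening.retained, "predictor"].tolist()

    report = run_comparison(df[predictors], y, retained=retained,
                            n_splits=cfg.cv_splits, n_repeats=cfg.cv_repeats,
                            seed=cfg.stage_seed("model"))
    report.to_csv(args.out / "model_report.csv", index=False)

    print("model comparison, 5-fold x 10 repeats (mean +/- SD across folds):")
    for r in report.itertuples():
        print(f"  {r.rank_by_mse}. {r.model:<18} MSE {r.mse_mean:.3f}+/-{r.mse_sd:.3f}  "
              f"MAPE {r.mape_mean:.3f}+/-{r.mape_sd:.3f}  "
              f"corr {r.corr_mean:.3f}+/-{r.corr_sd:.3f}  "
              f"R2 {r.r2_mean:.3f}+/-{r.r2_sd:.3f}")
    best = report.iloc[0]
    support = best.selected_features.split(",") if best.selected_features else []
    print(f"best by MSE: {best.model}"
          + (f"; support of {len(support)} features includes "
             f"{sum(p in support for p in TRUE_PREDICTORS)}/4 designated true "
             f"predictors" if support else ""))

    # full-data relaxed-lasso fit behind the predicted-vs-true export
    pipe = Pipeline([("scale", StandardScaler()),
                     ("model", LassoOLS(random_state=cfg.stage_seed("model")))])
    pipe.fit(df[predictors], y)
    pd.DataFrame({"true_index": y, "predicted_index": pipe.predict(df[predictors])}
                 ).to_csv(args.out / "lasso_ols_predictions.csv", index=False)
    print(f"wrote {args.out/'model_report.csv'}, lasso_ols_predictions.csv")


if __name__ == "__main__":
    main()
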