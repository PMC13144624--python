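"""Cross-validated comparison of eight regressors predicting the Hb/kg index.

The suite mirrors a common clinical-tabular benchmark: ordinary linear
regression, Lasso, Lasso followed by an OLS refit on the selected support
(relaxed lasso), RBF-kernel support-vector regression, k-nearest neighbours,
a decision tree, gradient-boosted trees (XGBoost) and a small multilayer
perceptron. Sparse models (lasso, lasso_ols) see the full candidate matrix
and select internally; all others receive only the Spearman-retained
features. Features are standardized inside each training fold (no leakage)
and per-fold MSE, MAPE, Pearson correlation and R^2 are aggregated as
mean +/- SD across all folds of a repeated k-fold scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.model_selection import RepeatedKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "LassoOLS",
    "default_model_specs",
    "compute_metrics",
    "fit_lasso_ols",
    "run_comparison",
]

MODEL_NAMES = (
    "linear",
    "lasso",
    "lasso_ols",
    "svm",
    "knn",
    "decision_tree",
    "gradient_boosting",
    "neural_net",
)

#: Records with |index| below this (g/kg) are excluded from MAPE only; a
#: relative error against a near-zero index is uninformative.
MAPE_MIN_ABS = 0.05


@dataclass
class ModelSpec:
    """One entry of the comparison suite."""

    name: str
    estimator: object
    uses_internal_selection: bool = False
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")


class LassoOLS(BaseEstimator, RegressorMixin):
    """Lasso support selection followed by an OLS refit (relaxed lasso).

    The L1 penalty is chosen by inner cross-validation over a logarithmic
    path; the final coefficients are the unpenalized least-squares fit on the
    selected support, which removes the shrinkage bias. An empty support
    falls back to an intercept-only model.
    """

    def __init__(self, cv: int = 5, n_alphas: int = 100, random_state: int = 0,
                 rule: str = "min", alpha: float | None = None):
        self.cv = cv
        self.n_alphas = n_alphas
        self.random_state = random_state
        self.rule = rule  # 'min' (CV-optimal) or '1se' (sparser)
        self.alpha = alpha  # fixed penalty; skips the inner CV when set

    def fit(self, X, y):
        from sklearn.linear_model import Lasso

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.alpha is not None:
            lasso = Lasso(alpha=self.alpha, max_iter=50_000).fit(X, y)
            self.support_ = np.flatnonzero(lasso.coef_ != 0)
            self.alpha_ = float(self.alpha)
            return self._refit(X, y)
        lasso = LassoCV(cv=self.cv, alphas=self.n_alphas,
                        random_state=self.random_state, max_iter=50_000)
        lasso.fit(X, y)
        alpha = lasso.alpha_
        if self.rule == "1se":
            # largest penalty whose mean CV error is within one standard
            # error of the minimum: fewer false selections
            mean = lasso.mse_path_.mean(axis=1)
            se = lasso.mse_path_.std(axis=1, ddof=1) / np.sqrt(lasso.mse_path_.shape[1])
            cutoff = mean.min() + se[np.argmin(mean)]
            alpha = float(np.max(lasso.alphas_[mean <= cutoff]))
            from sklearn.linear_model import Lasso
            lasso = Lasso(alpha=alpha, max_iter=50_000).fit(X, y)
        elif self.rule != "min":
            raise ValueError(f"unknown penalty rule {self.rule!r}")
        self.support_ = np.flatnonzero(lasso.coef_ != 0)
        self.alpha_ = alpha
        return self._refit(X, y)

    def _refit(self, X, y):
        self.coef_ = np.zeros(X.shape[1])
        if self.support_.size == 0:
            self.intercept_ = float(y.mean())
        else:
            ols = LinearRegression().fit(X[:, self.support_], y)
            self.coef_[self.support_] = ols.coef_
            self.intercept_ = float(ols.intercept_)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    """The eight-model suite with conventional, config-exposed defaults."""
    return [
        ModelSpec("linear", LinearRegression()),
        ModelSpec("lasso",
                  LassoCV(cv=5, alphas=100, random_state=seed, max_iter=50_000),
                  uses_internal_selection=True,
                  hyperparameters={"cv": 5, "n_alphas": 100}),
        ModelSpec("lasso_ols", LassoOLS(cv=5, n_alphas=100, random_state=seed),
                  uses_internal_selection=True,
                  hyperparameters={"cv": 5, "n_alphas": 100}),
        ModelSpec("svm", SVR(kernel="rbf", C=1.0, epsilon=0.1),
                  hyperparameters={"kernel": "rbf", "C": 1.0}),
        ModelSpec("knn", KNeighborsRegressor(n_neighbors=5),
                  hyperparameters={"k": 5}),
        ModelSpec("decision_tree",
                  DecisionTreeRegressor(min_samples_leaf=5, random_state=seed),
                  hyperparameters={"min_samples_leaf": 5}),
        ModelSpec("gradient_boosting",
                  XGBRegressor(n_estimators=300, max_depth=3, learning_rate=0.05,
                               subsample=0.9, random_state=seed, n_jobs=1,
                               verbosity=0),
                  hyperparameters={"n_estimators": 300, "max_depth": 3}),
        ModelSpec("neural_net",
                  MLPRegressor(hidden_layer_sizes=(64, 32), early_stopping=True,
                               max_iter=500, random_state=seed),
                  hyperparameters={"hidden_layers": (64, 32)}),
    ]


def compute_metrics(y_true, y_pred, mape_min_abs: float = MAPE_MIN_ABS):
    """(mse, mape, corr, r2) for one held-out fold.

    mse = mean squared residual; mape = mean(|y - yhat| / |y|) over records
    with |y| >= ``mape_min_abs``; corr = Pearson r of (y, yhat); r2 = 1 -
    SS_res/SS_tot. Degenerate cases (constant y or yhat) yield NaN corr; a
    constant y yields NaN r2.
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    resid = y - yhat
    mse = float(np.mean(resid**2))
    ok = np.abs(y) >= mape_min_abs
    mape = float(np.mean(np.abs(resid[ok]) / np.abs(y[ok]))) if ok.any() else np.nan
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        corr, r2 = np.nan, np.nan
    else:
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        corr = np.nan if np.std(yhat) == 0 else float(sps.pearsonr(y, yhat)[0])
    return mse, mape, corr, r2


def fit_lasso_ols(X, y, cv: int = 5, n_alphas: int = 100, seed: int = 0,
                  rule: str = "min"):
    """Standardize, select by cross-validated lasso, refit OLS on the support.

    ``rule='1se'`` picks the sparser one-standard-error penalty instead of
    the CV-optimal one. Returns ``(support_indices, refit_coefficients)`` on
    the standardized scale; coefficients are zero off-support.
    """
    scaler = StandardScaler().fit(X)
    model = LassoOLS(cv=cv, n_alphas=n_alphas, random_state=seed, rule=rule)
    model.fit(scaler.transform(X), y)
    return model.support_, model.coef_


def run_comparison(
    features: pd.DataFrame,
    target,
    specs: list[ModelSpec] | None = None,
    retained: list[str] | None = None,
    n_splits: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated k-fold comparison of the model suite.

    ``features`` is the full candidate matrix; models without internal
    selection are restricted to the ``retained`` columns (the Spearman
    screen), while lasso and lasso_ols see every column. Standardization is
    fit on each training fold only, inside a Pipeline, so no information
    leaks from held-out rows. Folds whose held-out target is constant are
    skipped and counted. Returns one row per model with mean/sd of each
    metric across folds, ranked by mean MSE, plus the features selected by
    the sparse models on the full data.
    """
    y = np.asarray(target, dtype=float)
    if features.isna().any().any():
        raise ValueError("feature matrix must be free of missing values")
    specs = specs if specs is not None else default_model_specs(seed)
    if len(y) < 2 * n_splits:
        raise ValueError("need n >= 2 x folds")
    X_full = features.to_numpy(dtype=float)
    cols = list(features.columns)
    kept = [c for c in (retained if retained is not None else cols) if c in cols]
    X_kept = features[kept].to_numpy(dtype=float)

    cv = RepeatedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    splits = list(cv.split(X_full))

    rows = []
    for spec in specs:
        X = X_full if spec.uses_internal_selection else X_kept
        fold_metrics, skipped, failures = [], 0, 0
        for train, test in splits:
            if np.std(y[test]) == 0:
                skipped += 1
                continue
            pipe = Pipeline([("scale", StandardScaler()),
                             ("model", clone(spec.estimator))])
            try:
                pipe.fit(X[train], y[train])
                yhat = pipe.predict(X[test])
            except Exception:  # a model failure is recorded, not fatal
                failures += 1
                continue
            fold_metrics.append(compute_metrics(y[test], yhat))
        m = np.asarray(fold_metrics, dtype=float)
        row = {"model": spec.name, "n_folds": len(m), "folds_skipped": skipped,
               "fit_failures": failures}
        for j, name in enumerate(("mse", "mape", "corr", "r2")):
            row[f"{name}_mean"] = float(np.nanmean(m[:, j])) if len(m) else np.nan
            row[f"{name}_sd"] = float(np.nanstd(m[:, j], ddof=1)) if len(m) > 1 else np.nan
        if spec.uses_internal_selection:
            pipe = Pipeline([("scale", StandardScaler()),
                             ("model", clone(spec.estimator))]).fit(X_full, y)
            est = pipe.named_steps["model"]
            support = np.flatnonzero(est.coef_ != 0) if hasattr(est, "coef_") else []
            row["selected_features"] = ",".join(cols[i] for i in support)
        else:
            row["selected_features"] = ""
        rows.append(row)

    report = pd.DataFrame(rows)
    report["rank_by_mse"] = report["mse_mean"].rank(method="min").astype(int)
    return report.sort_values("rank_by_mse").reset_index(drop=True)
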