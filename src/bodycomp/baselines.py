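"""Supervised comparison models under the shared evaluation protocol.

The estimators themselves are delegated to established implementations
(scikit-learn, XGBoost); what this module owns is the protocol around them:
fold-internal standard scaling (fit on the training fold only), repeated
standard K-fold cross-validation, and the shared RMSE% metric and results
schema, so supervised and graph-based results can be reported jointly.

Least-squares SVR is realized as RBF kernel ridge regression, which solves
the same squared-loss kernel problem. The multilayer perceptron uses ReLU
activation, the Adam optimizer and an L2 penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import BayesianRidge, Lasso, LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .evaluation import RESULT_COLUMNS, CVPlan, make_splits, rmse_percent
from .preprocessing import zscore_apply, zscore_fit
from .synthetic_cohort import Cohort

__all__ = ["BaselineSpec", "fit_baseline", "predict_baseline", "run_baseline_experiment",
           "default_baseline_specs", "FAMILIES"]

FAMILIES = (
    "linear",
    "ridge",
    "lasso",
    "bayesian",
    "polynomial",
    "svr",
    "lssvr",
    "random_forest",
    "gradient_boosting",
    "mlp",
)


@dataclass
class BaselineSpec:
    """One supervised model family plus its hyperparameters.

    Hyperparameter keys follow each family's convention: svr uses ``epsilon``
    and ``C``; lssvr uses ``gamma`` and ``C``; tree ensembles use
    ``n_estimators`` and ``max_depth``; mlp uses ``epochs`` (and optionally
    ``hidden``, ``alpha``); polynomial uses ``degree`` and ``alpha``.
    """

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def _make_estimator(spec: BaselineSpec, seed: int):
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "linear":
        return LinearRegression()
    if fam == "ridge":
        return Ridge(alpha=hp.get("alpha", 1.0))
    if fam == "lasso":
        return Lasso(alpha=hp.get("alpha", 0.1), max_iter=10_000)
    if fam == "bayesian":
        return BayesianRidge()
    if fam == "polynomial":
        return make_pipeline(
            PolynomialFeatures(degree=hp.get("degree", 2), include_bias=False),
            Ridge(alpha=hp.get("alpha", 1.0)),
        )
    if fam == "svr":
        return SVR(kernel="rbf", epsilon=hp.get("epsilon", 0.1), C=hp.get("C", 1.0))
    if fam == "lssvr":
        # squared-loss SVR == kernel ridge with RBF kernel; C maps to 1/(2*alpha)
        return KernelRidge(kernel="rbf", gamma=hp.get("gamma", 0.001),
                           alpha=1.0 / (2.0 * hp.get("C", 1.0)))
    if fam == "random_forest":
        return RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 50),
            max_depth=hp.get("max_depth", 15),
            random_state=seed,
        )
    if fam == "gradient_boosting":
        return XGBRegressor(
            n_estimators=hp.get("n_estimators", 35),
            max_depth=hp.get("max_depth", 5),
            random_state=seed,
            verbosity=0,
        )
    if fam == "mlp":
        return MLPRegressor(
            hidden_layer_sizes=hp.get("hidden", (64, 32)),
            activation="relu",
            solver="adam",
            alpha=hp.get("alpha", 1e-3),
            max_iter=hp.get("epochs", 200),
            random_state=seed,
        )
    raise ValueError(f"unknown model family {fam!r}")  # unreachable


def fit_baseline(spec: BaselineSpec, X_train: np.ndarray, y_train: np.ndarray, seed: int = 0):
    """Fit one supervised model; deterministic given ``seed``."""
    if len(X_train) == 0:
        raise ValueError("training set is empty")
    model = _make_estimator(spec, seed)
    model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=float))
    return model


def predict_baseline(model, X_test: np.ndarray) -> np.ndarray:
    pred = np.asarray(model.predict(np.asarray(X_test, dtype=float)), dtype=float)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("baseline produced non-finite predictions")
    return pred


def default_baseline_specs() -> list[BaselineSpec]:
    """One spec per family at protocol-level default hyperparameters."""
    return [BaselineSpec(family=f) for f in FAMILIES]


def run_baseline_experiment(
    cohort: Cohort,
    specs: Sequence[BaselineSpec],
    cv: CVPlan,
    target: str = "ALM",
    dataset: str = "combined",
) -> pd.DataFrame:
    """Repeated standard K-fold evaluation of the supervised models.

    Scaling discipline: the z-score scaler is fit on the training fold only
    and applied to both folds, so no test-fold statistics leak into the fit.
    Output uses the shared results schema (p and k are NaN here).
    """
    from .evaluation import _select_stratum  # shared stratum selection

    if cv.mode != "standard":
        raise ValueError("supervised baselines use standard K-fold CV")
    data = _select_stratum(cohort, dataset)
    X = data.X
    y = data.y(target)
    rows = []
    for run in range(cv.repeats):
        splits = make_splits(data.n, cv, run)
        for fold, (train, test) in enumerate(splits):
            scaler = zscore_fit(X[train])
            Xtr, Xte = zscore_apply(scaler, X[train]), zscore_apply(scaler, X[test])
            for spec in specs:
                seed = int(np.random.SeedSequence([cv.seed, run, fold]).generate_state(1)[0] % (2**31))
                model = fit_baseline(spec, Xtr, y[train], seed=seed)
                pred = predict_baseline(model, Xte)
                rows.append(
                    {
                        "target": target,
                        "dataset": dataset,
                        "variant": spec.family,
                        "p": np.nan,
                        "k": np.nan,
                        "training_percent": cv.training_percent,
                        "run": run,
                        "fold": fold,
                        "rmse_percent": rmse_percent(y[test], pred),
                    }
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
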