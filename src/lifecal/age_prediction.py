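"""Transcriptome age prediction with RBF support-vector regression.

Nested cross-validation: an outer 10-fold split isolates test folds;
inside each outer fold, probes are ranked by the p-value of a simple
linear regression of expression on age (so the test fold never
influences probe selection), the top N_cutoff probes are kept, and an
inner 10-fold grid search — a coarse base-2 grid over the kernel width
gamma and cost C, then a fine grid around the coarse optimum — selects
the hyperparameters minimizing squared error.  Accuracy is the mean
absolute error |age_actual - age_predicted| over all outer test
predictions; the defaults (N_cutoff 40 for human, 100 for mouse) follow
typical microarray panel sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .datamodel import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class PredictionModelSpec:
    """Feature count, hyperparameter grids (base-2 exponents) and folds."""

    n_cutoff: int = 40
    coarse_gamma_exp: np.ndarray = field(
        default_factory=lambda: np.arange(-15, 14, 2, dtype=float))
    coarse_cost_exp: np.ndarray = field(
        default_factory=lambda: np.arange(-5, 16, 2, dtype=float))
    fine_halfwidth: float = 1.5
    fine_step: float = 0.125
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be at least 2")
        if len(self.coarse_gamma_exp) == 0 or len(self.coarse_cost_exp) == 0:
            raise ValueError("empty hyperparameter grid")


@dataclass
class PredictionResult:
    """Out-of-fold predictions plus the per-fold model choices."""

    predictions: pd.DataFrame      # sample_id, age_actual, age_predicted, outer_fold
    accuracy: float                # mean |actual - predicted|
    r_squared: float
    fold_hyperparams: list[dict]
    fold_features: list[list[str]]
    fold_train_samples: list[list[str]]


# ---------------------------------------------------------------------------
# feature ranking
# ---------------------------------------------------------------------------

def rank_features_by_age(values: pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
    """Rank features by the slope p-value of expression ~ age (simple
    regression, vectorized through the correlation with age); constant
    features get p = 1 and rank last."""
    X = values.to_numpy(dtype=float)
    a = np.asarray(ages, dtype=float)
    n = len(a)
    if n < 10:
        raise ValueError("need at least 10 samples to rank features")
    a_c = a - a.mean()
    X_c = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((X_c ** 2).sum(axis=1) * (a_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, X_c @ a_c / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1e-300, 1.0 - r ** 2))
    from scipy import stats
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(denom > 0, p, 1.0)
    out = pd.DataFrame({"feature_id": values.index, "p_value": p,
                        "r_squared": r ** 2})
    out = out.sort_values(["p_value", "feature_id"], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def _svr_pipeline() -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])


def _grid_search(X: np.ndarray, y: np.ndarray, gamma_exp: np.ndarray,
                 cost_exp: np.ndarray, inner_folds: int, seed: int):
    cv = KFold(n_splits=min(inner_folds, len(y)), shuffle=True, random_state=seed)
    grid = {"svr__gamma": 2.0 ** np.asarray(gamma_exp, dtype=float),
            "svr__C": 2.0 ** np.asarray(cost_exp, dtype=float)}
    search = GridSearchCV(_svr_pipeline(), grid,
                          scoring="neg_mean_squared_error", cv=cv, n_jobs=None)
    search.fit(X, y)
    best = search.best_params_
    return (float(np.log2(best["svr__gamma"])), float(np.log2(best["svr__C"])),
            float(-search.best_score_))


def _tune(X: np.ndarray, y: np.ndarray, spec: PredictionModelSpec, seed: int):
    """Coarse then fine grid search; returns (gamma_exp, cost_exp, sse)."""
    g1, c1, _ = _grid_search(X, y, spec.coarse_gamma_exp, spec.coarse_cost_exp,
                             spec.inner_folds, seed)
    offsets = np.arange(-spec.fine_halfwidth, spec.fine_halfwidth + spec.fine_step / 2,
                        spec.fine_step)
    g2, c2, mse = _grid_search(X, y, g1 + offsets, c1 + offsets,
                               spec.inner_folds, seed)
    return g2, c2, mse * len(y)


def nested_cv_predict(ds: ExpressionDataset,
                      spec: PredictionModelSpec | None = None) -> PredictionResult:
    """Predict every sample's age from its outer test fold."""
    spec = spec or PredictionModelSpec()
    if ds.n_samples < 30:
        raise ValueError("need at least 30 samples for nested cross-validation")
    n_cutoff = spec.n_cutoff
    if n_cutoff > ds.n_features:
        logger.warning("n_cutoff %d exceeds %d available features; capped",
                       n_cutoff, ds.n_features)
        n_cutoff = ds.n_features

    ages = ds.sample_age
    sample_ids = np.asarray(ds.samples.index)
    outer = KFold(n_splits=spec.outer_folds, shuffle=True, random_state=spec.seed)
    pred = np.full(ds.n_samples, np.nan)
    fold_of = np.full(ds.n_samples, -1)
    hyper, feats, train_sets = [], [], []

    for k, (train_idx, test_idx) in enumerate(outer.split(ages)):
        train_values = ds.values.iloc[:, train_idx]
        ranking = rank_features_by_age(train_values, ages[train_idx])
        top = list(ranking["feature_id"].iloc[:n_cutoff])
        X_train = ds.values.loc[top].iloc[:, train_idx].to_numpy(dtype=float).T
        X_test = ds.values.loc[top].iloc[:, test_idx].to_numpy(dtype=float).T
        y_train = ages[train_idx]

        g, c, _ = _tune(X_train, y_train, spec, seed=spec.seed + k)
        model = _svr_pipeline().set_params(svr__gamma=2.0 ** g, svr__C=2.0 ** c)
        model.fit(X_train, y_train)
        pred[test_idx] = model.predict(X_test)
        fold_of[test_idx] = k
        hyper.append({"gamma_exp": g, "cost_exp": c})
        feats.append(top)
        train_sets.append(list(sample_ids[train_idx]))

    predictions = pd.DataFrame({"sample_id": sample_ids, "age_actual": ages,
                                "age_predicted": pred, "outer_fold": fold_of})
    accuracy = float(np.abs(ages - pred).mean())
    return PredictionResult(predictions, accuracy,
                            float(r2_score(ages, pred)), hyper, feats, train_sets)


def select_n_cutoff(ds: ExpressionDataset, candidates,
                    spec: PredictionModelSpec | None = None) -> pd.DataFrame:
    """Cross-validated SSE per candidate feature count.

    Per fold, features are ranked on the training split only; the coarse
    grid picks hyperparameters.  Selection of the final N is left to the
    user (the smallest N with near-optimal SSE is the usual choice).
    """
    spec = spec or PredictionModelSpec()
    ages = ds.sample_age
    cv = KFold(n_splits=min(spec.inner_folds, ds.n_samples), shuffle=True,
               random_state=spec.seed)
    rows = []
    for n in candidates:
        n_eff = min(int(n), ds.n_features)
        sse = 0.0
        for train_idx, val_idx in cv.split(ages):
            ranking = rank_features_by_age(ds.values.iloc[:, train_idx], ages[train_idx])
            top = list(ranking["feature_id"].iloc[:n_eff])
            X_tr = ds.values.loc[top].iloc[:, train_idx].to_numpy(float).T
            X_va = ds.values.loc[top].iloc[:, val_idx].to_numpy(float).T
            g, c, _ = _grid_search(X_tr, ages[train_idx], spec.coarse_gamma_exp,
                                   spec.coarse_cost_exp, spec.inner_folds, spec.seed)
            model = _svr_pipeline().set_params(svr__gamma=2.0 ** g, svr__C=2.0 ** c)
            model.fit(X_tr, ages[train_idx])
            sse += float(((model.predict(X_va) - ages[val_idx]) ** 2).sum())
        rows.append({"n_cutoff": int(n), "sse": sse})
    return pd.DataFrame(rows)
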