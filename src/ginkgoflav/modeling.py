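"""Regression of leaf TFC on mean spectra: split, grid search, predict.

Six model families are compared — SVR (RBF kernel), partial least squares
(PLSR), Bayesian ridge (BR), ordinary least squares, Lasso and Ridge — each
tuned by exhaustive grid search with k-fold cross-validation on the
training split only, scored by cross-validated RMSE.  The winning
configuration is refitted on the full training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import (
    BayesianRidge, Lasso, LinearRegression, Ridge)
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from . import evaluation
from .preprocessing import FittedPreprocessor, PreprocessConfig
from .segmentation import band_columns

FAMILIES = ("svr", "plsr", "br", "linear", "lasso", "ridge")

# Default experiment: all six families on raw spectra, plus the two
# best-performing families crossed with every pretreatment.
DEFAULT_PAIRS = [(fam, "raw") for fam in FAMILIES] + [
    (fam, method)
    for fam in ("plsr", "br")
    for method in ("msc", "snv", "savgol")
]


@dataclass
class SplitDataset:
    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    is_train: np.ndarray  # bool per row
    seed: int

    @property
    def n_train(self) -> int:
        return int(self.is_train.sum())

    @property
    def n_test(self) -> int:
        return int((~self.is_train).sum())


@dataclass
class ModelRun:
    family: str
    preprocessing: str
    best_params: dict
    seed: int
    metrics_train: dict
    metrics_test: dict
    ids_train: list[str] = field(default_factory=list)
    ids_test: list[str] = field(default_factory=list)
    y_train: list[float] = field(default_factory=list)
    y_test: list[float] = field(default_factory=list)
    pred_train: list[float] = field(default_factory=list)
    pred_test: list[float] = field(default_factory=list)
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "preprocessing": self.preprocessing,
            "best_params": self.best_params,
            "seed": self.seed,
            "metrics_train": self.metrics_train,
            "metrics_test": self.metrics_test,
            "ids_train": self.ids_train,
            "ids_test": self.ids_test,
            "y_train": self.y_train,
            "y_test": self.y_test,
            "pred_train": self.pred_train,
            "pred_test": self.pred_test,
            "error": self.error,
        }


def split_dataset(table: pd.DataFrame, ratio_train: float = 0.8,
                  seed: int = 0) -> SplitDataset:
    """Uniform random train/test split without replacement;
    train count = round(ratio_train * n)."""
    if not 0 < ratio_train < 1:
        raise ValueError("ratio_train must lie in (0, 1)")
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_train = int(round(ratio_train * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"ratio {ratio_train} yields an empty split for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    is_train = np.zeros(n, dtype=bool)
    is_train[perm[:n_train]] = True
    cols = band_columns(table)
    return SplitDataset(
        X=table[cols].to_numpy(dtype=float),
        y=table["tfc"].to_numpy(dtype=float),
        ids=list(table["sample_id"]),
        is_train=is_train,
        seed=seed,
    )


def _family_spec(family: str, n_train: int, n_features: int,
                 cv_folds: int) -> tuple[object, dict]:
    """Estimator prototype and hyperparameter grid for one family."""
    if family == "svr":
        return SVR(kernel="rbf"), {
            "C": [0.1, 1.0, 10.0, 100.0],
            "epsilon": [0.01, 0.1, 1.0],
            "gamma": ["scale", 0.01, 0.001],
        }
    if family == "plsr":
        # components can't exceed features or the smallest CV training fold
        max_comp = min(20, n_features,
                       n_train - (n_train // cv_folds) - 1)
        return PLSRegression(), {
            "n_components": list(range(2, max(max_comp, 2) + 1))}
    if family == "br":
        return BayesianRidge(), {}
    if family == "linear":
        return LinearRegression(), {}
    if family == "lasso":
        return Lasso(max_iter=50000), {
            "alpha": [float(a) for a in np.logspace(-4, 4, 9)]}
    if family == "ridge":
        return Ridge(), {"alpha": [float(a) for a in np.logspace(-4, 4, 9)]}
    raise ValueError(f"unknown model family {family!r}; expected one of "
                     f"{FAMILIES}")


def grid_search_fit(X: np.ndarray, y: np.ndarray, family: str,
                    cv_folds: int = 5, seed: int = 0):
    """Exhaustive grid search by k-fold CV RMSE on the training rows;
    returns ``(fitted_model, best_params)``.  Families without
    hyperparameters are fitted directly.  Ties go to the first grid point
    in enumeration order."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if len(y) < cv_folds:
        raise ValueError("fewer training rows than CV folds")
    proto, grid = _family_spec(family, len(y), X.shape[1], cv_folds)
    if not grid:
        model = clone(proto).fit(X, y)
        return model, {}
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        proto, grid, scoring="neg_root_mean_squared_error", cv=cv,
        refit=True, error_score=np.nan)
    search.fit(X, y)
    if not np.isfinite(search.best_score_):
        raise RuntimeError(f"every grid point failed for family {family}")
    return search.best_estimator_, dict(search.best_params_)


def predict_tfc(model, X: np.ndarray) -> np.ndarray:
    """One finite TFC prediction (mg·g⁻¹) per row."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0)
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(
            f"model expects {n_expected} bands, got {X.shape[1]}")
    pred = np.asarray(model.predict(X), dtype=float).reshape(X.shape[0], -1)
    return pred[:, 0]


def run_comparison(
    table: pd.DataFrame,
    families: list[str] | None = None,
    preprocess_methods: list[str] | None = None,
    seed: int = 0,
    *,
    ratio_train: float = 0.8,
    cv_folds: int = 5,
    savgol_half_window: int = 5,
    savgol_poly_order: int = 2,
) -> list[ModelRun]:
    """Fit every (family, pretreatment) combination on one shared split.

    With both lists None the default experiment runs: six families on raw
    spectra plus PLSR and BR under MSC, SNV and SavGol (12 runs).  Explicit
    lists are crossed in full.  Individual run failures are recorded on the
    returned :class:`ModelRun` and the comparison continues.
    """
    if families is not None and len(families) == 0:
        raise ValueError("families list is empty")
    if preprocess_methods is not None and len(preprocess_methods) == 0:
        raise ValueError("preprocess_methods list is empty")
    if families is None and preprocess_methods is None:
        pairs = list(DEFAULT_PAIRS)
    else:
        fams = list(families) if families is not None else list(FAMILIES)
        methods = list(preprocess_methods) if preprocess_methods is not None \
            else ["raw"]
        pairs = [(f, m) for f in fams for m in methods]

    split = split_dataset(table, ratio_train, seed)
    X_tr, X_te = split.X[split.is_train], split.X[~split.is_train]
    y_tr, y_te = split.y[split.is_train], split.y[~split.is_train]
    ids = np.asarray(split.ids, dtype=object)
    ids_tr = list(ids[split.is_train])
    ids_te = list(ids[~split.is_train])

    runs: list[ModelRun] = []
    for family, method in pairs:
        cfg = PreprocessConfig(method=method,
                               savgol_half_window=savgol_half_window,
                               savgol_poly_order=savgol_poly_order)
        try:
            prep = FittedPreprocessor(cfg).fit(X_tr)
            Z_tr, Z_te = prep.transform(X_tr), prep.transform(X_te)
            model, best = grid_search_fit(Z_tr, y_tr, family, cv_folds, seed)
            p_tr = predict_tfc(model, Z_tr)
            p_te = predict_tfc(model, Z_te)
            runs.append(ModelRun(
                family=family, preprocessing=method, best_params=best,
                seed=seed,
                metrics_train=evaluation.metrics(y_tr, p_tr),
                metrics_test=evaluation.metrics(y_te, p_te),
                ids_train=ids_tr, ids_test=ids_te,
                y_train=[float(v) for v in y_tr],
                y_test=[float(v) for v in y_te],
                pred_train=[float(v) for v in p_tr],
                pred_test=[float(v) for v in p_te],
            ))
        except Exception as exc:  # record and continue with other runs
            runs.append(ModelRun(
                family=family, preprocessing=method, best_params={},
                seed=seed, metrics_train={}, metrics_test={},
                error=f"{type(exc).__name__}: {exc}"))
    return runs
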