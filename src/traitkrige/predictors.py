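"""Trend models mapping MDS trait CWMs to ecosystem-function indices.

Three model families: partial least squares regression (linear), random
forest (100 trees) and a backpropagation feed-forward network (four hidden
layers of five logistic units, linear output, at most 500 iterations).
Rows are split 70/30 within each plot (floor(0.7 n) training rows per
plot, seed-deterministic); accuracy is reported as RMSE and MAE on the
held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

MODEL_KINDS = ("pls", "rf", "bpnn")


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0


@dataclass
class PredictionResult:
    kind: str
    model: object
    train_index: np.ndarray
    test_index: np.ndarray
    train_predictions: np.ndarray
    test_predictions: np.ndarray
    grid_predictions: np.ndarray | None
    train_residuals: np.ndarray       # observed - predicted on training rows
    rmse: float                       # on test rows
    mae: float


def split(table: pd.DataFrame, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stratified-by-plot random 70/30 split; returns (train, test) positions.

    Each plot contributes floor(train_fraction * n) training rows; every
    plot must be able to contribute both parts.
    """
    rng = np.random.default_rng(spec.seed)
    train, test = [], []
    positions = np.arange(len(table))
    for plot, grp in table.groupby("plot", sort=True):
        pos = positions[table["plot"].to_numpy() == plot]
        n = len(pos)
        n_train = int(np.floor(spec.train_fraction * n))
        if n_train < 1 or n - n_train < 1:
            raise ValueError(f"plot {plot} too small ({n} rows) for a "
                             f"{spec.train_fraction:.0%} split")
        perm = rng.permutation(pos)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def error_metrics(observed, predicted) -> tuple[float, float]:
    """(RMSE, MAE) of predictions against observations."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size == 0:
        raise ValueError("observed/predicted must be equal-length, non-empty")
    err = observed - predicted
    return float(np.sqrt(np.mean(err ** 2))), float(np.mean(np.abs(err)))


def _pls_components(X: np.ndarray, y: np.ndarray, seed: int) -> int:
    """Smallest component count within one SE of the minimum CV RMSE."""
    max_c = min(X.shape[1], X.shape[0] - 1, 10)
    if max_c <= 1:
        return 1
    n_splits = min(5, len(X))
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    mean_rmse, se_rmse = [], []
    for c in range(1, max_c + 1):
        fold_rmse = []
        for tr, va in cv.split(X):
            m = PLSRegression(n_components=c).fit(X[tr], y[tr])
            fold_rmse.append(error_metrics(y[va], m.predict(X[va]).ravel())[0])
        fold_rmse = np.array(fold_rmse)
        mean_rmse.append(fold_rmse.mean())
        se_rmse.append(fold_rmse.std(ddof=1) / np.sqrt(len(fold_rmse)))
    mean_rmse = np.array(mean_rmse)
    best = int(np.argmin(mean_rmse))
    cutoff = mean_rmse[best] + se_rmse[best]
    for c in range(len(mean_rmse)):
        if mean_rmse[c] <= cutoff:
            return c + 1
    return best + 1


def make_model(kind: str, n_features: int, X_train=None, y_train=None, seed: int = 0):
    if kind == "pls":
        n_comp = (_pls_components(np.asarray(X_train, float), np.asarray(y_train, float), seed)
                  if X_train is not None else min(2, n_features))
        return PLSRegression(n_components=n_comp)
    if kind == "rf":
        return RandomForestRegressor(n_estimators=100, random_state=seed)
    if kind == "bpnn":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(5, 5, 5, 5), activation="logistic",
                         solver="lbfgs", max_iter=500, random_state=seed))
    raise ValueError(f"unknown model kind {kind!r}; choose one of {MODEL_KINDS}")


def fit_predict(kind: str, table: pd.DataFrame, predictors: list[str], response: str,
                spec: SplitSpec | None = None, grid_table: pd.DataFrame | None = None
                ) -> PredictionResult:
    """Fit one trend model and evaluate on the held-out 30%.

    ``grid_table`` (default: the full input table) receives full-surface
    predictions for downstream kriging.
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictor traits")
    spec = spec or SplitSpec()
    y = table[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"response {response!r} is constant")
    X = table[predictors].to_numpy(dtype=float)
    tr, te = split(table, spec)

    model = make_model(kind, len(predictors), X[tr], y[tr], spec.seed)
    model.fit(X[tr], y[tr])

    def pred(Z):
        return np.asarray(model.predict(Z), dtype=float).reshape(-1)

    grid = table if grid_table is None else grid_table
    grid_pred = pred(grid[predictors].to_numpy(dtype=float))
    train_pred, test_pred = pred(X[tr]), pred(X[te])
    rmse, mae = error_metrics(y[te], test_pred)
    return PredictionResult(kind, model, tr, te, train_pred, test_pred, grid_pred,
                            y[tr] - train_pred, rmse, mae)
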