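"""Surrogate regression models and evaluation metrics.

Both screening steps use the same learner: an epsilon-support-vector
regressor with a radial-basis-function kernel, preceded by per-feature
standardisation fitted on the training rows only (RBF kernels need
comparable feature scales).  One shared hyperparameter set serves both
steps; defaults are C = 10, gamma = "scale" (1 / (n_features * var)),
epsilon = 0.01, all overridable, and :func:`tune` re-derives them by
cross-validated grid search when wanted.

Regression quality is reported as MSE / MAE / R^2; screening quality as MCC
and ROC AUC after thresholding the true APs at a cutoff (2.0 by default,
the conventional strong-aggregator line).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    matthews_corrcoef,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

DEFAULT_HYPERPARAMS: dict = {"C": 10.0, "gamma": "scale", "epsilon": 0.01}

#: AP threshold separating strong aggregators for the binary metrics.
DEFAULT_AP_CUTOFF = 2.0


class InsufficientDataError(ValueError):
    """Raised when a fit is attempted with fewer than two training rows.

    A regressor cannot be trained on a single example; the active-learning
    driver catches this and falls back to random selection for the first
    batch.
    """


@dataclass(frozen=True)
class RegressorModel:
    """An immutable fitted surrogate: scaler + SVR + the feature contract.

    ``predict`` refuses inputs whose feature names differ from those seen at
    fit time, so step-1 (Judred) and step-2 (high-resolution) models can
    never silently swap descriptor blocks.  Retraining produces a new value.
    """

    scaler: StandardScaler
    svr: SVR
    feature_names: tuple[str, ...]
    hyperparams: Mapping[str, object]
    train_size: int

    def predict(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got shape {X.shape}"
            )
        if feature_names is not None and tuple(feature_names) != self.feature_names:
            raise ValueError(
                "feature names differ from the training block; refusing to predict"
            )
        return self.svr.predict(self.scaler.transform(X))


def fit(
    X: np.ndarray,
    y: Sequence[float],
    feature_names: Sequence[str],
    hyperparams: Mapping[str, object] | None = None,
) -> RegressorModel:
    """Fit the standardise-then-SVR pipeline; deterministic for fixed inputs."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)}")
    if len(X) < 2:
        raise InsufficientDataError(
            f"cannot train a regressor on {len(X)} example(s); need >= 2"
        )
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    scaler = StandardScaler().fit(X)
    svr = SVR(kernel="rbf", **hp).fit(scaler.transform(X), y)
    return RegressorModel(
        scaler=scaler,
        svr=svr,
        feature_names=tuple(feature_names),
        hyperparams=hp,
        train_size=len(X),
    )


def tune(
    X: np.ndarray,
    y: Sequence[float],
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Grid-search hyperparameters by minimising mean CV MSE.

    Ties are broken toward the flattest model: smaller C first, then larger
    epsilon.  The CV split is seeded, so the winner is reproducible.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if folds > len(X):
        raise ValueError(f"{folds}-fold CV needs >= {folds} rows, got {len(X)}")
    grid = dict(grid or {
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": ["scale", 0.01, 0.1, 1.0],
        "epsilon": [0.001, 0.01, 0.1],
    })
    names = list(grid)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    feature_names = [f"f{i}" for i in range(X.shape[1])]

    def sort_key(item):
        hp, mse = item
        c = float(hp.get("C", DEFAULT_HYPERPARAMS["C"]))
        eps = float(hp.get("epsilon", DEFAULT_HYPERPARAMS["epsilon"]))
        return (mse, c, -eps)

    results = []
    for values in itertools.product(*(grid[n] for n in names)):
        hp = dict(zip(names, values))
        errs = []
        for tr, te in splits:
            model = fit(X[tr], y[tr], feature_names, hp)
            errs.append(mean_squared_error(y[te], model.predict(X[te])))
        results.append((hp, float(np.mean(errs))))
    return min(results, key=sort_key)[0]


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> tuple[float, float, float]:
    """(MSE, MAE, R^2); R^2 is None-flagged when the truth has zero variance."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need two equal-length vectors of >= 2 values")
    mse = float(mean_squared_error(y_true, y_pred))
    mae = float(mean_absolute_error(y_true, y_pred))
    r2 = None if np.allclose(y_true, y_true[0]) else float(r2_score(y_true, y_pred))
    return mse, mae, r2


def classification_metrics(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    cutoff: float = DEFAULT_AP_CUTOFF,
) -> tuple[float | None, float | None]:
    """(MCC, AUC) for recovering strong aggregators from predicted APs.

    The cutoff thresholds both vectors for the MCC confusion table but only
    the truth for the AUC, which ranks the raw predictions (standard ROC).
    Either metric is None-flagged when the thresholded truth has one class.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    true_cls = y_true > cutoff
    if true_cls.all() or not true_cls.any():
        return None, None
    mcc = float(matthews_corrcoef(true_cls, y_pred > cutoff))
    auc = float(roc_auc_score(true_cls, y_pred))
    return mcc, auc


def learning_curve(
    X: np.ndarray,
    y: Sequence[float],
    train_sizes: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    hyperparams: Mapping[str, object] | None = None,
) -> list[tuple[int, float]]:
    """Mean CV MSE as a function of training-set size.

    For each size, rows are subsampled (seeded, without replacement) and the
    pipeline is scored by k-fold CV on that subset.  On a learnable problem
    the curve decreases; on pure noise it is flat.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    feature_names = [f"f{i}" for i in range(X.shape[1])]
    out = []
    for size in train_sizes:
        if size > len(X):
            raise ValueError(f"train size {size} exceeds {len(X)} rows")
        idx = rng.choice(len(X), size=size, replace=False)
        Xs, ys = X[idx], y[idx]
        kf = KFold(n_splits=min(folds, size), shuffle=True, random_state=seed)
        errs = [
            mean_squared_error(
                ys[te], fit(Xs[tr], ys[tr], feature_names, hyperparams).predict(Xs[te])
            )
            for tr, te in kf.split(Xs)
        ]
        out.append((int(size), float(np.mean(errs))))
    return out


_ARCHIVE_VERSION = 1


def save_model(model: RegressorModel, path) -> None:
    """Serialise a fitted model as a JSON archive (version-checked on load)."""
    payload = {
        "archive_version": _ARCHIVE_VERSION,
        "feature_names": list(model.feature_names),
        "hyperparams": {k: v for k, v in model.hyperparams.items()},
        "train_size": model.train_size,
        "scaler": {
            "mean": model.scaler.mean_.tolist(),
            "scale": model.scaler.scale_.tolist(),
        },
        "svr": {
            "support_vectors": model.svr.support_vectors_.tolist(),
            "dual_coef": model.svr.dual_coef_.tolist(),
            "intercept": model.svr.intercept_.tolist(),
            "gamma_value": float(model.svr._gamma),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> RegressorModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("archive_version") != _ARCHIVE_VERSION:
        raise ValueError(
            f"model archive version {payload.get('archive_version')} is not "
            f"readable by this package (expected {_ARCHIVE_VERSION})"
        )
    scaler = StandardScaler()
    scaler.mean_ = np.array(payload["scaler"]["mean"])
    scaler.scale_ = np.array(payload["scaler"]["scale"])
    scaler.var_ = scaler.scale_ ** 2
    scaler.n_features_in_ = len(scaler.mean_)

    hp = payload["hyperparams"]
    svr = SVR(kernel="rbf", **hp)
    sv = np.array(payload["svr"]["support_vectors"])
    svr.support_vectors_ = sv
    svr.dual_coef_ = np.array(payload["svr"]["dual_coef"])
    svr.intercept_ = np.array(payload["svr"]["intercept"])
    svr._gamma = payload["svr"]["gamma_value"]
    svr.n_features_in_ = sv.shape[1]
    # sklearn's predict needs the remaining fitted attributes; reconstruct
    # the dual representation directly instead.
    model = RegressorModel(
        scaler=scaler,
        svr=svr,
        feature_names=tuple(payload["feature_names"]),
        hyperparams=hp,
        train_size=int(payload["train_size"]),
    )
    object.__setattr__(model, "predict", _dual_predict(model))
    return model


def _dual_predict(model: RegressorModel):
    sv = model.svr.support_vectors_
    dual = model.svr.dual_coef_.ravel()
    intercept = model.svr.intercept_.ravel()[0]
    gamma = model.svr._gamma

    def predict(X, feature_names=None):
        X = np.asarray(X, float)
        if feature_names is not None and tuple(feature_names) != model.feature_names:
            raise ValueError("feature names differ from the training block")
        Z = model.scaler.transform(X)
        d2 = ((Z[:, None, :] - sv[None, :, :]) ** 2).sum(-1)
        return np.exp(-gamma * d2) @ dual + intercept

    return predict
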