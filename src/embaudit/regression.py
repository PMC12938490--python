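"""Regularized regression on embedding features.

Continuous targets are fit with ridge regression (L2 penalty); binary targets
with logistic ridge. In both cases the embedding coordinates are standardized
(centered and scaled to unit variance) before penalization and the intercept
is left unpenalized, matching the documented default behaviour of the usual
penalized-regression tooling. The penalty weight ``lambda`` is selected by
seeded k-fold cross-validation over a grid, and the per-lambda CV loss is
retained (``cv_trace_``) so every reported number is replayable.

For the continuous case the solution at penalty ``lam`` on standardized
features ``Z`` and centered target ``y_c`` is the closed form

    coef = (Z'Z + lam * I)^{-1} Z' y_c

computed here via one SVD of ``Z`` so the whole lambda path is cheap; at
``lam = 0`` this degenerates to the minimum-norm least-squares solution. The
logistic case is delegated to scikit-learn's ``LogisticRegression`` with
``C = 1 / lambda`` (its objective is ``0.5 ||w||^2 + C * sum(loss)``, i.e.
our penalty scale exactly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from ._utils import as_1d_float, as_2d_float
from .datasets import BehaviorVector
from .encoders import EmbeddingMatrix
from .errors import DegenerateDataError, ParameterError, UsageError

__all__ = [
    "EmbeddingRidge",
    "EmbeddingLogisticRidge",
    "fit",
    "predict",
    "score",
    "ScoreBundle",
    "save_model",
    "load_model",
]


def _coerce_X(X) -> np.ndarray:
    if isinstance(X, EmbeddingMatrix):
        return X.matrix
    return as_2d_float(X, "X")


def _coerce_y(y) -> np.ndarray:
    if isinstance(y, BehaviorVector):
        return y.values
    return as_1d_float(y, "y")


def _standardize(X):
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through
    return (X - center) / scale, center, scale


def _auto_grid_continuous(n: int, n_points: int = 15) -> np.ndarray:
    # Z'Z has diagonal ~= n after standardization, so lambda/n spans the
    # effective-df range; cover from nearly-unpenalized to nearly-constant.
    return n * np.logspace(-5.0, 3.0, n_points)


def _auto_grid_binary(n_points: int = 6) -> np.ndarray:
    return np.logspace(-1.0, 4.0, n_points)


def _select_lambda(grid, fold_losses, rule):
    """Pick the penalty from per-fold CV losses.

    ``rule='min'`` takes the loss minimizer; ``rule='1se'`` (the usual
    cross-validation one-standard-error rule) takes the largest penalty whose
    mean loss is within one standard error of the minimum — preferring the
    most regularized model the CV evidence cannot distinguish from the best,
    which keeps in-sample fits from interpolating noise when p >> n.
    """
    losses = fold_losses.mean(axis=0)
    k = fold_losses.shape[0]
    best = int(np.argmin(losses))
    if rule == "min":
        return best, losses
    if rule != "1se":
        raise ParameterError(f"selection rule must be 'min' or '1se', got {rule!r}")
    se = fold_losses[:, best].std(ddof=1) / np.sqrt(k)
    threshold = losses[best] + se
    admissible = np.nonzero(losses <= threshold)[0]
    order = np.argsort(grid)
    for idx in order[::-1]:  # largest admissible lambda
        if idx in admissible:
            return int(idx), losses
    return best, losses


def _ridge_path_coefs(Z, yc, lambdas, rcond=1e-10):
    """Coefficients for every lambda from one SVD of Z."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    uty = U.T @ yc
    coefs = np.empty((len(lambdas), Z.shape[1]))
    for i, lam in enumerate(lambdas):
        if lam == 0.0:
            d = np.where(s > rcond * s.max(initial=1.0), 1.0 / np.maximum(s, 1e-300), 0.0)
        else:
            d = s / (s**2 + lam)
        coefs[i] = Vt.T @ (d * uty)
    return coefs


class EmbeddingRidge(RegressorMixin, BaseEstimator):
    """Ridge regression on standardized embedding features with CV'd penalty.

    Parameters
    ----------
    lambda_grid : "auto" or sequence of non-negative reals
        Penalty grid searched by k-fold CV (squared-error loss). A single
        value skips the search.
    k_folds : int
        Number of CV folds (>= 2); requires ``n >= k_folds``.
    random_state : int
        Seed for the fold assignment.

    Attributes
    ----------
    coef_ : (dim,) weights on the standardized coordinates.
    intercept_ : float
    lambda_ : float, selected penalty (CV-loss minimizer when a grid is used).
    cv_trace_ : dict mapping each grid lambda to its mean CV loss.
    center_, scale_ : standardization parameters stored at fit time.
    """

    mode = "continuous"

    def __init__(self, lambda_grid="auto", k_folds=10, random_state=0,
                 selection_rule="1se"):
        self.lambda_grid = lambda_grid
        self.k_folds = k_folds
        self.random_state = random_state
        self.selection_rule = selection_rule

    def _grid(self, n):
        if isinstance(self.lambda_grid, str) and self.lambda_grid == "auto":
            return _auto_grid_continuous(n)
        grid = np.atleast_1d(np.asarray(self.lambda_grid, dtype=float))
        if np.any(grid < 0):
            raise ParameterError("lambda values must be >= 0")
        return grid

    def fit(self, X, y):
        X = _coerce_X(X)
        y = _coerce_y(y)
        n = X.shape[0]
        if len(y) != n:
            raise UsageError("X and y must have the same number of rows")
        grid = self._grid(n)
        if len(grid) > 1:
            if self.k_folds < 2:
                raise UsageError("k_folds must be >= 2")
            if n < self.k_folds:
                raise UsageError(f"n = {n} is smaller than k_folds = {self.k_folds}")
            kf = KFold(n_splits=self.k_folds, shuffle=True, random_state=self.random_state)
            fold_losses = np.zeros((self.k_folds, len(grid)))
            for f, (tr, va) in enumerate(kf.split(X)):
                Ztr, center, scale = _standardize(X[tr])
                ytr = y[tr]
                mu = ytr.mean()
                coefs = _ridge_path_coefs(Ztr, ytr - mu, grid)
                Zva = (X[va] - center) / scale
                preds = mu + coefs @ Zva.T
                fold_losses[f] = ((preds - y[va]) ** 2).mean(axis=1)
            best, losses = _select_lambda(grid, fold_losses, self.selection_rule)
            self.cv_trace_ = {float(l): float(v) for l, v in zip(grid, losses)}
            self.lambda_ = float(grid[best])
        else:
            self.cv_trace_ = {}
            self.lambda_ = float(grid[0])
        Z, self.center_, self.scale_ = _standardize(X)
        mu = y.mean()
        self.coef_ = _ridge_path_coefs(Z, y - mu, [self.lambda_])[0]
        self.intercept_ = float(mu)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = _coerce_X(X)
        if X.shape[1] != self.n_features_in_:
            raise UsageError(
                f"X has {X.shape[1]} features, model was fit with {self.n_features_in_}"
            )
        Z = (X - self.center_) / self.scale_
        return self.intercept_ + Z @ self.coef_

    def fitted_values(self, X):
        """In-sample predictions; alias used by the exchange protocol."""
        return self.predict(X)


class EmbeddingLogisticRidge(ClassifierMixin, BaseEstimator):
    """Logistic ridge on standardized embedding features with CV'd penalty.

    CV loss is the binomial deviance of held-out fold predictions. Predicted
    labels use a 0.5 threshold with ties predicted positive.
    """

    mode = "binary"

    def __init__(self, lambda_grid="auto", k_folds=10, random_state=0,
                 selection_rule="1se", max_iter=2000):
        self.lambda_grid = lambda_grid
        self.k_folds = k_folds
        self.random_state = random_state
        self.selection_rule = selection_rule
        self.max_iter = max_iter

    def _grid(self):
        if isinstance(self.lambda_grid, str) and self.lambda_grid == "auto":
            return _auto_grid_binary()
        grid = np.atleast_1d(np.asarray(self.lambda_grid, dtype=float))
        if np.any(grid < 0):
            raise ParameterError("lambda values must be >= 0")
        return grid

    def _solver(self, lam):
        if lam == 0.0:
            return LogisticRegression(penalty=None, max_iter=self.max_iter)
        return LogisticRegression(C=1.0 / lam, max_iter=self.max_iter)

    def fit(self, X, y):
        X = _coerce_X(X)
        y = _coerce_y(y)
        n = X.shape[0]
        if len(y) != n:
            raise UsageError("X and y must have the same number of rows")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise UsageError("binary mode requires a 0/1 target")
        if y.min() == y.max():
            raise DegenerateDataError("constant y in binary mode: cannot fit a classifier")
        grid = self._grid()
        if len(grid) > 1:
            if self.k_folds < 2:
                raise UsageError("k_folds must be >= 2")
            if n < self.k_folds:
                raise UsageError(f"n = {n} is smaller than k_folds = {self.k_folds}")
            kf = KFold(n_splits=self.k_folds, shuffle=True, random_state=self.random_state)
            fold_losses = np.zeros((self.k_folds, len(grid)))
            for f, (tr, va) in enumerate(kf.split(X)):
                if y[tr].min() == y[tr].max():
                    raise DegenerateDataError("a CV fold received a constant y")
                Ztr, center, scale = _standardize(X[tr])
                Zva = (X[va] - center) / scale
                for i, lam in enumerate(grid):
                    clf = self._solver(lam).fit(Ztr, y[tr])
                    p = np.clip(clf.predict_proba(Zva)[:, 1], 1e-12, 1 - 1e-12)
                    fold_losses[f, i] = -2.0 * np.mean(
                        y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p)
                    )
            best, losses = _select_lambda(grid, fold_losses, self.selection_rule)
            self.cv_trace_ = {float(l): float(v) for l, v in zip(grid, losses)}
            self.lambda_ = float(grid[best])
        else:
            self.cv_trace_ = {}
            self.lambda_ = float(grid[0])
        Z, self.center_, self.scale_ = _standardize(X)
        clf = self._solver(self.lambda_).fit(Z, y)
        self.coef_ = clf.coef_.ravel().copy()
        self.intercept_ = float(clf.intercept_[0])
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = _coerce_X(X)
        if X.shape[1] != self.n_features_in_:
            raise UsageError(
                f"X has {X.shape[1]} features, model was fit with {self.n_features_in_}"
            )
        Z = (X - self.center_) / self.scale_
        logits = self.intercept_ + Z @ self.coef_
        p = np.clip(1.0 / (1.0 + np.exp(-logits)), 1e-12, 1 - 1e-12)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        # threshold 0.5, ties predicted positive
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)

    def fitted_values(self, X):
        """In-sample predicted probabilities; used by the exchange protocol."""
        return self.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit(X, y, lambda_grid="auto", k_folds=10, seed=0):
    """Fit ridge (continuous y) or logistic ridge (binary y) on embeddings."""
    mode = y.mode if isinstance(y, BehaviorVector) else "continuous"
    cls = EmbeddingLogisticRidge if mode == "binary" else EmbeddingRidge
    return cls(lambda_grid=lambda_grid, k_folds=k_folds, random_state=seed).fit(X, y)


def predict(model, X):
    """Predictions: real values (continuous) or probabilities in (0, 1) (binary)."""
    if model.mode == "binary":
        return model.predict_proba(X)[:, 1]
    return model.predict(X)


@dataclass
class ScoreBundle:
    """Metric bundle from :func:`score`.

    Continuous mode fills ``r`` (Pearson, NaN when undefined) and
    ``mean_signed_error``; binary mode fills ``accuracy`` and ``deviance_r2``.
    """

    mode: str
    r: Optional[float] = None
    r_defined: Optional[bool] = None
    mean_signed_error: Optional[float] = None
    accuracy: Optional[float] = None
    deviance_r2: Optional[float] = None

    def to_dict(self):
        return {k: v for k, v in self.__dict__.items() if v is not None or k == "r"}


def score(predictions, y, mode="continuous") -> ScoreBundle:
    """Evaluate predictions against a target.

    Continuous: Pearson r plus mean signed error; when either argument has
    zero variance the correlation is undefined and reported as NaN with
    ``r_defined=False`` (never silently 0). Binary: accuracy at the
    documented >=0.5 threshold and a deviance-based determination
    coefficient ``1 - dev(model)/dev(null)``.
    """
    pred = as_1d_float(predictions, "predictions")
    yv = _coerce_y(y)
    if len(pred) != len(yv):
        raise UsageError("predictions and y must have equal length")
    if mode == "continuous":
        signed = float(np.mean(pred - yv))
        if np.std(pred) == 0 or np.std(yv) == 0:
            return ScoreBundle(mode, r=float("nan"), r_defined=False,
                               mean_signed_error=signed)
        r = float(np.corrcoef(pred, yv)[0, 1])
        return ScoreBundle(mode, r=r, r_defined=True, mean_signed_error=signed)
    if mode == "binary":
        if not np.all(np.isin(yv, (0.0, 1.0))):
            raise UsageError("binary mode requires a 0/1 target")
        labels = (pred >= 0.5).astype(float)
        acc = float(np.mean(labels == yv))
        p = np.clip(pred, 1e-12, 1 - 1e-12)
        dev = -2.0 * np.sum(yv * np.log(p) + (1 - yv) * np.log(1 - p))
        pbar = yv.mean()
        if pbar in (0.0, 1.0):
            return ScoreBundle(mode, accuracy=acc, deviance_r2=float("nan"))
        dev_null = -2.0 * np.sum(yv * np.log(pbar) + (1 - yv) * np.log(1 - pbar))
        return ScoreBundle(mode, accuracy=acc, deviance_r2=float(1.0 - dev / dev_null))
    raise UsageError(f"unknown mode: {mode!r}")


# ---------------------------------------------------------------------------
# model persistence (full provenance for the exchange protocol)
# ---------------------------------------------------------------------------


def save_model(model, path, encoder_id: Optional[str] = None) -> None:
    payload = {
        "mode": model.mode,
        "weights": model.coef_.tolist(),
        "intercept": model.intercept_,
        "lambda": model.lambda_,
        "cv_trace": {str(k): v for k, v in model.cv_trace_.items()},
        "center": model.center_.tolist(),
        "scale": model.scale_.tolist(),
        "params": model.get_params(),
        "encoder_id": encoder_id,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path):
    payload = json.loads(Path(path).read_text())
    cls = EmbeddingLogisticRidge if payload["mode"] == "binary" else EmbeddingRidge
    model = cls(**payload["params"])
    model.coef_ = np.asarray(payload["weights"], dtype=float)
    model.intercept_ = float(payload["intercept"])
    model.lambda_ = float(payload["lambda"])
    model.cv_trace_ = {float(k): float(v) for k, v in payload["cv_trace"].items()}
    model.center_ = np.asarray(payload["center"], dtype=float)
    model.scale_ = np.asarray(payload["scale"], dtype=float)
    model.n_features_in_ = len(model.coef_)
    if payload["mode"] == "binary":
        model.classes_ = np.array([0.0, 1.0])
    return model
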