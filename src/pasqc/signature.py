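"""Sparse pathway signature separating iPSC lines from fibroblasts.

An L1-penalised logistic regression (LASSO) over per-pathway PAS features.
Features are standardised internally (zero mean, unit SD per pathway); the
penalty strength λ is chosen by inner leave-one-out cross-validation
maximising held-out accuracy, with ties resolved toward the sparser (larger
λ) model.  Class encoding is fibroblast = 1, iPSC = 0, so a positive
coefficient marks a pathway with higher PAS in fibroblasts.

The optimisation problem is  min_w,b  ||w||_1 + (1/λ) Σ_i log-loss_i ,
solved by scikit-learn's liblinear coordinate-descent solver (C = 1/λ).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .pas import PASMatrix

__all__ = [
    "SignatureError",
    "SignatureModel",
    "DEFAULT_LAMBDA_GRID",
    "fit_signature",
    "loocv_accuracy",
]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-2, 1, 7))

# liblinear also penalises the intercept; a large intercept_scaling makes
# that penalty negligible without changing the coefficient solution
_INTERCEPT_SCALING = 100.0
_TOL = 1e-7


class SignatureError(ValueError):
    """Invalid input to the signature classifier."""


@dataclass
class SignatureModel:
    """A fitted sparse pathway classifier.

    Coefficients are on the standardised feature scale; ``selected`` is the
    set of pathways with a nonzero coefficient.  ``majority_class`` is the
    training-fold majority label, used as the prediction when the penalty
    drives every coefficient to zero.
    """

    coefficients: pd.Series
    intercept: float
    lambda_: float
    feature_mean: pd.Series
    feature_sd: pd.Series
    majority_class: int
    dropped: tuple[str, ...] = ()

    @property
    def selected(self) -> list[str]:
        return self.coefficients.index[self.coefficients != 0.0].tolist()

    def decision_function(self, features: pd.DataFrame) -> pd.Series:
        """Linear score per line (rows = lines, columns = pathways)."""
        z = (features[self.coefficients.index] - self.feature_mean) / self.feature_sd
        return z @ self.coefficients + self.intercept

    def predict(self, features: pd.DataFrame) -> pd.Series:
        if not self.selected:
            return pd.Series(self.majority_class, index=features.index, dtype=int)
        return (self.decision_function(features) > 0).astype(int)

    def predict_pas(self, pas: PASMatrix) -> pd.Series:
        return self.predict(_features(pas))

    def save(self, path: str | Path) -> None:
        payload = {
            "pathways": self.coefficients.index.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "majority_class": self.majority_class,
            "dropped": list(self.dropped),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SignatureModel":
        payload = json.loads(Path(path).read_text())
        idx = pd.Index(payload["pathways"], name="pathway")
        return cls(
            coefficients=pd.Series(payload["coefficients"], index=idx),
            intercept=float(payload["intercept"]),
            lambda_=float(payload["lambda"]),
            feature_mean=pd.Series(payload["feature_mean"], index=idx),
            feature_sd=pd.Series(payload["feature_sd"], index=idx),
            majority_class=int(payload["majority_class"]),
            dropped=tuple(payload.get("dropped", ())),
        )


def _features(pas: PASMatrix) -> pd.DataFrame:
    """Lines × pathways feature frame from a PAS matrix."""
    return pas.data.T


def _as_labels(labels: Mapping[str, int] | pd.Series, index: pd.Index) -> pd.Series:
    s = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    missing = index.difference(s.index)
    if len(missing):
        raise SignatureError(f"label(s) missing for line(s): {missing.tolist()[:5]}")
    s = s.loc[index].astype(int)
    if not set(s.unique()) <= {0, 1}:
        raise SignatureError("labels must be binary 0/1 (1 = fibroblast)")
    return s


def _fit_at_lambda(
    X: np.ndarray, y: np.ndarray, lam: float, seed: int
) -> LogisticRegression:
    clf = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        C=1.0 / lam,
        solver="liblinear",
        tol=_TOL,
        intercept_scaling=_INTERCEPT_SCALING,
        max_iter=10_000,
        random_state=seed,
    )
    clf.fit(X, y)
    return clf


def _standardize(
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, tuple[str, ...]]:
    mean = features.mean(axis=0)
    sd = features.std(axis=0, ddof=1)
    constant = tuple(sd.index[sd == 0.0])
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant pathway feature(s): "
            f"{list(constant)[:5]}",
            stacklevel=3,
        )
    keep = sd.index[sd > 0.0]
    z = (features[keep] - mean[keep]) / sd[keep]
    return z, mean[keep], sd[keep], constant


def _select_lambda(
    z: pd.DataFrame,
    y: pd.Series,
    lambda_grid: Sequence[float],
    seed: int,
) -> float:
    """Inner LOOCV accuracy per λ; ties go to the larger (sparser) λ."""
    if len(set(lambda_grid)) == 1:
        return float(next(iter(lambda_grid)))
    X = z.to_numpy()
    yv = y.to_numpy()
    n = len(yv)
    best_lambda, best_acc = None, -1.0
    for lam in sorted(lambda_grid):
        correct = 0
        for i in range(n):
            mask = np.arange(n) != i
            y_tr = yv[mask]
            if y_tr.min() == y_tr.max():
                pred = int(y_tr[0])  # single-class fold: constant prediction
            else:
                clf = _fit_at_lambda(X[mask], y_tr, lam, seed)
                if np.all(clf.coef_ == 0.0):
                    counts = np.bincount(y_tr, minlength=2)
                    pred = int(np.argmax(counts))
                else:
                    pred = int(clf.predict(X[i : i + 1])[0])
            correct += pred == yv[i]
        acc = correct / n
        if acc >= best_acc:  # >= so the largest λ wins ties
            best_acc, best_lambda = acc, lam
    return float(best_lambda)


def fit_signature(
    pas: PASMatrix,
    labels: Mapping[str, int] | pd.Series,
    lambda_grid: Sequence[float] | None = None,
    lambda_: float | None = None,
    seed: int = 42,
) -> SignatureModel:
    """Fit the sparse pathway signature on all lines of a PAS matrix.

    ``labels`` maps each line to 0 (iPSC) or 1 (fibroblast).  When
    ``lambda_`` is not given, the penalty is chosen from ``lambda_grid`` by
    inner leave-one-out cross-validation.
    """
    features = _features(pas)
    y = _as_labels(labels, features.index)
    if y.nunique() < 2:
        raise SignatureError("both classes must be present")
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise SignatureError("each class needs at least 2 lines")
    return _fit(features, y, lambda_grid, lambda_, seed)


def _fit(
    features: pd.DataFrame,
    y: pd.Series,
    lambda_grid: Sequence[float] | None,
    lambda_: float | None,
    seed: int,
) -> SignatureModel:
    z, mean, sd, dropped = _standardize(features)
    if z.shape[1] == 0:
        raise SignatureError("all pathway features are constant")
    grid = tuple(lambda_grid) if lambda_grid is not None else DEFAULT_LAMBDA_GRID
    if any(l <= 0 for l in grid):
        raise SignatureError("lambda values must be positive")
    lam = float(lambda_) if lambda_ is not None else _select_lambda(z, y, grid, seed)
    clf = _fit_at_lambda(z.to_numpy(), y.to_numpy(), lam, seed)
    counts = np.bincount(y.to_numpy(), minlength=2)
    return SignatureModel(
        coefficients=pd.Series(clf.coef_[0], index=z.columns, name="coefficient"),
        intercept=float(clf.intercept_[0]),
        lambda_=lam,
        feature_mean=mean,
        feature_sd=sd,
        majority_class=int(np.argmax(counts)),
        dropped=dropped,
    )


def loocv_accuracy(
    pas: PASMatrix,
    labels: Mapping[str, int] | pd.Series,
    lambda_grid: Sequence[float] | None = None,
    seed: int = 42,
) -> tuple[float, pd.Series]:
    """Leave-one-out accuracy of the signature, with per-line predictions.

    Each line is held out in turn; the model (including its inner λ
    selection) is refit on the remaining lines and used to predict the
    held-out line's class.
    """
    features = _features(pas)
    y = _as_labels(labels, features.index)
    if len(y) < 3:
        raise SignatureError("leave-one-out needs >= 3 lines")
    if y.nunique() < 2:
        raise SignatureError("both classes must be present")
    predictions = pd.Series(index=features.index, dtype=int, name="predicted")
    for line in features.index:
        rest = features.index.drop(line)
        y_rest = y.loc[rest]
        if y_rest.nunique() < 2:
            # remainder is single-class: only the constant model is fittable
            predictions.loc[line] = int(y_rest.iloc[0])
            continue
        model = _fit(features.loc[rest], y_rest, lambda_grid, None, seed)
        predictions.loc[line] = int(model.predict(features.loc[[line]]).iloc[0])
    accuracy = float((predictions == y).mean())
    return accuracy, predictions
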