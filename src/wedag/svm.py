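"""Soft-margin binary linear SVM.

The model is the primal problem

    min_{w, xi, b}  1/2 ||w||^2 + eps * sum_n xi_n
    s.t.            y_n (w . x_n - b) >= 1 - xi_n,   xi_n >= 0

with labels y_n in {-1, +1} and error penalty ``eps`` (the parameter
conventionally called C; the default 0.05 matches the protocol this package
reproduces).  Note the bias sign: the decision score is ``L = w.x - b``, and
sgn(0) breaks toward the positive class.

The quadratic program is solved through scikit-learn's libsvm binding with a
tight stopping tolerance; the trained hyperplane is re-expressed in the
convention above and its slacks recomputed for diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "BinarySVMModel",
    "DegenerateDataError",
    "train_svm",
    "decision_score",
    "predict",
    "primal_objective",
    "model_to_dict",
    "model_from_dict",
]

DEFAULT_PENALTY = 0.05


class DegenerateDataError(ValueError):
    """Raised when a binary training set does not contain two classes."""


@dataclass(frozen=True)
class BinarySVMModel:
    """A trained hyperplane: score L(x) = w.x - b, L > 0 votes ``pos_class``."""

    w: np.ndarray
    b: float
    penalty: float
    pos_class: Any
    neg_class: Any
    slack: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 1 or not np.all(np.isfinite(w)):
            raise ValueError("w must be a finite 1D vector")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "b", float(self.b))
        object.__setattr__(self, "slack", np.asarray(self.slack, dtype=float))

    @property
    def n_features(self) -> int:
        return self.w.size


def train_svm(
    X: np.ndarray,
    y: Sequence,
    penalty: float = DEFAULT_PENALTY,
    pos_class: Any | None = None,
    neg_class: Any | None = None,
) -> BinarySVMModel:
    """Fit the soft-margin linear SVM on a two-class dataset.

    ``pos_class``/``neg_class`` pin the +1/-1 label mapping; by default the
    two classes are taken in order of first appearance in ``y``.
    """
    if penalty <= 0:
        raise ValueError(f"penalty must be > 0, got {penalty}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2D (samples x features), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    y = np.asarray(y)
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match the number of rows of X")
    classes = list(dict.fromkeys(y.tolist()))
    if len(classes) < 2:
        raise DegenerateDataError(
            f"binary training requires two classes, got only {classes!r}"
        )
    if len(classes) > 2:
        raise ValueError(f"more than two classes present: {classes!r}")
    if pos_class is None and neg_class is None:
        pos_class, neg_class = classes
    elif pos_class is None or neg_class is None:
        raise ValueError("specify both pos_class and neg_class, or neither")
    if set(classes) != {pos_class, neg_class}:
        raise ValueError(
            f"pos/neg classes {pos_class!r}/{neg_class!r} do not match data "
            f"classes {classes!r}"
        )
    y_num = np.where(y == pos_class, 1.0, -1.0)

    clf = SVC(kernel="linear", C=penalty, tol=1e-9, shrinking=False)
    clf.fit(X, y_num)
    w = clf.coef_[0].copy()
    b = -float(clf.intercept_[0])
    # libsvm orients the hyperplane by its internal class order; flip if the
    # positive numeric class ended up on the negative side.
    if clf.classes_[1] != 1.0:  # pragma: no cover - defensive
        w, b = -w, -b
    slack = np.maximum(0.0, 1.0 - y_num * (X @ w - b))
    return BinarySVMModel(
        w=w, b=b, penalty=float(penalty), pos_class=pos_class,
        neg_class=neg_class, slack=slack,
    )


def decision_score(model: BinarySVMModel, x: np.ndarray) -> float | np.ndarray:
    """L(x) = w.x - b for a single vector (returns float) or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if x.size != model.n_features:
            raise ValueError(
                f"feature vector of length {x.size}; model expects {model.n_features}"
            )
        return float(model.w @ x - model.b)
    if x.ndim == 2:
        if x.shape[1] != model.n_features:
            raise ValueError(
                f"feature matrix with {x.shape[1]} columns; model expects "
                f"{model.n_features}"
            )
        return x @ model.w - model.b
    raise ValueError(f"x must be 1D or 2D, got shape {x.shape}")


def predict(model: BinarySVMModel, x: np.ndarray):
    """Class vote: L >= 0 -> pos_class, L < 0 -> neg_class."""
    score = decision_score(model, x)
    if np.isscalar(score):
        return model.pos_class if score >= 0 else model.neg_class
    return np.where(score >= 0, model.pos_class, model.neg_class)


def primal_objective(model: BinarySVMModel, X: np.ndarray, y: Sequence) -> float:
    """1/2 ||w||^2 + eps * sum xi on the given (training) set."""
    X = np.asarray(X, dtype=float)
    y_num = np.where(np.asarray(y) == model.pos_class, 1.0, -1.0)
    xi = np.maximum(0.0, 1.0 - y_num * (X @ model.w - model.b))
    return 0.5 * float(model.w @ model.w) + model.penalty * float(xi.sum())


def model_to_dict(model: BinarySVMModel) -> dict:
    return {
        "w": model.w.tolist(),
        "b": model.b,
        "penalty": model.penalty,
        "pos_class": model.pos_class,
        "neg_class": model.neg_class,
    }


def model_from_dict(d: dict) -> BinarySVMModel:
    return BinarySVMModel(
        w=np.asarray(d["w"], dtype=float),
        b=float(d["b"]),
        penalty=float(d["penalty"]),
        pos_class=d["pos_class"],
        neg_class=d["neg_class"],
    )
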