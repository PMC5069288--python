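"""Decision-DAG multiclass wrapper over pairwise linear SVMs (DDAG).

For C ordered classes the classifier trains one binary SVM per unordered
class pair — (C-1)C/2 models — and predicts by descending a rooted directed
acyclic graph: the root compares the first class against the last, and each
node's score eliminates one of the two classes it compares.  For the model
of pair (i, j) with i < j, class i is mapped to +1 and class j to -1, so a
non-negative score L_ij(x) means "x is not in class j" (class j is
eliminated); a negative score eliminates class i.  After exactly C-1
evaluations one class remains.

Feature standardisation (z-score per feature, statistics from the training
data handed to :func:`train_dag`) is applied by default and stored with the
classifier, since the entropy features this package produces live on
different scales across subbands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np

from .svm import (
    BinarySVMModel,
    DEFAULT_PENALTY,
    decision_score,
    model_from_dict,
    model_to_dict,
    train_svm,
)

__all__ = [
    "DAGClassifier",
    "train_dag",
    "dag_predict",
    "dag_predict_batch",
    "dag_to_dict",
    "dag_from_dict",
]


@dataclass(frozen=True)
class DAGClassifier:
    """(C-1)C/2 pairwise SVMs plus the class order that fixes the DAG."""

    class_names: tuple
    models: dict  # (i, j) with i < j -> BinarySVMModel
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        C = len(self.class_names)
        expected = {(i, j) for i in range(C) for j in range(i + 1, C)}
        if set(self.models) != expected:
            raise ValueError(
                f"pairwise models must cover every class pair exactly once; "
                f"expected {len(expected)} models, got keys {sorted(self.models)}"
            )
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            return X
        return (X - self.mean) / self.scale


def train_dag(
    X: np.ndarray,
    y: Sequence,
    penalty: float = DEFAULT_PENALTY,
    class_names: Sequence | None = None,
    standardize: bool = True,
) -> DAGClassifier:
    """Train all pairwise SVMs; each sees only the samples of its two classes."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2D, got shape {X.shape}")
    y = np.asarray(y)
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match the number of rows of X")
    if class_names is None:
        class_names = list(dict.fromkeys(y.tolist()))
    class_names = list(class_names)
    if len(class_names) < 2:
        raise ValueError("need at least two classes")
    for name in class_names:
        if not np.any(y == name):
            raise ValueError(f"class {name!r} has no training samples")
    extra = set(y.tolist()) - set(class_names)
    if extra:
        raise ValueError(f"labels outside the declared class set: {sorted(extra)!r}")

    mean = scale = None
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        X = (X - mean) / scale

    models: dict[tuple[int, int], BinarySVMModel] = {}
    for i in range(len(class_names)):
        for j in range(i + 1, len(class_names)):
            ci, cj = class_names[i], class_names[j]
            mask = (y == ci) | (y == cj)
            models[(i, j)] = train_svm(
                X[mask], y[mask], penalty=penalty, pos_class=ci, neg_class=cj
            )
    return DAGClassifier(
        class_names=tuple(class_names), models=models, mean=mean, scale=scale
    )


def dag_predict(
    clf: DAGClassifier, x: np.ndarray, return_trace: bool = False
):
    """Descend the DAG: C-1 pairwise evaluations, one class eliminated each.

    With ``return_trace=True`` also returns the list of visited nodes as
    ``(pos_class, neg_class, score, eliminated_class)`` tuples.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"dag_predict takes a single feature vector, got shape {x.shape}")
    xs = clf._transform(x)
    lo, hi = 0, clf.n_classes - 1
    trace = []
    while lo < hi:
        model = clf.models[(lo, hi)]
        score = decision_score(model, xs)
        if score >= 0:  # x is not in class j = hi
            eliminated = clf.class_names[hi]
            hi -= 1
        else:
            eliminated = clf.class_names[lo]
            lo += 1
        trace.append((model.pos_class, model.neg_class, score, eliminated))
    label = clf.class_names[lo]
    if return_trace:
        return label, trace
    return label


def dag_predict_batch(clf: DAGClassifier, X) -> list:
    """Element-wise :func:`dag_predict` over the rows of a feature table."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D feature table, got shape {arr.shape}")
    out = []
    for i, row in enumerate(arr):
        try:
            out.append(dag_predict(clf, row))
        except Exception as exc:
            raise type(exc)(f"row {i}: {exc}") from exc
    return out


def dag_to_dict(clf: DAGClassifier) -> dict:
    return {
        "class_names": list(clf.class_names),
        "models": {
            f"{i},{j}": model_to_dict(m) for (i, j), m in sorted(clf.models.items())
        },
        "mean": None if clf.mean is None else clf.mean.tolist(),
        "scale": None if clf.scale is None else clf.scale.tolist(),
    }


def dag_from_dict(d: dict) -> DAGClassifier:
    models = {}
    for key, md in d["models"].items():
        i, j = (int(s) for s in key.split(","))
        models[(i, j)] = model_from_dict(md)
    mean = d.get("mean")
    scale = d.get("scale")
    return DAGClassifier(
        class_names=tuple(d["class_names"]),
        models=models,
        mean=None if mean is None else np.asarray(mean, dtype=float),
        scale=None if scale is None else np.asarray(scale, dtype=float),
    )
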