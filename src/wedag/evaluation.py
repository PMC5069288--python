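"""Repeated stratified k-fold cross-validation and confusion-matrix metrics.

The evaluation protocol is runs x k-fold CV: for each of ``runs``
repetitions the samples are split into k stratified folds (sizes differing
by at most one; with 49 samples and k = 10 that is nine folds of 5 and one
of 4), each fold serves once as the validation set of a DAG-SVM trained on
the other k-1 folds, and validation predictions from every run are pooled
into one C x C confusion matrix (rows = true class, columns = predicted).

Per-class metrics use the one-vs-rest reduction of the pooled matrix:
TP = cm[c,c], FN = row c minus TP, FP = column c minus TP, TN = the rest;
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision = TP/(TP+FP),
accuracy = (TP+TN)/total.  A zero denominator yields ``None`` ("undefined"),
never a silent 0 or 100.  Reported percentages are rounded to two decimals;
internal arithmetic is unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold

from .features import extract_batch
from .svm import DEFAULT_PENALTY
from .dag import dag_predict_batch, train_dag
from .wavelet import build_filter_bank

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "ClassMetrics",
    "CVResult",
    "make_folds",
    "run_cv",
    "overall_accuracy",
    "class_metrics",
    "metrics_table",
    "run_accuracies",
    "level_sweep",
    "permutation_null_band",
]


@dataclass(frozen=True)
class FoldPlan:
    """A deterministic assignment of samples to k disjoint folds."""

    run_seed: int
    k: int
    assignments: np.ndarray  # per-sample fold index in [0, k)

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


@dataclass
class ConfusionMatrix:
    """C x C validation counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    class_names: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        C = len(self.class_names)
        if counts.shape != (C, C):
            raise ValueError(f"counts shape {counts.shape} != ({C}, {C})")
        if np.any(counts < 0):
            raise ValueError("negative confusion count")
        self.counts = counts
        self.class_names = tuple(self.class_names)

    @classmethod
    def zeros(cls, class_names: Sequence) -> "ConfusionMatrix":
        C = len(class_names)
        return cls(np.zeros((C, C), dtype=int), tuple(class_names))

    @classmethod
    def from_labels(
        cls, y_true: Sequence, y_pred: Sequence, class_names: Sequence
    ) -> "ConfusionMatrix":
        counts = _sk_confusion(y_true, y_pred, labels=list(class_names))
        return cls(counts, tuple(class_names))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_names != other.class_names:
            raise ValueError("class name mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_names), columns=list(self.class_names)
        )


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest proportions in [0, 1]; ``None`` marks an undefined ratio."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None

    def as_percent(self, decimals: int = 2) -> dict:
        return {
            k: (None if v is None else round(100.0 * v, decimals))
            for k, v in self.__dict__.items()
        }


def make_folds(
    labels: Sequence, k: int, seed: int, stratified: bool = True
) -> FoldPlan:
    """Stratified (default) or plain shuffled k-fold assignment, seed-fixed."""
    labels = np.asarray(labels)
    S = labels.size
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > S:
        raise ValueError(f"k={k} exceeds the number of samples S={S}")
    _, class_counts = np.unique(labels, return_counts=True)
    # stratification needs every class in every fold boundary condition:
    # k cannot exceed the smallest class (e.g. leave-one-out falls back)
    if stratified and class_counts.size > 1 and k <= class_counts.min():
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(S, dtype=int)
    for fold, (_, val_idx) in enumerate(splitter.split(np.zeros((S, 1)), labels)):
        assignments[val_idx] = fold
    return FoldPlan(run_seed=seed, k=k, assignments=assignments)


@dataclass
class CVResult:
    """Everything the runs x k protocol produced."""

    fold_counts: np.ndarray  # (runs, k, 2): (correct, total) per validation fold
    confusion: ConfusionMatrix
    config: dict = field(default_factory=dict)

    @property
    def runs(self) -> int:
        return self.fold_counts.shape[0]

    @property
    def k(self) -> int:
        return self.fold_counts.shape[1]

    @property
    def per_run_accuracy(self) -> np.ndarray:
        """Percent correct of each run, pooled over its folds."""
        correct = self.fold_counts[:, :, 0].sum(axis=1)
        total = self.fold_counts[:, :, 1].sum(axis=1)
        return 100.0 * correct / total

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_run_accuracy.mean())

    def fold_table(self) -> pd.DataFrame:
        """Run x fold table of ``"correct (total)"`` cells plus run summaries."""
        rows = {}
        for r in range(self.runs):
            cells = [
                f"{int(c)} ({int(t)})" for c, t in self.fold_counts[r]
            ]
            correct = int(self.fold_counts[r, :, 0].sum())
            total = int(self.fold_counts[r, :, 1].sum())
            rows[f"Run {r + 1}"] = cells + [
                f"{correct} ({total})",
                round(self.per_run_accuracy[r], 2),
            ]
        columns = [f"F{f + 1}" for f in range(self.k)] + ["Total", "Acc. (%)"]
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
        frame.loc["Average", "Acc. (%)"] = round(self.mean_accuracy, 2)
        return frame

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "fold_counts": self.fold_counts.tolist(),
            "per_run_accuracy": [round(a, 4) for a in self.per_run_accuracy],
            "mean_accuracy": round(self.mean_accuracy, 4),
            "overall_accuracy": round(overall_accuracy(self.confusion), 4),
            "confusion": {
                "class_names": list(self.confusion.class_names),
                "counts": self.confusion.counts.tolist(),
            },
        }


def run_cv(
    features,
    labels: Sequence,
    k: int = 10,
    runs: int = 10,
    penalty: float = DEFAULT_PENALTY,
    seed: int = 0,
    stratified: bool = True,
    standardize: bool = True,
    class_names: Sequence | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV of the DAG-SVM on a fixed feature table.

    Run r uses fold seed ``seed + r``.  Standardisation statistics are
    recomputed on each training part, never on the validation fold.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be 2D with one row per label")
    if class_names is None:
        class_names = sorted(np.unique(y).tolist())
    class_names = list(class_names)

    fold_counts = np.zeros((runs, k, 2), dtype=int)
    confusion = ConfusionMatrix.zeros(class_names)
    for r in range(runs):
        plan = make_folds(y, k, seed + r, stratified=stratified)
        for f in range(k):
            val_idx = plan.fold_indices(f)
            train_mask = np.ones(y.size, dtype=bool)
            train_mask[val_idx] = False
            y_train = y[train_mask]
            missing = [c for c in class_names if not np.any(y_train == c)]
            if missing:
                raise ValueError(
                    f"run {r}, fold {f}: training part lacks class(es) {missing!r}"
                )
            clf = train_dag(
                X[train_mask], y_train, penalty=penalty,
                class_names=class_names, standardize=standardize,
            )
            preds = dag_predict_batch(clf, X[val_idx])
            confusion = confusion + ConfusionMatrix.from_labels(
                y[val_idx], preds, class_names
            )
            correct = int(np.sum(np.asarray(preds) == y[val_idx]))
            fold_counts[r, f] = (correct, val_idx.size)
    config = {
        "k": k, "runs": runs, "penalty": penalty, "seed": seed,
        "stratified": stratified, "standardize": standardize,
        "class_names": class_names,
    }
    return CVResult(fold_counts=fold_counts, confusion=confusion, config=config)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of pooled validation predictions on the diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * cm.correct / cm.total


def class_metrics(cm: ConfusionMatrix, cls) -> ClassMetrics:
    """One-vs-rest sensitivity/specificity/precision/accuracy for one class."""
    if cls not in cm.class_names:
        raise ValueError(f"unknown class {cls!r}; have {cm.class_names}")
    c = cm.class_names.index(cls)
    counts = cm.counts
    tp = int(counts[c, c])
    fn = int(counts[c, :].sum()) - tp
    fp = int(counts[:, c].sum()) - tp
    tn = cm.total - tp - fn - fp

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return ClassMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        accuracy=ratio(tp + tn, cm.total),
    )


def metrics_table(cm: ConfusionMatrix, decimals: int = 2) -> pd.DataFrame:
    """Per-class metric table in percent (NaN where a ratio is undefined)."""
    rows = {}
    for cls in cm.class_names:
        pct = class_metrics(cm, cls).as_percent(decimals)
        rows[cls] = {
            k.capitalize(): (np.nan if v is None else v) for k, v in pct.items()
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "Class"
    return frame


def run_accuracies(fold_counts) -> tuple[np.ndarray, float]:
    """Per-run percent accuracies and their average from (correct, total) counts.

    ``fold_counts`` is (runs, k, 2) shaped (or nested lists of that shape).
    """
    counts = np.asarray(fold_counts, dtype=float)
    if counts.ndim != 3 or counts.shape[2] != 2:
        raise ValueError("expected a (runs, k, 2) array of (correct, total)")
    per_run = 100.0 * counts[:, :, 0].sum(axis=1) / counts[:, :, 1].sum(axis=1)
    return per_run, float(per_run.mean())


def level_sweep(
    images: Sequence[np.ndarray],
    labels: Sequence,
    levels: Sequence[int],
    wavelet: str = "bior5.5",
    entropy_variant: str = "energy",
    **cv_kwargs,
) -> pd.DataFrame:
    """Full extract -> CV pipeline per decomposition level (accuracy table)."""
    fb = build_filter_bank(wavelet)
    rows = []
    for level in levels:
        feats = extract_batch(images, fb, level, variant=entropy_variant)
        result = run_cv(feats, labels, **cv_kwargs)
        rows.append(
            {
                "level": level,
                "n_features": 3 * level + 1,
                "overall_accuracy": round(overall_accuracy(result.confusion), 2),
            }
        )
    return pd.DataFrame(rows)


def permutation_null_band(
    features,
    labels: Sequence,
    n_permutations: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
    **cv_kwargs,
) -> tuple[float, float]:
    """(lo, hi) empirical quantiles of CV accuracy under label permutation.

    The band brackets the accuracy expected when features carry no class
    information; the permutation RNG is independent of the CV fold seeds.
    """
    rng = np.random.default_rng(seed + 10_000)
    y = np.asarray(labels)
    accs = []
    for _ in range(n_permutations):
        perm = rng.permutation(y.size)
        result = run_cv(features, y[perm], seed=seed, **cv_kwargs)
        accs.append(result.mean_accuracy)
    lo, hi = np.quantile(accs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
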