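"""Evaluation protocol: stratified k-fold CV, leave-one-subject-out,
per-class recall, macro precision, averaged confusion matrices, prediction
timing and fold-wise t-tests.

The reducer and classifier are always fitted inside each fold on the
training split only, so no information leaks from the test split.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import classify, reduction
from .recording import CLASS_ORDER


@dataclass
class FoldAssignment:
    fold: np.ndarray  # per-sample fold index in 0..k-1
    k: int


@dataclass
class ConfusionMatrix:
    """Rows = actual classes, columns = predicted, in ``class_order``."""

    counts: np.ndarray
    class_order: tuple


@dataclass
class CVResult:
    class_order: tuple
    fold_accuracies: np.ndarray
    per_class_recall: np.ndarray  # mean over folds, class order
    macro_precision_pct: float
    overall_accuracy_pct: float
    confusion: np.ndarray  # mean per-fold confusion matrix
    time_ms: float  # mean wall time to predict one reference batch
    batch_size: int

    def table_row(self, algorithm: str) -> dict:
        """One row shaped like the results tables: recall per class,
        average precision (%), time cost (ms)."""
        rec = "/".join(f"{r:.2f}" for r in self.per_class_recall)
        return {
            "Algorithm": algorithm,
            "Recall": rec,
            "Average precision (%)": round(self.macro_precision_pct, 2),
            "Time cost (ms)": round(self.time_ms, 3),
        }


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    mean_b: float


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment: shuffle within each class, deal round-robin.

    Per-fold class proportions match the global ones within one sample per
    class.  Every class must have at least ``k`` samples.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold = np.full(labels.shape[0], -1, dtype=int)
    for c in dict.fromkeys(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ValueError(f"class {c!r} has {idx.size} samples < k={k}")
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return FoldAssignment(fold, k)


def confusion_matrix(actual, predicted, class_order=CLASS_ORDER) -> ConfusionMatrix:
    """Entry (i, j) counts samples of actual class i predicted as class j."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)))
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"label outside class_order: {a!r} / {p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def _recall_precision(cm: np.ndarray):
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, np.diag(cm) / row, 0.0)
        precision = np.where(col > 0, np.diag(cm) / col, 0.0)
    return recall, precision


def _make_reducer(spec, X, y):
    if spec is None:
        return None
    name, params = spec
    if name == "pca":
        return reduction.fit_pca(X, **params)
    if name == "lda":
        return reduction.fit_lda(X, y, **params)
    raise ValueError(f"unknown reducer {name!r}")


def _make_classifier(spec, X, y, class_order, seed):
    name, params = spec
    params = dict(params)
    if name == "svmlin":
        return "svm", classify.train_svm(
            X, y, classify.KernelSpec("linear"), class_order=class_order, **params
        )
    if name == "svmrbf":
        return "svm", classify.train_svm(
            X, y, classify.KernelSpec("rbf", params.pop("gamma", None)),
            class_order=class_order, **params,
        )
    if name == "nn":
        return "nn", classify.train_nn(
            X, y, class_order=class_order, seed=seed, **params
        )
    raise ValueError(f"unknown classifier {name!r}")


def _predict(kind, model, X):
    if kind == "svm":
        return classify.predict_svm(model, X).labels
    return classify.predict_nn(model, X).labels


def fit_predict(reducer_spec, classifier_spec, X_train, y_train, X_test,
                class_order=CLASS_ORDER, seed: int = 0):
    """Fit reducer + classifier on the training split, predict the test split."""
    order = [c for c in class_order if c in set(y_train)]
    red = _make_reducer(reducer_spec, X_train, y_train)
    Ztr = reduction.transform(red, X_train) if red is not None else X_train
    kind, model = _make_classifier(classifier_spec, Ztr, y_train, order, seed)
    Zte = reduction.transform(red, X_test) if red is not None else X_test
    return _predict(kind, model, Zte), (red, kind, model)


def evaluate_pipeline(
    reducer_spec,
    classifier_spec,
    X,
    y,
    k: int = 10,
    seed: int = 0,
    batch_size: int = 2000,
    class_order=CLASS_ORDER,
) -> CVResult:
    """Stratified k-fold cross-validation of a reducer + classifier pipeline.

    Per fold: fit on the training split only, predict the held-out split,
    record accuracy, per-class recall/precision, the confusion matrix, and
    the wall time to predict ``batch_size`` items resampled from the test
    split (the reference batch sizes are 2000 dynamic / 130 static).
    Aggregates are means over folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fa = stratified_kfold(y, k, seed)
    rng = np.random.default_rng(seed)
    accs, recalls, precisions, cms, times = [], [], [], [], []
    for f in range(k):
        test = fa.fold == f
        train = ~test
        pred, (red, kind, model) = fit_predict(
            reducer_spec, classifier_spec, X[train], y[train], X[test],
            class_order, seed,
        )
        cm = confusion_matrix(y[test], pred, class_order).counts
        accs.append(np.trace(cm) / cm.sum())
        r, p = _recall_precision(cm)
        recalls.append(r)
        precisions.append(p)
        cms.append(cm)
        batch_idx = rng.integers(0, test.sum(), size=batch_size)
        Xb = X[test][batch_idx]
        Zb = reduction.transform(red, Xb) if red is not None else Xb
        t0 = time.perf_counter()
        _predict(kind, model, Zb)
        times.append((time.perf_counter() - t0) * 1e3)
    return CVResult(
        tuple(class_order),
        np.asarray(accs),
        np.mean(recalls, axis=0),
        float(np.mean(precisions) * 100.0),
        float(np.mean(accs) * 100.0),
        np.mean(cms, axis=0),
        float(np.mean(times)),
        batch_size,
    )


def loso_evaluate(
    reducer_spec,
    classifier_spec,
    X,
    y,
    subjects,
    class_order=CLASS_ORDER,
    seed: int = 0,
):
    """Leave-one-subject-out generalization test.

    One round per subject: train on all other subjects, test on the held
    out one.  Rounds whose training split is missing a class are skipped
    with a warning.  Returns (per_subject_accuracy, mean_accuracy,
    per_class_accuracy).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    unique = list(dict.fromkeys(subjects))
    if len(unique) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    present = [c for c in class_order if c in set(y)]
    per_subject = {}
    cm_total = np.zeros((len(class_order), len(class_order)))
    for s in unique:
        test = subjects == s
        train = ~test
        if set(present) - set(y[train]):
            warnings.warn(
                f"subject {s!r} skipped: training split lacks a class",
                stacklevel=2,
            )
            continue
        pred, _ = fit_predict(
            reducer_spec, classifier_spec, X[train], y[train], X[test],
            class_order, seed,
        )
        cm = confusion_matrix(y[test], pred, class_order).counts
        per_subject[s] = float(np.trace(cm) / cm.sum())
        cm_total += cm
    if not per_subject:
        raise ValueError("no LOSO round had all classes in training")
    recall, _ = _recall_precision(cm_total)
    return per_subject, float(np.mean(list(per_subject.values()))), recall


def compare_folds(acc_a, acc_b, equal_var: bool = False) -> TTestResult:
    """Two-sample t-test on per-fold accuracies (Welch by default).

    Identical zero-variance groups are defined to give t=0, p=1.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, float(a.mean()), float(b.mean()))
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf, 0.0,
                           float(a.mean()), float(b.mean()))
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(t), float(p), float(a.mean()), float(b.mean()))
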