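"""Evaluation: accuracy, per-class MCC, cross-validation, K-sweep driver.

Localization is multi-class, so the Matthews correlation coefficient is
computed one-vs-rest per location while a single overall accuracy (the
fraction of proteins whose predicted label equals the curated one) covers
the whole table. Ensembles are scored by seeded stratified k-fold
cross-validation; the K-sweep driver reproduces the accuracy-versus-
number-of-predictors experiment for the exhaustive, minimalist-chain and
top-K-accuracy subset strategies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .ensemble import canonical_scheme, train_meta
from .io import PredictionTable
from .selection import greedy_backward_chain, top_k_by_accuracy


def overall_accuracy(pred, truth) -> float:
    """Fraction of positions where predicted and true labels agree."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch between predictions and truth")
    if pred.size < 1:
        raise ValueError("empty label vectors")
    return float((pred == truth).mean())


def binary_confusion(pred, truth, cls: str) -> tuple[int, int, int, int]:
    """One-vs-rest TP, TN, FP, FN counts for class ``cls``."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch between predictions and truth")
    p = pred == cls
    t = truth == cls
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    return tp, tn, fp, fn


def per_class_mcc(pred, truth, cls: str) -> float:
    """One-vs-rest Matthews correlation coefficient for class ``cls``.

    Defined as 0 when any factor of the denominator is 0.
    """
    tp, tn, fp, fn = binary_confusion(pred, truth, cls)
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


@dataclass
class EvalReport:
    """Pooled cross-validation (or holdout) evaluation results."""

    overall_accuracy: float
    per_class_mcc: dict[str, float]
    confusion: dict[str, dict[str, int]]
    n: int
    fold_assignment: list[int] = field(default_factory=list)
    fold_accuracies: list[float] = field(default_factory=list)
    scheme: str = ""
    subset: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class_mcc": dict(sorted(self.per_class_mcc.items())),
            "confusion": {k: self.confusion[k] for k in sorted(self.confusion)},
            "n": self.n,
            "fold_assignment": list(self.fold_assignment),
            "fold_accuracies": list(self.fold_accuracies),
            "scheme": self.scheme,
            "subset": list(self.subset),
        }


def evaluate_labels(pred, truth, classes=None) -> EvalReport:
    """Accuracy, per-class MCC and confusion counts for label vectors."""
    truth = np.asarray(truth, dtype=object)
    if classes is None:
        classes = sorted({str(t) for t in truth})
    mcc = {c: per_class_mcc(pred, truth, c) for c in classes}
    conf = {}
    for c in classes:
        tp, tn, fp, fn = binary_confusion(pred, truth, c)
        conf[c] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    return EvalReport(
        overall_accuracy=overall_accuracy(pred, truth),
        per_class_mcc=mcc,
        confusion=conf,
        n=int(truth.size),
    )


def stratified_folds(y, folds: int, seed: int = 0) -> np.ndarray:
    """Seeded stratified fold assignment; returns a fold index per row.

    Classes with fewer members than folds trigger a warning and are simply
    spread over as many folds as they have members.
    """
    y = np.asarray(y, dtype=object)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.shape[0], dtype=int)
    offset = 0
    for cls in sorted({str(v) for v in y}):
        idx = np.flatnonzero(y == cls)
        if idx.size < folds:
            warnings.warn(
                f"class {cls!r} has only {idx.size} members for {folds} folds; "
                "it cannot appear in every fold",
                stacklevel=2,
            )
        rng.shuffle(idx)
        for t, i in enumerate(idx):
            assignment[i] = (t + offset) % folds
        offset = (offset + idx.size) % folds
    return assignment


def cross_validate(
    table: PredictionTable,
    subset=None,
    scheme: str = "logistic_regression",
    folds: int = 10,
    seed: int = 0,
    selection: str = "fixed",
    k: int | None = None,
    **clf_params,
) -> EvalReport:
    """Stratified k-fold cross-validation of an ensemble scheme.

    ``selection`` controls predictor-subset handling per fold:

    * ``"fixed"`` (default) — use ``subset`` as given (all predictors when
      ``None``);
    * ``"cfs"`` — re-run the greedy backward CFS chain on each fold's
      training rows and keep its size-``k`` subset;
    * ``"topk"`` — keep each fold's ``k`` most accurate predictors.

    Re-selecting inside the fold keeps subset choice blind to the test
    rows.
    """
    if table.true_labels is None:
        raise ValueError("cross-validation requires true labels")
    scheme = canonical_scheme(scheme)
    if selection not in ("fixed", "cfs", "topk"):
        raise ValueError(f"unknown selection mode {selection!r}")
    if selection != "fixed" and k is None:
        raise ValueError("in-fold selection requires k")
    if subset is None:
        subset = tuple(range(table.n_predictors))
    subset = tuple(subset)

    y = np.asarray(table.true_labels, dtype=object)
    assignment = stratified_folds(y, folds, seed)
    pooled = np.empty(table.n_proteins, dtype=object)
    fold_acc = []
    for f in range(folds):
        test_idx = np.flatnonzero(assignment == f)
        train_idx = np.flatnonzero(assignment != f)
        if test_idx.size == 0:
            fold_acc.append(float("nan"))
            continue
        train = table.subset_rows(train_idx)
        if selection == "cfs":
            chain = greedy_backward_chain(train)
            fold_subset = chain.subset_of_size(k)
        elif selection == "topk":
            fold_subset = top_k_by_accuracy(train, k)
        else:
            fold_subset = subset
        model = train_meta(train, fold_subset, scheme=scheme, seed=seed, **clf_params)
        pred = model.classifier.predict(table.predictions[test_idx][:, list(fold_subset)])
        pooled[test_idx] = pred
        fold_acc.append(overall_accuracy(pred, y[test_idx]))

    report = evaluate_labels(pooled, y)
    report.fold_assignment = [int(a) for a in assignment]
    report.fold_accuracies = fold_acc
    report.scheme = scheme
    report.subset = [table.predictor_names[j] for j in subset]
    return report


def performance_vs_k(
    table: PredictionTable,
    schemes=("logistic_regression",),
    mode: str = "minimalist",
    folds: int = 10,
    seed: int = 0,
    k_range=None,
) -> pd.DataFrame:
    """Cross-validated accuracy as a function of subset size K.

    ``mode`` is one of ``exhaustive`` (every size-K combination: the dot
    cloud), ``minimalist`` (one CFS-chain subset per K: the line) or
    ``topk`` (the K most accurate predictors per K). Returns a tidy frame
    with columns mode, scheme, k, subset, cv_accuracy, is_minimalist.
    """
    if mode not in ("exhaustive", "minimalist", "topk"):
        raise ValueError(f"unknown mode {mode!r}")
    p = table.n_predictors
    if k_range is None:
        k_range = range(2, p + 1)
    schemes = [canonical_scheme(s) for s in schemes]

    chain = greedy_backward_chain(table)
    chain_sets = {len(s): tuple(sorted(s)) for s in chain.subsets}

    rows = []
    for k in k_range:
        if mode == "exhaustive":
            subsets = list(combinations(range(p), k))
        elif mode == "minimalist":
            subsets = [chain_sets[k]]
        else:
            subsets = [top_k_by_accuracy(table, k)]
        for subset in subsets:
            for scheme in schemes:
                report = cross_validate(
                    table, subset, scheme=scheme, folds=folds, seed=seed
                )
                rows.append(
                    {
                        "mode": mode,
                        "scheme": scheme,
                        "k": int(k),
                        "subset": ",".join(
                            table.predictor_names[j] for j in subset
                        ),
                        "cv_accuracy": report.overall_accuracy,
                        "is_minimalist": tuple(sorted(subset))
                        == chain_sets.get(k),
                    }
                )
    return pd.DataFrame(rows)
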