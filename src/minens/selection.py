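"""Minimalist predictor-subset selection.

The goal is to prune a panel of component predictors down to a small
complementary subset whose categorical outputs are jointly highly
correlated with the true location while being minimally correlated with
each other. Correlation between nominal variables is measured by symmetric
uncertainty SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)) with entropies in bits,
and a candidate subset of size k is scored with the CFS merit

    merit(S) = k * mean(r_cf) / sqrt(k + k (k - 1) * mean(r_ff))

where r_cf are the SU values between each subset member and the class and
r_ff the pairwise SU values between members.

Subsets are searched greedily backward: starting from the full panel,
repeatedly drop the predictor whose removal leaves the highest-merit
remainder, recording every intermediate subset down to size 1. Two
baselines are provided: top-K selection by standalone accuracy, and
exhaustive enumeration of all size-K subsets scored by cross-validated
ensemble accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import PredictionTable

_TIE_TOL = 1e-12


def symmetric_uncertainty(x, y) -> float:
    """Symmetric uncertainty between two categorical vectors, in [0, 1].

    Returns ``2 * I(x;y) / (H(x) + H(y))`` with entropies in bits, defined
    as 0 when both variables are constant (H(x) + H(y) = 0).
    """
    x = np.asarray(x, dtype=object)
    y = np.asarray(y, dtype=object)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("empty vectors")
    hx = _entropy_bits(x)
    hy = _entropy_bits(y)
    if hx + hy == 0.0:
        return 0.0
    hxy = _entropy_bits([f"{a}\x00{b}" for a, b in zip(x, y)])
    mi = max(hx + hy - hxy, 0.0)
    return min(2.0 * mi / (hx + hy), 1.0)


def _entropy_bits(values) -> float:
    _, counts = np.unique(np.asarray(values, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class MeritScore:
    subset: tuple[int, ...]
    merit: float


@dataclass(frozen=True)
class SubsetChain:
    """Nested subsets of sizes N, N-1, ..., 1 from the backward search."""

    subsets: list[tuple[int, ...]]
    merits: list[float]

    def subset_of_size(self, k: int) -> tuple[int, ...]:
        for s in self.subsets:
            if len(s) == k:
                return s
        raise KeyError(f"no subset of size {k} in chain")


def _su_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Feature-class SU vector and feature-feature SU matrix."""
    p = X.shape[1]
    su_cf = np.array([symmetric_uncertainty(X[:, j], y) for j in range(p)])
    su_ff = np.eye(p)
    for a in range(p):
        for b in range(a + 1, p):
            su_ff[a, b] = su_ff[b, a] = symmetric_uncertainty(X[:, a], X[:, b])
    return su_cf, su_ff


def _merit_from_matrices(
    subset: tuple[int, ...], su_cf: np.ndarray, su_ff: np.ndarray
) -> float:
    k = len(subset)
    if k == 0:
        raise ValueError("merit of the empty subset is undefined")
    mean_cf = float(su_cf[list(subset)].mean())
    if k == 1:
        return mean_cf
    pairs = [(a, b) for a, b in combinations(subset, 2)]
    mean_ff = float(np.mean([su_ff[a, b] for a, b in pairs]))
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def _table_arrays(table: PredictionTable) -> tuple[np.ndarray, np.ndarray]:
    if table.true_labels is None:
        raise ValueError("selection requires true labels")
    mask = table.complete_rows()
    X = table.predictions[mask]
    y = np.asarray(table.true_labels, dtype=object)[mask]
    if X.shape[0] == 0:
        raise ValueError("no complete rows available for selection")
    return X, y


def cfs_merit(table: PredictionTable, subset) -> MeritScore:
    """CFS merit of a predictor subset against the true labels.

    Rows containing the ``NA`` sentinel are excluded before the entropy
    computations.
    """
    subset = tuple(sorted(subset))
    if len(subset) == 0:
        raise ValueError("merit of the empty subset is undefined")
    X, y = _table_arrays(table)
    su_cf, su_ff = _su_matrices(X[:, list(subset)], y)
    # matrices were built on the restricted columns: remap to local indices
    local = tuple(range(len(subset)))
    return MeritScore(subset=subset, merit=_merit_from_matrices(local, su_cf, su_ff))


def _greedy_backward(su_cf: np.ndarray, su_ff: np.ndarray) -> SubsetChain:
    p = su_cf.shape[0]
    current = tuple(range(p))
    subsets = [current]
    merits = [_merit_from_matrices(current, su_cf, su_ff)]
    while len(current) > 1:
        best_merit = -np.inf
        candidates: list[int] = []
        for drop in current:
            remainder = tuple(j for j in current if j != drop)
            m = _merit_from_matrices(remainder, su_cf, su_ff)
            if m > best_merit + _TIE_TOL:
                best_merit = m
                candidates = [drop]
            elif m >= best_merit - _TIE_TOL:
                candidates.append(drop)
        # tie policy: drop the candidate with the lowest standalone
        # feature-class correlation; remaining ties by column order
        drop = min(candidates, key=lambda j: (su_cf[j], j))
        current = tuple(j for j in current if j != drop)
        subsets.append(current)
        merits.append(_merit_from_matrices(current, su_cf, su_ff))
    return SubsetChain(subsets=subsets, merits=merits)


def greedy_backward_chain(table: PredictionTable) -> SubsetChain:
    """Backward greedy CFS search recording every subset from size N to 1."""
    X, y = _table_arrays(table)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors for a backward search")
    su_cf, su_ff = _su_matrices(X, y)
    return _greedy_backward(su_cf, su_ff)


def select_minimalist(table: PredictionTable, k: int) -> tuple[int, ...]:
    """The size-``k`` subset recorded by the greedy backward CFS chain."""
    if not 1 <= k <= table.n_predictors:
        raise ValueError(f"k={k} out of range 1..{table.n_predictors}")
    if k == table.n_predictors:
        return tuple(range(table.n_predictors))
    return greedy_backward_chain(table).subset_of_size(k)


def predictor_accuracies(table: PredictionTable) -> np.ndarray:
    """Overall accuracy of each predictor column (complete rows only)."""
    X, y = _table_arrays(table)
    return (X == y[:, None]).mean(axis=0)


def top_k_by_accuracy(table: PredictionTable, k: int) -> tuple[int, ...]:
    """The ``k`` predictors with highest standalone accuracy.

    Ties are broken by column order (earlier column wins).
    """
    if not 1 <= k <= table.n_predictors:
        raise ValueError(f"k={k} out of range 1..{table.n_predictors}")
    acc = predictor_accuracies(table)
    order = np.argsort(-acc, kind="stable")
    return tuple(sorted(int(j) for j in order[:k]))


def exhaustive_search(
    table: PredictionTable,
    k: int,
    scheme: str = "logistic_regression",
    folds: int = 10,
    seed: int = 0,
) -> tuple[tuple[int, ...], float, list[MeritScore]]:
    """Evaluate every size-``k`` subset by cross-validated ensemble accuracy.

    Returns the best subset, its CV accuracy, and the full score list (one
    entry per combination, CV accuracy stored in the ``merit`` slot).
    """
    from .evaluation import cross_validate  # deferred: avoids an import cycle

    if not 1 <= k <= table.n_predictors:
        raise ValueError(f"k={k} out of range 1..{table.n_predictors}")
    scores: list[MeritScore] = []
    best: tuple[int, ...] | None = None
    best_acc = -np.inf
    for subset in combinations(range(table.n_predictors), k):
        report = cross_validate(table, subset, scheme=scheme, folds=folds, seed=seed)
        scores.append(MeritScore(subset=subset, merit=report.overall_accuracy))
        if report.overall_accuracy > best_acc:
            best_acc = report.overall_accuracy
            best = subset
    assert best is not None
    return best, float(best_acc), scores


class _LabelSelectorBase(TransformerMixin, BaseEstimator):
    """Shared plumbing for selectors over matrices of categorical labels.

    Validation is done by hand because the feature matrix holds strings,
    which the standard numeric array checks reject.
    """

    def _validate_labels(self, X, y):
        X = np.asarray(X, dtype=object)
        y = np.asarray(y, dtype=object).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix of categorical labels")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        return X, y

    def get_support(self):
        check_is_fitted(self, "selected_indices_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[list(self.selected_indices_)] = True
        return mask

    def transform(self, X):
        check_is_fitted(self, "selected_indices_")
        X = np.asarray(X, dtype=object)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns as seen in fit"
            )
        return X[:, list(self.selected_indices_)]


class CFSBackwardSelector(_LabelSelectorBase):
    """Greedy backward CFS subset selector over categorical predictor outputs.

    Parameters
    ----------
    k : int or None
        Target subset size. ``None`` keeps the chain subset with the
        highest merit.

    Attributes
    ----------
    chain_subsets_ : list of tuple of int
        Nested subsets of sizes N..1 recorded during the backward search.
    chain_merits_ : list of float
        CFS merit of each recorded subset.
    selected_indices_ : tuple of int
        Columns retained after selection.
    """

    def __init__(self, k: int | None = None):
        self.k = k

    def fit(self, X, y):
        X, y = self._validate_labels(X, y)
        self.n_features_in_ = X.shape[1]
        if self.n_features_in_ < 2:
            raise ValueError("need at least 2 predictors")
        su_cf, su_ff = _su_matrices(X, y)
        chain = _greedy_backward(su_cf, su_ff)
        self.chain_subsets_ = chain.subsets
        self.chain_merits_ = chain.merits
        if self.k is None:
            best = int(np.argmax(chain.merits))
            self.selected_indices_ = tuple(sorted(chain.subsets[best]))
        else:
            if not 1 <= self.k <= self.n_features_in_:
                raise ValueError(f"k={self.k} out of range")
            self.selected_indices_ = tuple(sorted(chain.subset_of_size(self.k)))
        return self


class TopKAccuracySelector(_LabelSelectorBase):
    """Keep the ``k`` predictors with highest standalone accuracy."""

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y):
        X, y = self._validate_labels(X, y)
        self.n_features_in_ = X.shape[1]
        if not 1 <= self.k <= self.n_features_in_:
            raise ValueError(f"k={self.k} out of range")
        acc = (X == y[:, None]).mean(axis=0)
        self.accuracies_ = acc
        order = np.argsort(-acc, kind="stable")
        self.selected_indices_ = tuple(sorted(int(j) for j in order[: self.k]))
        return self
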