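"""Meta-classifier ensembles over categorical predictor outputs.

Each component predictor emits one categorical location label per protein;
the ensemble treats those labels as features and learns a mapping to the
true location. Five combination schemes are supported:

* ``weighted_vote`` — pick the label with the largest accuracy-weighted
  vote sum (each predictor's weight is its training-set overall accuracy);
* ``lda`` — LDA-weighted voting: per location, a Fisher discriminant on
  the binary vote indicators assigns each predictor an optimal voting
  weight; a protein is assigned the location with the highest discriminant
  score. Votes for a location only ever count toward that location, so
  this remains a voting scheme — unlike the classifier schemes it cannot
  learn cross-label rules such as "when tool A says Secretory the protein
  is usually mitochondrial";
* ``naive_bayes`` — categorical naive Bayes with add-one smoothing;
* ``decision_tree`` — CART with a minimum leaf size of 2;
* ``logistic_regression`` — multinomial logistic regression with weak L2
  regularisation (unregularised fits diverge when a predictor separates
  the training data).

The classifier schemes operate on a one-hot encoding with one binary
column per (predictor, observed label) pair; labels unseen at training
time encode as an all-zero block. Vote ties are broken by label-vocabulary
order so predictions are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import CategoricalNB
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .io import PredictionTable

SCHEMES = ("weighted_vote", "lda", "naive_bayes", "decision_tree", "logistic_regression")

_SCHEME_ALIASES = {
    "vote": "weighted_vote",
    "weighted_vote": "weighted_vote",
    "lda": "lda",
    "nb": "naive_bayes",
    "naive_bayes": "naive_bayes",
    "dt": "decision_tree",
    "decision_tree": "decision_tree",
    "lr": "logistic_regression",
    "logistic_regression": "logistic_regression",
}


def canonical_scheme(scheme: str) -> str:
    try:
        return _SCHEME_ALIASES[scheme]
    except KeyError:
        raise ValueError(f"unknown ensemble scheme {scheme!r}") from None


class OneHotLabelEncoder:
    """One-hot encoder for a matrix of categorical predictor labels.

    One binary column per (predictor, label-observed-in-training) pair;
    a label unseen during fit maps to an all-zero block for its predictor.
    """

    def __init__(self, categories: list[list[str]] | None = None):
        self.categories_ = categories

    def fit(self, X: np.ndarray) -> "OneHotLabelEncoder":
        X = np.asarray(X, dtype=object)
        self.categories_ = [
            sorted({str(v) for v in X[:, j]}) for j in range(X.shape[1])
        ]
        return self

    @property
    def n_columns(self) -> int:
        return sum(len(c) for c in self.categories_)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.categories_ is None:
            raise RuntimeError("encoder is not fitted")
        X = np.asarray(X, dtype=object)
        if X.shape[1] != len(self.categories_):
            raise ValueError(
                f"expected {len(self.categories_)} predictor columns, "
                f"got {X.shape[1]}"
            )
        out = np.zeros((X.shape[0], self.n_columns))
        col = 0
        for j, cats in enumerate(self.categories_):
            index = {lab: col + r for r, lab in enumerate(cats)}
            for i in range(X.shape[0]):
                r = index.get(X[i, j])
                if r is not None:
                    out[i, r] = 1.0
            col += len(cats)
        return out

    def to_dict(self) -> dict:
        return {"categories": self.categories_}

    @classmethod
    def from_dict(cls, d: dict) -> "OneHotLabelEncoder":
        return cls(categories=[list(c) for c in d["categories"]])


def encode_features(
    table_or_matrix, subset=None, encoder: OneHotLabelEncoder | None = None
) -> tuple[np.ndarray, OneHotLabelEncoder]:
    """One-hot encode selected predictor columns.

    Accepts a :class:`PredictionTable` or a raw label matrix. With an
    existing ``encoder``, applies it (unseen labels become zero blocks);
    otherwise fits a fresh one on the given data.
    """
    if isinstance(table_or_matrix, PredictionTable):
        X = table_or_matrix.predictions
    else:
        X = np.asarray(table_or_matrix, dtype=object)
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("empty predictor subset")
        X = X[:, subset]
    elif X.shape[1] == 0:
        raise ValueError("empty predictor subset")
    if encoder is None:
        encoder = OneHotLabelEncoder().fit(X)
    return encoder.transform(X), encoder


def weighted_vote(row, weights, vocabulary) -> str:
    """Accuracy-weighted plurality vote over one row of predictor labels.

    Returns the label maximising the weighted vote sum; ties are broken by
    vocabulary order.
    """
    weights = np.asarray(weights, dtype=float)
    if len(row) != weights.shape[0]:
        raise ValueError("weights not aligned with predictors")
    if (weights < 0).any():
        raise ValueError("negative weight")
    scores = {lab: 0.0 for lab in vocabulary}
    for lab, w in zip(row, weights):
        if lab in scores:
            scores[lab] += float(w)
        else:
            scores[lab] = float(w)
    # vocabulary order first, then any out-of-vocabulary labels by name
    ordered = list(vocabulary) + sorted(set(scores) - set(vocabulary))
    return max(ordered, key=lambda lab: (scores[lab], -ordered.index(lab)))


def _fit_lda_voting(X, y, vocabulary, shrinkage):
    """Per-location Fisher-discriminant voting weights.

    For each location c, the binary vote indicators [p_i == c] are
    projected onto the LDA direction separating proteins of class c from
    the rest; the resulting per-predictor weights and intercept give the
    location's score. The pooled covariance gets a shrinkage term because
    vote indicators of coupled predictors are nearly collinear. Locations
    that cannot be fitted (absent from training, or no predictor ever
    votes them) score -inf.
    """
    n, p = X.shape
    weights = np.zeros((len(vocabulary), p))
    intercepts = np.full(len(vocabulary), -np.inf)
    for ci, c in enumerate(vocabulary):
        votes = (X == c).astype(float)
        is_c = (y == c).astype(int)
        if is_c.min() == is_c.max():
            continue  # class absent (or universal) in training
        keep = votes.std(axis=0) > 0
        if not keep.any():
            continue
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        lda.fit(votes[:, keep], is_c)
        # decision_function sign convention: positive means "is class c"
        weights[ci, keep] = lda.coef_[0]
        intercepts[ci] = float(np.atleast_1d(lda.intercept_)[0])
    return weights, intercepts


def _lda_voting_scores(X, vocabulary, weights, intercepts):
    scores = np.empty((X.shape[0], len(vocabulary)))
    for ci, c in enumerate(vocabulary):
        votes = (X == c).astype(float)
        scores[:, ci] = votes @ weights[ci] + intercepts[ci]
    return scores


class EnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Meta-classifier over categorical component-predictor outputs.

    Parameters
    ----------
    scheme : str
        One of ``weighted_vote``, ``lda``, ``naive_bayes``,
        ``decision_tree``, ``logistic_regression`` (short aliases
        ``vote``/``nb``/``dt``/``lr`` accepted).
    vocabulary : sequence of str, optional
        Ordered label vocabulary used for vote tie-breaking and score
        ordering; defaults to the sorted union of labels seen in fit.
    C : float
        Inverse L2 strength for logistic regression (sklearn's default;
        mild regularisation keeps the redundant one-hot encoding from
        overfitting and guarantees convergence on separable data).
    lda_shrinkage : float
        Shrinkage applied to the pooled covariance in LDA, needed because
        one-hot blocks are collinear.
    min_samples_leaf : int
        Minimum leaf size for the decision tree.
    nb_alpha : float
        Laplace smoothing for categorical naive Bayes.
    random_state : int, optional
        Seed forwarded to the underlying estimators.
    """

    def __init__(
        self,
        scheme: str = "logistic_regression",
        vocabulary=None,
        C: float = 1.0,
        lda_shrinkage: float = 1e-6,
        min_samples_leaf: int = 2,
        nb_alpha: float = 1.0,
        random_state: int | None = None,
    ):
        self.scheme = scheme
        self.vocabulary = vocabulary
        self.C = C
        self.lda_shrinkage = lda_shrinkage
        self.min_samples_leaf = min_samples_leaf
        self.nb_alpha = nb_alpha
        self.random_state = random_state

    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=object)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix of categorical labels")
        if y is None:
            return X
        y = np.asarray(y, dtype=object).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        return X, y

    def fit(self, X, y):
        X, y = self._validate(X, y)
        scheme = canonical_scheme(self.scheme)
        self.scheme_ = scheme
        self.n_features_in_ = X.shape[1]
        classes = sorted({str(v) for v in y})
        if scheme in ("lda", "logistic_regression") and len(classes) < 2:
            raise ValueError(f"{scheme} requires at least 2 distinct true labels")
        if self.vocabulary is not None:
            self.vocabulary_ = tuple(self.vocabulary)
        else:
            seen = {str(v) for v in X.ravel()} | set(classes)
            self.vocabulary_ = tuple(sorted(seen))
        self.classes_ = np.asarray(classes, dtype=object)

        if scheme == "weighted_vote":
            self.weights_ = (X == y[:, None]).mean(axis=0).astype(float)
            self.encoder_ = None
            self.model_ = None
            return self

        if scheme == "lda":
            self.lda_weights_, self.lda_intercepts_ = _fit_lda_voting(
                X, y, self.vocabulary_, self.lda_shrinkage
            )
            self.encoder_ = None
            self.model_ = None
            return self

        Xenc, self.encoder_ = encode_features(X)
        if scheme == "logistic_regression":
            model = LogisticRegression(C=self.C, max_iter=2000)
            model.fit(Xenc, y.astype(str))
        elif scheme == "naive_bayes":
            model = CategoricalNB(alpha=self.nb_alpha, min_categories=2)
            model.fit(Xenc.astype(int), y.astype(str))
        elif scheme == "decision_tree":
            model = DecisionTreeClassifier(
                min_samples_leaf=self.min_samples_leaf,
                random_state=self.random_state,
            )
            model.fit(Xenc, y.astype(str))
        else:  # pragma: no cover - canonical_scheme already screens
            raise ValueError(scheme)
        self.model_ = model
        return self

    def predict(self, X):
        check_is_fitted(self, "scheme_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} predictors, expected {self.n_features_in_}"
            )
        if self.scheme_ == "weighted_vote":
            return np.asarray(
                [weighted_vote(row, self.weights_, self.vocabulary_) for row in X],
                dtype=object,
            )
        if self.scheme_ == "lda":
            scores = _lda_voting_scores(
                X, self.vocabulary_, self.lda_weights_, self.lda_intercepts_
            )
            picks = np.argmax(scores, axis=1)  # first index wins: vocab order
            return np.asarray([self.vocabulary_[i] for i in picks], dtype=object)
        Xenc = self.encoder_.transform(X)
        if self.scheme_ == "naive_bayes":
            Xenc = Xenc.astype(int)
        return np.asarray(self.model_.predict(Xenc), dtype=object)

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y, dtype=object)).mean())


@dataclass
class EnsembleModel:
    """A fitted ensemble bound to named component predictors."""

    scheme: str
    selected_predictors: list[str]
    classifier: EnsembleClassifier

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return self.classifier.vocabulary_


def train_meta(
    table: PredictionTable,
    subset,
    scheme: str = "logistic_regression",
    seed: int | None = 0,
    **params,
) -> EnsembleModel:
    """Fit an ensemble on a truth-labelled table restricted to ``subset``."""
    if table.true_labels is None:
        raise ValueError("training requires true labels")
    subset = list(subset)
    if len(subset) == 0:
        raise ValueError("empty predictor subset")
    clf = EnsembleClassifier(scheme=scheme, random_state=seed, **params)
    clf.fit(table.predictions[:, subset], np.asarray(table.true_labels, dtype=object))
    return EnsembleModel(
        scheme=canonical_scheme(scheme),
        selected_predictors=[table.predictor_names[j] for j in subset],
        classifier=clf,
    )


def predict_meta(model: EnsembleModel, table: PredictionTable) -> np.ndarray:
    """Predict unified labels for every protein in ``table``.

    The table must contain every predictor column the model was trained
    on (matched by name; column order in the table is irrelevant).
    """
    name_to_col = {n: j for j, n in enumerate(table.predictor_names)}
    missing = [n for n in model.selected_predictors if n not in name_to_col]
    if missing:
        raise ValueError(f"table is missing predictor column(s): {missing}")
    cols = [name_to_col[n] for n in model.selected_predictors]
    return model.classifier.predict(table.predictions[:, cols])
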