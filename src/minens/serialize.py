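"""Versioned JSON serialization of fitted ensemble models.

A serialized model is a plain JSON document holding the scheme tag, the
selected predictor names, the label vocabulary, the one-hot encoder state
and the learned parameters (weights, coefficient matrices, conditional
log-probability tables or tree arrays). Loaded models predict through
small numpy routines equivalent to the fitted estimators.
"""

from __future__ import annotations

import json

import numpy as np

from .ensemble import EnsembleClassifier, EnsembleModel, OneHotLabelEncoder

FORMAT_VERSION = 1


class _LoadedLinear:
    """argmax(X @ coef.T + intercept) predictor for LR and LDA models."""

    def __init__(self, coef, intercept, classes):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = np.asarray(intercept, dtype=float)
        self.classes = np.asarray(classes, dtype=object)

    def predict(self, Xenc):
        scores = Xenc @ self.coef.T + self.intercept
        if self.coef.shape[0] == 1 and len(self.classes) == 2:
            return self.classes[(scores.ravel() > 0).astype(int)]
        return self.classes[np.argmax(scores, axis=1)]


class _LoadedNaiveBayes:
    """Categorical naive Bayes predictor from stored log-probability tables."""

    def __init__(self, class_log_prior, feature_log_prob, classes):
        self.class_log_prior = np.asarray(class_log_prior, dtype=float)
        self.feature_log_prob = [np.asarray(t, dtype=float) for t in feature_log_prob]
        self.classes = np.asarray(classes, dtype=object)

    def predict(self, Xenc):
        X = np.asarray(Xenc, dtype=int)
        jll = np.tile(self.class_log_prior, (X.shape[0], 1))
        for i, table in enumerate(self.feature_log_prob):
            cats = np.clip(X[:, i], 0, table.shape[1] - 1)
            jll += table[:, cats].T
        return self.classes[np.argmax(jll, axis=1)]


class _LoadedTree:
    """CART predictor from stored node arrays."""

    def __init__(self, children_left, children_right, feature, threshold, value, classes):
        self.left = np.asarray(children_left, dtype=int)
        self.right = np.asarray(children_right, dtype=int)
        self.feature = np.asarray(feature, dtype=int)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(value, dtype=float)
        self.classes = np.asarray(classes, dtype=object)

    def predict(self, Xenc):
        out = np.empty(Xenc.shape[0], dtype=object)
        for i, row in enumerate(np.asarray(Xenc, dtype=float)):
            node = 0
            while self.left[node] != -1:
                if row[self.feature[node]] <= self.threshold[node]:
                    node = self.left[node]
                else:
                    node = self.right[node]
            out[i] = self.classes[int(np.argmax(self.value[node]))]
        return out


def model_to_dict(model: EnsembleModel) -> dict:
    clf = model.classifier
    doc: dict = {
        "format_version": FORMAT_VERSION,
        "scheme": model.scheme,
        "selected_predictors": list(model.selected_predictors),
        "vocabulary": list(clf.vocabulary_),
        "classes": [str(c) for c in clf.classes_],
        "n_features_in": int(clf.n_features_in_),
    }
    if model.scheme == "weighted_vote":
        doc["weights"] = [float(w) for w in clf.weights_]
        return doc
    if model.scheme == "lda":
        # -inf intercepts (unfittable locations) are stored as null
        doc["lda_weights"] = np.asarray(clf.lda_weights_).tolist()
        doc["lda_intercepts"] = [
            float(b) if np.isfinite(b) else None for b in clf.lda_intercepts_
        ]
        return doc
    doc["encoder"] = clf.encoder_.to_dict()
    inner = clf.model_
    if model.scheme == "logistic_regression":
        doc["coef"] = (
            np.asarray(inner.coef).tolist()
            if isinstance(inner, _LoadedLinear)
            else inner.coef_.tolist()
        )
        doc["intercept"] = (
            np.asarray(inner.intercept).tolist()
            if isinstance(inner, _LoadedLinear)
            else np.atleast_1d(inner.intercept_).tolist()
        )
        doc["model_classes"] = [str(c) for c in _inner_classes(inner)]
    elif model.scheme == "naive_bayes":
        if isinstance(inner, _LoadedNaiveBayes):
            prior = inner.class_log_prior
            tables = inner.feature_log_prob
        else:
            prior = inner.class_log_prior_
            tables = inner.feature_log_prob_
        doc["class_log_prior"] = np.asarray(prior).tolist()
        doc["feature_log_prob"] = [np.asarray(t).tolist() for t in tables]
        doc["model_classes"] = [str(c) for c in _inner_classes(inner)]
    elif model.scheme == "decision_tree":
        if isinstance(inner, _LoadedTree):
            doc["tree"] = {
                "children_left": inner.left.tolist(),
                "children_right": inner.right.tolist(),
                "feature": inner.feature.tolist(),
                "threshold": inner.threshold.tolist(),
                "value": inner.value.tolist(),
            }
        else:
            t = inner.tree_
            doc["tree"] = {
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "value": t.value[:, 0, :].tolist(),
            }
        doc["model_classes"] = [str(c) for c in _inner_classes(inner)]
    else:  # pragma: no cover
        raise ValueError(model.scheme)
    return doc


def _inner_classes(inner):
    if hasattr(inner, "classes_"):
        return inner.classes_
    return inner.classes


def model_from_dict(doc: dict) -> EnsembleModel:
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {doc.get('format_version')!r}")
    scheme = doc["scheme"]
    clf = EnsembleClassifier(scheme=scheme)
    clf.scheme_ = scheme
    clf.vocabulary_ = tuple(doc["vocabulary"])
    clf.classes_ = np.asarray(doc["classes"], dtype=object)
    clf.n_features_in_ = int(doc["n_features_in"])
    if scheme == "weighted_vote":
        clf.weights_ = np.asarray(doc["weights"], dtype=float)
        clf.encoder_ = None
        clf.model_ = None
    elif scheme == "lda":
        clf.lda_weights_ = np.asarray(doc["lda_weights"], dtype=float)
        clf.lda_intercepts_ = np.asarray(
            [float("-inf") if b is None else b for b in doc["lda_intercepts"]],
            dtype=float,
        )
        clf.encoder_ = None
        clf.model_ = None
    else:
        clf.encoder_ = OneHotLabelEncoder.from_dict(doc["encoder"])
        if scheme == "logistic_regression":
            clf.model_ = _LoadedLinear(
                doc["coef"], doc["intercept"], doc["model_classes"]
            )
        elif scheme == "naive_bayes":
            clf.model_ = _LoadedNaiveBayes(
                doc["class_log_prior"], doc["feature_log_prob"], doc["model_classes"]
            )
        elif scheme == "decision_tree":
            t = doc["tree"]
            clf.model_ = _LoadedTree(
                t["children_left"],
                t["children_right"],
                t["feature"],
                t["threshold"],
                t["value"],
                doc["model_classes"],
            )
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return EnsembleModel(
        scheme=scheme,
        selected_predictors=list(doc["selected_predictors"]),
        classifier=clf,
    )


def save_model(model: EnsembleModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")


def load_model(path) -> EnsembleModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
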