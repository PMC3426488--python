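import numpy as np
import pytest

from minens import (
    EnsembleClassifier,
    PredictionTable,
    encode_features,
    generate,
    model_from_dict,
    model_to_dict,
    paper_like_config,
    predict_meta,
    train_meta,
    weighted_vote,
)
from tests.conftest import WORKED_ROW, random_table

SCHEMES = ("weighted_vote", "lda", "naive_bayes", "decision_tree", "logistic_regression")


def perfect_table(n=40, seed=0):
    """pred0 always equals the truth; pred1 is noise."""
    rng = np.random.default_rng(seed)
    truth = rng.choice(["A", "B", "C"], size=n)
    noise = rng.choice(["A", "B", "C"], size=n)
    return PredictionTable(
        protein_ids=[f"p{i}" for i in range(n)],
        predictor_names=["oracle", "noise"],
        predictions=np.stack([truth, noise], axis=1).astype(object),
        true_labels=truth.tolist(),
    )


class TestEncoding:
    def test_one_hot_shape_and_row_sums(self):
        X = np.array([["A"], ["B"], ["A"]], dtype=object)
        enc, encoder = encode_features(X)
        assert enc.shape == (3, 2)
        assert enc.sum(axis=1).tolist() == [1.0, 1.0, 1.0]

    def test_column_count_two_predictors_four_labels(self):
        X = np.array(
            [[a, b] for a in "WXYZ" for b in "WXYZ"], dtype=object
        )
        enc, _ = encode_features(X)
        assert enc.shape[1] == 8

    def test_novel_label_encodes_as_zero_block(self):
        X = np.array([["A"], ["B"]], dtype=object)
        _, encoder = encode_features(X)
        out, _ = encode_features(np.array([["Q"]], dtype=object), encoder=encoder)
        assert out.tolist() == [[0.0, 0.0]]

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            encode_features(np.array([["A"]], dtype=object), subset=[])


class TestWeightedVote:
    def test_unanimous_row_wins_regardless_of_weights(self):
        assert (
            weighted_vote(["N", "N", "N"], [0.1, 0.9, 0.4], ("C", "N")) == "N"
        )

    def test_argmax_by_weight(self):
        assert weighted_vote(["A", "B"], [0.9, 0.5], ("A", "B")) == "A"
        assert weighted_vote(["A", "B"], [0.5, 0.9], ("A", "B")) == "B"

    def test_worked_row_equal_weights_gives_majority(self):
        vocab = ("Cytosol", "Mitochondrion", "Nucleus", "Secretory")
        assert weighted_vote(WORKED_ROW, [1.0] * 9, vocab) == "Nucleus"

    def test_tie_broken_by_vocabulary_order(self):
        assert weighted_vote(["A", "B"], [0.5, 0.5], ("B", "A")) == "B"

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_vote(["A", "B"], [0.5, -0.1], ("A", "B"))

    def test_equal_weights_equal_plurality(self):
        rng = np.random.default_rng(3)
        vocab = ("A", "B", "C")
        for _ in range(50):
            row = rng.choice(vocab, size=7).tolist()
            counts = {v: row.count(v) for v in vocab}
            best = max(vocab, key=lambda v: (counts[v], -vocab.index(v)))
            assert weighted_vote(row, [1.0] * 7, vocab) == best


class TestEnsembleClassifier:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_perfect_feature_reaches_training_accuracy_one(self, scheme):
        t = perfect_table()
        model = train_meta(t, [0, 1], scheme=scheme, seed=0)
        pred = predict_meta(model, t)
        assert (pred == np.asarray(t.true_labels, dtype=object)).mean() == 1.0

    def test_vote_weights_are_training_accuracies(self):
        rng = np.random.default_rng(1)
        truth = rng.choice(["A", "B"], size=200)
        p1 = np.where(rng.random(200) < 0.8, truth, np.where(truth == "A", "B", "A"))
        p2 = np.where(rng.random(200) < 0.6, truth, np.where(truth == "A", "B", "A"))
        t = PredictionTable(
            protein_ids=[f"p{i}" for i in range(200)],
            predictor_names=["x", "y"],
            predictions=np.stack([p1, p2], axis=1).astype(object),
            true_labels=truth.tolist(),
        )
        model = train_meta(t, [0, 1], scheme="vote")
        np.testing.assert_allclose(
            model.classifier.weights_,
            [(p1 == truth).mean(), (p2 == truth).mean()],
        )

    @pytest.mark.parametrize("scheme", ["lda", "lr"])
    def test_single_class_training_rejected(self, scheme):
        t = PredictionTable(
            protein_ids=["p1", "p2"],
            predictor_names=["A", "B"],
            predictions=np.array([["X", "Y"], ["Y", "X"]], dtype=object),
            true_labels=["X", "X"],
        )
        with pytest.raises(ValueError):
            train_meta(t, [0, 1], scheme=scheme)

    def test_missing_predictor_column_named_in_error(self, yeast_table):
        model = train_meta(yeast_table, [0, 1, 2], scheme="lr")
        reduced = yeast_table.subset_columns([0, 2, 3])
        with pytest.raises(ValueError, match="YLoc_like"):
            predict_meta(model, reduced)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_column_permutation_invariance(self, scheme, yeast_table):
        # predict_meta matches columns by name, so table column order is
        # irrelevant
        model = train_meta(yeast_table, [0, 2, 5], scheme=scheme, seed=0)
        permuted = yeast_table.subset_columns([8, 5, 2, 0, 1])
        np.testing.assert_array_equal(
            predict_meta(model, yeast_table), predict_meta(model, permuted)
        )

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            EnsembleClassifier(scheme="boosting").fit(
                np.array([["A"], ["B"]], dtype=object), np.array(["A", "B"])
            )

    def test_sklearn_param_protocol(self):
        from sklearn.base import clone

        clf = EnsembleClassifier(scheme="nb", nb_alpha=0.5)
        cloned = clone(clf)
        assert cloned.get_params()["nb_alpha"] == 0.5

    def test_ensemble_beats_best_single_predictor_held_out(self):
        train = generate(paper_like_config("yeast_lowres", n_proteins=800, seed=31)).table
        test = generate(paper_like_config("yeast_lowres", n_proteins=2000, seed=32)).table
        model = train_meta(train, range(9), scheme="lr", seed=0)
        truth = np.asarray(test.true_labels, dtype=object)
        ens_acc = (predict_meta(model, test) == truth).mean()
        best_single = max(
            (test.predictions[:, j] == truth).mean() for j in range(9)
        )
        assert ens_acc > best_single


class TestLogisticRegressionOracle:
    def test_agrees_with_independent_multinomial_fit(self):
        # statsmodels MNLogit fitted on the identical one-hot encoding is
        # an implementation-independent reference for the LR scheme
        import statsmodels.api as sm

        train = generate(paper_like_config("yeast_lowres", n_proteins=800, seed=41)).table
        test = generate(paper_like_config("yeast_lowres", n_proteins=800, seed=42)).table
        model = train_meta(train, range(9), scheme="lr", seed=0)
        ours = predict_meta(model, test)

        Xtr, encoder = encode_features(train.predictions)
        Xte, _ = encode_features(test.predictions, encoder=encoder)
        classes = sorted(set(train.true_labels))
        y = np.array([classes.index(t) for t in train.true_labels])
        ref = sm.MNLogit(y, sm.add_constant(Xtr)).fit_regularized(
            alpha=1.0, disp=False
        )
        probs = ref.predict(sm.add_constant(Xte, has_constant="add"))
        theirs = np.array([classes[i] for i in np.asarray(probs).argmax(axis=1)])
        agreement = (ours == theirs).mean()
        assert agreement >= 0.97


class TestSerialization:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_json_round_trip_preserves_predictions(self, scheme, yeast_table):
        import json

        model = train_meta(yeast_table, [0, 1, 4, 7], scheme=scheme, seed=0)
        doc = json.loads(json.dumps(model_to_dict(model)))
        loaded = model_from_dict(doc)
        fresh = generate(
            paper_like_config("yeast_lowres", n_proteins=300, seed=99)
        ).table
        np.testing.assert_array_equal(
            predict_meta(model, fresh), predict_meta(loaded, fresh)
        )

    def test_unsupported_version_rejected(self):
        with pytest.raises(ValueError, match="format"):
            model_from_dict({"format_version": 99})
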