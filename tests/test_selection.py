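import math
from collections import Counter
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minens import (
    CFSBackwardSelector,
    PredictionTable,
    TopKAccuracySelector,
    cfs_merit,
    exhaustive_search,
    greedy_backward_chain,
    select_minimalist,
    symmetric_uncertainty,
    top_k_by_accuracy,
)
from tests.conftest import random_table


def entropy_oracle(values) -> float:
    counts = Counter(values)
    n = sum(counts.values())
    return -sum(c / n * math.log2(c / n) for c in counts.values())


def su_oracle(x, y) -> float:
    hx, hy = entropy_oracle(x), entropy_oracle(y)
    if hx + hy == 0:
        return 0.0
    hxy = entropy_oracle(list(zip(x, y)))
    return 2 * (hx + hy - hxy) / (hx + hy)


def merit_oracle(table, subset) -> float:
    X = table.predictions
    y = table.true_labels
    k = len(subset)
    r_cf = np.mean([su_oracle(X[:, j].tolist(), y) for j in subset])
    if k == 1:
        return float(r_cf)
    r_ff = np.mean(
        [su_oracle(X[:, a].tolist(), X[:, b].tolist()) for a, b in combinations(subset, 2)]
    )
    return float(k * r_cf / math.sqrt(k + k * (k - 1) * r_ff))


def table_with_duplicate(seed=0, n=120):
    """pred2 is an exact copy of pred0."""
    base = random_table(n, 3, seed, labels=("A", "B", "C"))
    preds = base.predictions.copy()
    preds[:, 2] = preds[:, 0]
    return PredictionTable(
        protein_ids=base.protein_ids,
        predictor_names=base.predictor_names,
        predictions=preds,
        true_labels=base.true_labels,
    )


class TestSymmetricUncertainty:
    def test_identical_balanced_variables(self):
        x = ["A", "B"] * 10
        assert symmetric_uncertainty(x, x) == pytest.approx(1.0)

    def test_constant_vs_varying_is_zero(self):
        x = ["A" if i % 2 else "B" for i in range(20)]
        y = ["C"] * 20
        assert symmetric_uncertainty(x, y) == 0.0

    def test_both_constant_defined_as_zero(self):
        assert symmetric_uncertainty(["A"] * 5, ["B"] * 5) == 0.0

    def test_hand_computed_joint(self):
        # joint counts {(A,A):2, (A,B):1, (B,B):3}
        x = ["A", "A", "A", "B", "B", "B"]
        y = ["A", "A", "B", "B", "B", "B"]
        assert symmetric_uncertainty(x, y) == pytest.approx(su_oracle(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            symmetric_uncertainty(["A"], ["A", "B"])

    @settings(deadline=None, max_examples=50)
    @given(
        data=st.lists(
            st.tuples(st.sampled_from("AB"), st.sampled_from("XYZ")),
            min_size=2,
            max_size=40,
        )
    )
    def test_symmetry_and_range(self, data):
        x = [a for a, _ in data]
        y = [b for _, b in data]
        s = symmetric_uncertainty(x, y)
        assert s == pytest.approx(symmetric_uncertainty(y, x))
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(su_oracle(x, y), abs=1e-12)


class TestCfsMerit:
    def test_singleton_merit_is_feature_class_su(self):
        t = random_table(80, 3, 5)
        m = cfs_merit(t, (1,))
        assert m.merit == pytest.approx(
            symmetric_uncertainty(t.predictions[:, 1], t.true_labels)
        )

    def test_duplicate_pair_never_beats_singleton(self):
        # with k=2 and r_ff=1 the merit collapses exactly to r_cf, so an
        # exact duplicate adds nothing (but also subtracts nothing)
        t = table_with_duplicate()
        pair = cfs_merit(t, (0, 2)).merit
        single = cfs_merit(t, (0,)).merit
        assert pair <= single + 1e-12
        assert pair == pytest.approx(single)

    def test_duplicate_never_increases_merit_of_any_subset(self):
        t = table_with_duplicate()
        for subset in [(0, 1), (0, 1, 2)]:
            with_dup = cfs_merit(t, tuple(sorted(set(subset) | {2}))).merit
            without = cfs_merit(t, tuple(sorted(set(subset) - {2}))).merit
            assert with_dup <= without + 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_subsets_match_oracle(self, seed):
        t = random_table(100, 4, seed, labels=("C", "M", "N", "S"))
        for k in range(1, 5):
            for subset in combinations(range(4), k):
                got = cfs_merit(t, subset).merit
                assert got == pytest.approx(merit_oracle(t, subset), abs=1e-9)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            cfs_merit(random_table(10, 2, 0), ())


class TestGreedyChain:
    def test_chain_structure_nine_predictors(self, yeast_table):
        chain = greedy_backward_chain(yeast_table)
        assert [len(s) for s in chain.subsets] == list(range(9, 0, -1))
        for big, small in zip(chain.subsets, chain.subsets[1:]):
            assert set(small) < set(big)
            assert len(big) - len(small) == 1

    def test_duplicate_removed_first(self):
        t = table_with_duplicate()
        chain = greedy_backward_chain(t)
        removed = set(chain.subsets[0]) - set(chain.subsets[1])
        assert removed <= {0, 2}

    def test_first_removal_maximises_merit(self):
        # oracle: compare against explicit evaluation of all single drops
        t = random_table(150, 5, 3, labels=("C", "M", "N", "S"))
        chain = greedy_backward_chain(t)
        best = max(
            cfs_merit(t, tuple(j for j in range(5) if j != drop)).merit
            for drop in range(5)
        )
        assert chain.merits[1] == pytest.approx(best, abs=1e-12)

    def test_unique_feature_predictor_survives_into_small_subsets(self):
        # the PPI analog has errors independent of all other predictors,
        # so the backward search keeps it long after the redundant
        # composition-based columns are gone
        from minens import generate, paper_like_config

        t = generate(paper_like_config("yeast_lowres", n_proteins=1000, seed=201)).table
        chain = greedy_backward_chain(t)
        assert 0 in chain.subset_of_size(3)


class TestSelectMinimalist:
    def test_full_set_and_tail(self, yeast_table):
        assert select_minimalist(yeast_table, 9) == tuple(range(9))
        assert len(select_minimalist(yeast_table, 1)) == 1

    def test_duplicate_table_drops_one_copy(self):
        t = table_with_duplicate()
        subset = select_minimalist(t, 2)
        assert len(set(subset) & {0, 2}) == 1

    def test_k_out_of_range(self, yeast_table):
        with pytest.raises(ValueError):
            select_minimalist(yeast_table, 0)
        with pytest.raises(ValueError):
            select_minimalist(yeast_table, 10)


class TestTopK:
    def test_matches_sorting_oracle(self, yeast_table):
        acc = (
            yeast_table.predictions
            == np.asarray(yeast_table.true_labels, dtype=object)[:, None]
        ).mean(axis=0)
        for k in (1, 3, 9):
            expected = tuple(sorted(np.argsort(-acc, kind="stable")[:k].tolist()))
            assert top_k_by_accuracy(yeast_table, k) == expected

    def test_ties_broken_by_column_order(self):
        t = PredictionTable(
            protein_ids=["p1", "p2"],
            predictor_names=["A", "B", "C"],
            predictions=np.array(
                [["X", "X", "Y"], ["Y", "Y", "Y"]], dtype=object
            ),
            true_labels=["X", "Y"],
        )
        # A and B both 100% accurate; first column wins the K=1 slot
        assert top_k_by_accuracy(t, 1) == (0,)


class TestExhaustive:
    def test_combination_count(self):
        t = random_table(60, 4, 1)
        _, _, scores = exhaustive_search(t, 2, scheme="vote", folds=3, seed=0)
        assert len(scores) == 6

    def test_full_set_single_combination(self):
        t = random_table(60, 4, 2)
        best, _, scores = exhaustive_search(t, 4, scheme="vote", folds=3, seed=0)
        assert best == (0, 1, 2, 3)
        assert len(scores) == 1

    def test_best_dominates_minimalist_subset(self, yeast_table):
        k = 3
        best, best_acc, scores = exhaustive_search(
            yeast_table, k, scheme="vote", folds=5, seed=11
        )
        from minens import cross_validate

        mini = select_minimalist(yeast_table, k)
        mini_acc = cross_validate(
            yeast_table, mini, scheme="vote", folds=5, seed=11
        ).overall_accuracy
        assert best_acc >= mini_acc - 1e-12


class TestSklearnSelectors:
    def test_cfs_selector_matches_function(self, yeast_table):
        sel = CFSBackwardSelector(k=3).fit(
            yeast_table.predictions, np.asarray(yeast_table.true_labels, dtype=object)
        )
        assert sel.selected_indices_ == select_minimalist(yeast_table, 3)
        reduced = sel.transform(yeast_table.predictions)
        assert reduced.shape == (yeast_table.n_proteins, 3)

    def test_topk_selector_matches_function(self, yeast_table):
        sel = TopKAccuracySelector(k=4).fit(
            yeast_table.predictions, np.asarray(yeast_table.true_labels, dtype=object)
        )
        assert sel.selected_indices_ == top_k_by_accuracy(yeast_table, 4)
        assert sel.get_support().sum() == 4

    def test_selector_clonable(self):
        from sklearn.base import clone

        sel = CFSBackwardSelector(k=2)
        assert clone(sel).get_params() == sel.get_params()
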