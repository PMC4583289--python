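"""The cost-sensitive tree learner: priors, splits, growth, pruning,
flattening."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lgibtree as lt
from lgibtree.cart import (
    NodeStats,
    PriorSpec,
    delta_impurity,
    flatten,
    gini,
    weights_from_prior,
)
from lgibtree.core import Admission, Cohort, Field
from lgibtree.rules import classify

from conftest import cohorts, oracle_best_split


def labeled(id_, principal, secondary=(), lgib=False):
    return Admission(id_, principal, frozenset(secondary), lgib=lgib)


class TestPriorWeights:
    def test_derivation_cohort_ratios_round_to_published_folds(self):
        assert round(weights_from_prior(0.20, 297, 6677).ratio) == 6
        assert round(weights_from_prior(0.70, 297, 6677).ratio) == 52

    def test_empirical_prior_is_unweighted(self):
        spec = weights_from_prior(297 / 6974, 297, 6677)
        assert spec.ratio == pytest.approx(1.0)

    def test_root_weighted_proportion_recovers_pi(self):
        for pi in (0.1, 0.2, 0.5, 0.7, 0.9):
            spec = weights_from_prior(pi, 297, 6677)
            stats = NodeStats(297, 6677, spec.w_case, spec.w_noncase)
            assert stats.p_case == pytest.approx(pi)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_priors_rejected(self, bad):
        with pytest.raises(lt.LgibError):
            weights_from_prior(bad, 10, 10)

    def test_degenerate_counts_rejected(self):
        with pytest.raises(lt.LgibError):
            weights_from_prior(0.5, 0, 10)


def test_gini_shape():
    assert gini(0.0) == 0.0
    assert gini(1.0) == 0.0
    assert gini(0.5) == 0.25
    assert gini(0.04) == pytest.approx(0.0384)
    with pytest.raises(lt.LgibError):
        gini(1.2)


class TestDeltaImpurity:
    def test_perfect_split_of_balanced_parent(self):
        parent = NodeStats(10, 10, 1.0, 1.0)
        left = NodeStats(10, 0, 1.0, 1.0)
        right = NodeStats(0, 10, 1.0, 1.0)
        assert delta_impurity(parent, left, right) == pytest.approx(0.25)

    def test_empty_child_rejected(self):
        parent = NodeStats(10, 10, 1.0, 1.0)
        with pytest.raises(lt.LgibError, match="empty child"):
            delta_impurity(parent, parent, NodeStats(0, 0, 1.0, 1.0))

    def test_non_partition_rejected(self):
        parent = NodeStats(10, 10, 1.0, 1.0)
        with pytest.raises(lt.LgibError, match="partition"):
            delta_impurity(parent, NodeStats(3, 3, 1.0, 1.0), NodeStats(3, 3, 1.0, 1.0))


class TestBestSplitAgainstOracle:
    @given(
        cohorts(min_size=6, max_size=40, both_classes=True),
        st.sampled_from([0.2, 0.5, 0.7]),
        st.sampled_from([1, 2, 7]),
    )
    @settings(max_examples=60)
    def test_matches_exhaustive_search(self, cohort, pi, min_node):
        n1 = cohort.n_lgib
        spec = weights_from_prior(pi, n1, len(cohort) - n1)
        expected = oracle_best_split(cohort, spec.w_case, spec.w_noncase, min_node)
        got = lt.best_split(cohort, spec, min_node=min_node)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert got.feature == expected[1]
            assert got.delta == pytest.approx(expected[0])

    def test_matches_oracle_on_200_record_cohort(self):
        rng = np.random.default_rng(42)
        codes = [f"C{i}" for i in range(25)]
        adms = []
        for i in range(200):
            lgib = bool(rng.random() < 0.3)
            principal = codes[rng.integers(0, 10)] if not lgib else codes[rng.integers(0, 25)]
            secondary = frozenset(
                rng.choice(codes, size=rng.integers(0, 5), replace=False).tolist()
            )
            adms.append(Admission(f"r{i}", principal, secondary, lgib=lgib))
        cohort = Cohort(tuple(adms))
        spec = weights_from_prior(0.5, cohort.n_lgib, len(cohort) - cohort.n_lgib)
        expected = oracle_best_split(cohort, spec.w_case, spec.w_noncase, 7)
        got = lt.best_split(cohort, spec, min_node=7)
        assert got.feature == expected[1]
        assert got.delta == pytest.approx(expected[0])

    def test_perfect_separator_is_chosen(self):
        adms = [labeled(f"p{i}", "SIG", lgib=True) for i in range(10)]
        adms += [labeled(f"n{i}", f"BG{i % 3}", lgib=False) for i in range(10)]
        cohort = Cohort(tuple(adms))
        spec = weights_from_prior(0.5, 10, 10)
        ev = lt.best_split(cohort, spec, min_node=1)
        assert ev.feature == (Field.PRINCIPAL_DX, "SIG")
        assert ev.delta == pytest.approx(0.25)

    def test_derivation_like_fixture_splits_on_principal_562_12(self, table3_fixture):
        spec = weights_from_prior(0.20, 297, 6677)
        ev = lt.best_split(table3_fixture, spec, min_node=7)
        assert ev.feature == (Field.PRINCIPAL_DX, "562.12")


class TestGrowTree:
    def test_single_class_cohort_gives_root_only_tree(self):
        cohort = Cohort(tuple(labeled(f"a{i}", "X", lgib=True) for i in range(5)))
        tree = lt.grow_tree(cohort, pi=0.5)
        assert tree.root.is_leaf and tree.root.prediction is True

    def test_no_informative_feature_gives_majority_root(self):
        adms = [labeled(f"a{i}", "SAME", lgib=(i < 3)) for i in range(10)]
        tree = lt.grow_tree(Cohort(tuple(adms)), pi=0.3, min_node=1)
        assert tree.root.is_leaf and tree.root.prediction is False

    def test_separable_two_feature_cohort_has_zero_training_error(self):
        adms = [labeled(f"p{i}", "A", {"K"}, lgib=True) for i in range(8)]
        adms += [labeled(f"q{i}", "B", {"K"}, lgib=True) for i in range(8)]
        adms += [labeled(f"n{i}", "C", {"L"}, lgib=False) for i in range(8)]
        cohort = Cohort(tuple(adms))
        tree = lt.grow_tree(cohort, pi=0.5, min_node=1)
        assert all(tree.predict(a) == a.lgib for a in cohort)
        depth = 0
        node = tree.root
        while not node.is_leaf:
            depth += 1
            node = node.absent
        assert tree.n_leaves <= 4

    @given(cohorts(min_size=10, max_size=40, both_classes=True))
    @settings(max_examples=25)
    def test_terminal_nodes_respect_min_node_or_purity(self, cohort):
        tree = lt.grow_tree(cohort, pi=0.4, min_node=3)
        for leaf in tree.root.leaves():
            assert leaf.stats.n >= 3 or leaf.stats.is_pure

    def test_grown_tree_refines_single_split_on_training_data(self, table3_fixture):
        from lgibtree.evaluation import evaluate

        full = flatten(lt.grow_tree(table3_fixture, pi=0.20))
        single = flatten(lt.grow_tree(table3_fixture, pi=0.20, max_depth=1))
        _, m_full = evaluate(full, table3_fixture)
        _, m_single = evaluate(single, table3_fixture)
        assert m_full.sensitivity >= m_single.sensitivity


class TestPrune:
    def _noisy_cohort(self, seed, n=300):
        rng = np.random.default_rng(seed)
        adms = []
        for i in range(n):
            lgib = bool(rng.random() < 0.5)  # labels independent of codes
            principal = f"P{rng.integers(0, 6)}"
            secondary = frozenset(f"S{j}" for j in rng.integers(0, 12, size=3))
            adms.append(Admission(f"x{i}", principal, secondary, lgib=lgib))
        return Cohort(tuple(adms))

    def test_noise_fits_are_pruned_back(self):
        cohort = self._noisy_cohort(7)
        tree = lt.grow_tree(cohort, pi=0.5, min_node=7)
        assert tree.n_leaves > 1  # it did overfit the noise
        pruned = lt.prune(tree, cohort, folds=5, seed=0)
        assert pruned.n_leaves < tree.n_leaves

    def test_prune_is_deterministic_under_seed(self):
        cohort = self._noisy_cohort(8)
        tree = lt.grow_tree(cohort, pi=0.5, min_node=7)
        p1 = lt.prune(tree, cohort, folds=5, seed=3)
        p2 = lt.prune(tree, cohort, folds=5, seed=3)
        assert flatten(p1).clauses == flatten(p2).clauses
        assert p1.n_leaves == p2.n_leaves

    def test_signal_survives_pruning(self):
        # one strongly predictive code plus noise: pruning keeps the signal
        rng = np.random.default_rng(5)
        adms = []
        for i in range(400):
            sig = bool(rng.random() < 0.2)
            lgib = bool(rng.random() < (0.9 if sig else 0.05))
            principal = "SIG" if sig else f"P{rng.integers(0, 5)}"
            secondary = frozenset(f"S{j}" for j in rng.integers(0, 10, size=2))
            adms.append(Admission(f"x{i}", principal, secondary, lgib=lgib))
        cohort = Cohort(tuple(adms))
        tree = lt.grow_tree(cohort, pi=0.5, min_node=7)
        pruned = lt.prune(tree, cohort, folds=5, seed=1)
        assert not pruned.root.is_leaf
        assert pruned.root.feature == (Field.PRINCIPAL_DX, "SIG")

    def test_too_few_folds_rejected(self, table3_fixture):
        tree = lt.grow_tree(table3_fixture, pi=0.2, max_depth=1)
        with pytest.raises(lt.LgibError, match="folds"):
            lt.prune(tree, table3_fixture, folds=1)


class TestFlatten:
    def test_root_only_negative_tree_is_empty_rule(self):
        cohort = Cohort(tuple(labeled(f"a{i}", "X", lgib=False) for i in range(5)))
        rule = flatten(lt.grow_tree(cohort, pi=0.5))
        assert rule.clauses == ()
        assert rule.default is False

    def test_single_split_flattens_to_one_simple_clause(self):
        adms = [labeled(f"p{i}", "562.12", lgib=True) for i in range(10)]
        adms += [labeled(f"n{i}", f"BG{i % 2}", lgib=False) for i in range(10)]
        tree = lt.grow_tree(Cohort(tuple(adms)), pi=0.5, min_node=1, max_depth=1)
        rule = flatten(tree)
        assert len(rule.clauses) == 1
        assert rule.clauses[0].is_simple
        assert rule.clauses[0].field is Field.PRINCIPAL_DX
        assert rule.clauses[0].code == "562.12"

    def test_single_branch_tree_flattens_without_negative_literals(self, table3_fixture):
        tree = lt.grow_tree(table3_fixture, pi=0.20)
        rule = flatten(tree)
        assert all(cl.is_simple for cl in rule.clauses)

    @given(
        cohorts(min_size=10, max_size=40, both_classes=True),
        st.sampled_from([0.2, 0.5, 0.8]),
    )
    @settings(max_examples=25)
    def test_tree_and_flattened_rule_agree_everywhere(self, cohort, pi):
        tree = lt.grow_tree(cohort, pi=pi, min_node=2)
        rule = flatten(tree)
        for a in cohort:
            assert classify(rule, a)[0] == tree.predict(a)


def test_root_split_matches_sklearn_reference():
    """Independent cross-check: with identical class weights, the first
    split of a reference CART implementation (sklearn) agrees with ours."""
    sklearn = pytest.importorskip("sklearn.tree")
    rng = np.random.default_rng(0)
    codes = [f"C{i}" for i in range(12)]
    adms = []
    for i in range(300):
        lgib = bool(rng.random() < 0.25)
        principal = codes[rng.integers(0, 4)] if lgib else codes[rng.integers(0, 12)]
        secondary = frozenset(
            rng.choice(codes, size=rng.integers(0, 4), replace=False).tolist()
        )
        adms.append(Admission(f"s{i}", principal, secondary, lgib=lgib))
    cohort = Cohort(tuple(adms))
    spec = weights_from_prior(0.5, cohort.n_lgib, len(cohort) - cohort.n_lgib)
    ours = lt.best_split(cohort, spec, min_node=7)

    from lgibtree.cart import _Dataset

    ds = _Dataset(cohort)
    clf = sklearn.DecisionTreeClassifier(
        max_depth=1,
        min_samples_leaf=7,
        class_weight={True: spec.w_case, False: spec.w_noncase},
        random_state=0,
    )
    clf.fit(ds.X.toarray(), ds.y)
    ref_feature = ds.features[clf.tree_.feature[0]]
    assert ours.feature == ref_feature
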