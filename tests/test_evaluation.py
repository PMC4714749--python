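"""AUC, hierarchical metrics, cross-validation, rank-sum and pruning."""

import numpy as np
import pandas as pd
import pytest

from fgga import (
    DagSpec,
    SimSpec,
    UndefinedMetricError,
    cross_validate,
    hierarchical_prf,
    prune_predicted_graph,
    random_godag,
    ranksum_compare,
    sample_annotations,
    term_auc,
)
from fgga.evaluation import stratified_folds
from fgga.ontology import GoDag, GoTerm


class TestTermAuc:
    def test_perfect_separation(self):
        assert term_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs_ordered(self):
        assert term_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_label_inversion_symmetry(self):
        scores = [0.9, 0.4, 0.6, 0.1]
        labels = [1, 1, 0, 0]
        inverted = [0, 0, 1, 1]
        assert term_auc(scores, labels) == pytest.approx(
            1 - term_auc(scores, inverted)
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        assert term_auc(np.exp(scores), labels) == pytest.approx(
            term_auc(scores, labels)
        )

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            term_auc([0.5, 0.6], [1, 1])


@pytest.fixture
def chain3():
    """root -> a -> b, for set-arithmetic checks."""
    return GoDag(
        [GoTerm("GO:root"), GoTerm("GO:a"), GoTerm("GO:b")],
        [("GO:a", "GO:root"), ("GO:b", "GO:a")],
    )


class TestHierarchicalPrf:
    def frame(self, rows):
        """rows: list of dicts term -> label."""
        return pd.DataFrame(rows).astype("int8")

    def test_identical_sets_score_one(self, chain3):
        truth = self.frame([
            {"GO:root": 1, "GO:a": 1, "GO:b": 1},
            {"GO:root": 1, "GO:a": 1, "GO:b": 0},
        ])
        hm = hierarchical_prf(chain3, truth, truth)
        assert (hm.HP, hm.HR, hm.HF) == (1.0, 1.0, 1.0)

    def test_parent_only_prediction(self, chain3):
        # truth {a, b}, prediction {a}: HP=1, HR=1/2, HF=2/3
        truth = self.frame([{"GO:root": 1, "GO:a": 1, "GO:b": 1}])
        pred = self.frame([{"GO:root": 1, "GO:a": 1, "GO:b": 0}])
        hm = hierarchical_prf(chain3, pred, truth)
        assert hm.HP == 1.0
        assert hm.HR == pytest.approx(0.5)
        assert hm.HF == pytest.approx(2 / 3)

    def test_empty_conventions(self, chain3):
        empty = self.frame([{"GO:root": 1, "GO:a": 0, "GO:b": 0}])  # empty set
        full = self.frame([{"GO:root": 1, "GO:a": 1, "GO:b": 1}])
        both_empty = hierarchical_prf(chain3, empty, empty)
        assert (both_empty.HP, both_empty.HR, both_empty.HF) == (1.0, 1.0, 1.0)
        miss = hierarchical_prf(chain3, empty, full)
        assert (miss.HP, miss.HR, miss.HF) == (0.0, 0.0, 0.0)

    def test_disjoint_nonempty_sets(self):
        dag = GoDag(
            [GoTerm("GO:r"), GoTerm("GO:x"), GoTerm("GO:y")],
            [("GO:x", "GO:r"), ("GO:y", "GO:r")],
        )
        pred = self.frame([{"GO:r": 1, "GO:x": 1, "GO:y": 0}])
        truth = self.frame([{"GO:r": 1, "GO:x": 0, "GO:y": 1}])
        hm = hierarchical_prf(dag, pred, truth)
        assert (hm.HP, hm.HR, hm.HF) == (0.0, 0.0, 0.0)

    def test_non_closed_input_rejected(self, chain3):
        bad = self.frame([{"GO:root": 1, "GO:a": 0, "GO:b": 1}])
        good = self.frame([{"GO:root": 1, "GO:a": 1, "GO:b": 1}])
        with pytest.raises(ValueError, match="repair_labels"):
            hierarchical_prf(chain3, bad, good)


class TestRanksum:
    def test_identical_samples_tie(self):
        stat, p, verdict = ranksum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert verdict == "tie"
        assert p == 1.0

    def test_fully_separated_small_samples_exact_p(self):
        # exact two-sided p = 2 / C(10,5) = 2/252
        stat, p, verdict = ranksum_compare([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert p == pytest.approx(2 / 252)
        assert verdict == "a"

    def test_swap_flips_winner_keeps_p(self):
        a, b = [6, 7, 8, 9, 10], [1, 2, 3, 4, 5]
        _, p_ab, w_ab = ranksum_compare(a, b)
        _, p_ba, w_ba = ranksum_compare(b, a)
        assert p_ab == pytest.approx(p_ba)
        assert (w_ab, w_ba) == ("a", "b")

    def test_large_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = np.round(rng.normal(0.7, 0.05, 60), 2)
        b = np.round(rng.normal(0.5, 0.05, 60), 2)
        _, p, verdict = ranksum_compare(a, b)
        assert verdict == "a"
        assert p < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ranksum_compare([], [1.0])


class TestPrunePredictedGraph:
    def test_all_confident_marginals_keep_whole_subgraph(self, toy7):
        marg = pd.Series(1.0, index=list(toy7.term_ids))
        pruned = prune_predicted_graph(toy7, marg)
        assert set(pruned.kept) == set(toy7.term_ids)

    def test_low_confidence_leaf_removed(self, toy7):
        marg = pd.Series(0.99, index=list(toy7.term_ids))
        marg["GO:0000007"] = 0.6  # leaf under the default 0.95 cut
        pruned = prune_predicted_graph(toy7, marg)
        assert "GO:0000007" not in pruned.kept
        assert "GO:0000004" in pruned.leaves  # exposed as the new leaf

    def test_removal_cascades_up_a_chain(self):
        # 3-level chain below the root: removing the weak bottom leaf
        # exposes its weak parent, which is then removed too, so the bottom
        # two levels collapse and the confident top level becomes the leaf
        dag = GoDag(
            [GoTerm(t) for t in ["GO:r", "GO:l1", "GO:l2", "GO:l3"]],
            [("GO:l1", "GO:r"), ("GO:l2", "GO:l1"), ("GO:l3", "GO:l2")],
        )
        marg = pd.Series({"GO:r": 1.0, "GO:l1": 0.99, "GO:l2": 0.90, "GO:l3": 0.94})
        pruned = prune_predicted_graph(dag, marg, leaf_cut=0.95)
        assert pruned.kept == ("GO:l1", "GO:r")
        assert list(pruned.leaves) == ["GO:l1"]

    def test_confident_leaf_shields_its_weaker_ancestors(self):
        # only leaves of the current subgraph are ever tested, so a leaf
        # above the cut keeps its whole ancestor path regardless of their
        # marginals
        dag = GoDag(
            [GoTerm(t) for t in ["GO:r", "GO:l1", "GO:l2", "GO:l3"]],
            [("GO:l1", "GO:r"), ("GO:l2", "GO:l1"), ("GO:l3", "GO:l2")],
        )
        marg = pd.Series({"GO:r": 1.0, "GO:l1": 0.99, "GO:l2": 0.90, "GO:l3": 0.99})
        pruned = prune_predicted_graph(dag, marg, leaf_cut=0.95)
        assert set(pruned.kept) == {"GO:r", "GO:l1", "GO:l2", "GO:l3"}

    def test_kept_set_closed_and_subset_of_positives(self, toy7):
        rng = np.random.default_rng(2)
        marg = pd.Series(rng.random(7), index=list(toy7.term_ids))
        marg[toy7.root] = 1.0
        pruned = prune_predicted_graph(toy7, marg, leaf_cut=0.8)
        kept = set(pruned.kept)
        for c, p in toy7.edges:
            if c in kept:
                assert p in kept
        assert all(marg[t] > 0.5 or t == toy7.root for t in kept)

    def test_top_k_ordering(self, toy7):
        marg = pd.Series(1.0, index=list(toy7.term_ids))
        marg["GO:0000006"] = 0.97
        marg["GO:0000007"] = 0.99
        pruned = prune_predicted_graph(toy7, marg, top_k=2)
        assert pruned.top[0][1] >= pruned.top[1][1]


@pytest.fixture(scope="module")
def cv_setup():
    dag = random_godag(DagSpec(n_terms=10, n_levels=4, max_parents=2, seed=5))
    sim = SimSpec(theta=0.8, eta=0.25, n_samples=120, seed=5)
    labels = sample_annotations(dag, sim)
    rng = np.random.default_rng(5)
    feats = pd.DataFrame(
        labels.to_numpy(float) + rng.normal(0, 0.3, labels.shape),
        index=labels.index,
        columns=[f"f{i}" for i in range(labels.shape[1])],
    )
    return dag, labels, feats


class TestCrossValidate:
    def test_folds_partition_the_gene_set(self, cv_setup):
        dag, labels, feats = cv_setup
        folds = stratified_folds(labels, k=3, seed=1)
        assert set(folds.index) == set(labels.index)
        assert set(folds.unique()) == {0, 1, 2}

    def test_same_seed_gives_identical_folds(self, cv_setup):
        dag, labels, feats = cv_setup
        a = stratified_folds(labels, k=3, seed=7)
        b = stratified_folds(labels, k=3, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_per_term_positive_counts_balanced(self, cv_setup):
        dag, labels, feats = cv_setup
        k = 3
        folds = stratified_folds(labels, k=k, seed=2)
        counts = labels.sum(axis=0)
        for term in labels.columns:
            pos = labels.index[labels[term] == 1]
            per_fold = folds.loc[pos].value_counts().reindex(range(k), fill_value=0)
            # ancestor-closed labels nest, so ancestors inherit their
            # descendants' assignments; the rarest (freely dealt) term is
            # balanced to +/-1 and every term's spread stays within 2
            assert per_fold.max() - per_fold.min() <= 2
            if counts[term] == counts.drop(dag.root).min():
                assert abs(per_fold - len(pos) / k).max() <= 1 + 1e-9

    def test_full_protocol_outputs(self, cv_setup):
        dag, labels, feats = cv_setup
        cv = cross_validate(labels, feats, dag, k=3, seed=5)
        assert set(cv.auc) == {"flat", "tpr_dag", "fgga"}
        mean_auc = cv.mean_auc().mean()
        assert (mean_auc > 0.8).all()  # low-noise features are informative
        hier = cv.mean_hier()
        assert set(hier.index) == {"flat", "tpr_dag", "fgga"}
        assert ((hier >= 0) & (hier <= 1)).all().all()
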