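"""Clustering statistics and cross-validated classifiers."""

import numpy as np
import pandas as pd
import pytest

from mdinet.evaluation import (
    LinkageTree,
    hca,
    hca_correct_clustering,
    hca_correct_first_cluster,
    hca_discrimination_distance,
    kmeans_cluster,
    kmeans_eval,
    permutation_test,
    plsda_classify_cv,
    recommended_plsda_components,
    rf_classify_cv,
    roc_auc_cv,
    select_components_q2,
)


def _blobs(n_classes=3, per_class=4, sep=20.0, seed=0, dims=4):
    """Well-separated class clouds; between-class >> within-class distances."""
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    idx = []
    for c in range(n_classes):
        center = rng.normal(0, 1, dims) + sep * c
        for j in range(per_class):
            sid = f"c{c}s{j}"
            rows.append(center + rng.normal(0, 0.1, dims))
            labels[sid] = f"class{c}"
            idx.append(sid)
    return pd.DataFrame(rows, index=idx), labels


class TestHca:
    def test_merge_count_and_monotone_heights(self):
        prof, _ = _blobs()
        tree = hca(prof)
        assert tree.merges.shape[0] == prof.shape[0] - 1
        assert (np.diff(tree.merges[:, 2]) >= -1e-12).all()

    def test_separated_blobs_cluster_perfectly(self):
        prof, labels = _blobs()
        tree = hca(prof)
        assert hca_correct_clustering(tree, labels) == 100.0
        assert hca_correct_first_cluster(tree, labels) == 100.0
        # every first merge happens within class: the first n_classes merges
        # all involve same-class leaves by construction of the blobs
        assert hca_discrimination_distance(tree, labels) > 0.5

    def test_correct_clustering_partial(self):
        # 4 classes, one contaminated: force B1 next to the A cloud
        prof, labels = _blobs(n_classes=4, per_class=3)
        prof.loc["c1s0"] = prof.loc["c0s0"] + 0.01
        tree = hca(prof)
        assert hca_correct_clustering(tree, labels) == 50.0  # classes 0 and 1 broken
        assert hca_correct_clustering(tree, {s: "x" for s in prof.index}) == 100.0

    def test_every_class_mixed_scores_zero(self):
        prof, _ = _blobs(n_classes=2, per_class=3)
        # alternate labels so no pure subtree of size > 1 matches a class
        labels = {s: f"m{i % 2}" for i, s in enumerate(sorted(prof.index))}
        tree = hca(prof)
        assert hca_correct_clustering(tree, labels) == 0.0
        assert hca_discrimination_distance(tree, labels) == 0.0


class TestDiscriminationDistance:
    def _tree(self):
        # leaves 0..3; classes: {0,1} = A, {2,3} = B
        # A forms at h=1 (node 4), B at h=2 (node 5), root at h=5 (node 6)
        merges = np.array(
            [[0.0, 1.0, 1.0, 2.0], [2.0, 3.0, 2.0, 2.0], [4.0, 5.0, 5.0, 4.0]]
        )
        return LinkageTree(merges, ["a1", "a2", "b1", "b2"])

    def test_gap_variant(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        tree = self._tree()
        # A: (5-1)/5 = 0.8; B: (5-2)/5 = 0.6 -> mean 0.7
        assert hca_discrimination_distance(tree, labels) == pytest.approx(0.7)

    def test_absorption_variant(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        # both classes absorbed at the root height 5 -> 1.0 each
        assert hca_discrimination_distance(
            self._tree(), labels, variant="absorption"
        ) == pytest.approx(1.0)

    def test_incorrect_class_contributes_zero(self):
        labels = {"a1": "A", "a2": "B", "b1": "B", "b2": "A"}
        assert hca_discrimination_distance(self._tree(), labels) == 0.0

    def test_singleton_class_formation_height_zero(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "C"}
        tree = self._tree()
        # B and C are leaves (form at 0), absorbed at h=2 -> 0.4 each;
        # A: 0.8 -> mean (0.8 + 0.4 + 0.4)/3
        assert hca_discrimination_distance(tree, labels) == pytest.approx(
            (0.8 + 0.4 + 0.4) / 3
        )


class TestFirstCluster:
    def test_bad_first_merge_counts_both_endpoints(self):
        merges = np.array(
            [[0.0, 2.0, 1.0, 2.0], [1.0, 3.0, 2.0, 2.0], [4.0, 5.0, 4.0, 4.0]]
        )
        tree = LinkageTree(merges, ["A1", "A2", "B1", "B2"])
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        # A1 merges first with B1 and A2 with B2: all four samples wrong
        assert hca_correct_first_cluster(tree, labels) == 0.0

    def test_joining_existing_pure_cluster_is_correct(self):
        merges = np.array(
            [[0.0, 1.0, 1.0, 2.0], [2.0, 4.0, 2.0, 3.0], [3.0, 5.0, 4.0, 4.0]]
        )
        tree = LinkageTree(merges, ["A1", "A2", "A3", "B1"])
        labels = {"A1": "A", "A2": "A", "A3": "A", "B1": "B"}
        # A3 joins the pure pair {A1, A2}: correct; B1 then joins a pure
        # A-cluster: wrong for B1 only
        assert hca_correct_first_cluster(tree, labels) == 75.0


class TestKmeans:
    def test_blobs_recovered_and_inertia_optimal(self):
        prof, labels = _blobs(n_classes=2, per_class=5)
        part, centroids, inertia = kmeans_cluster(prof, 2, restarts=20, seed=0)
        res = kmeans_eval(part, centroids, labels)
        assert res.correct_clustering_pct == 100.0
        assert res.adjusted_rand == 1.0
        singles = [
            kmeans_cluster(prof, 2, restarts=1, seed=s)[2] for s in range(5)
        ]
        assert inertia <= min(singles) + 1e-9

    def test_k_equals_n_gives_zero_inertia(self):
        prof, _ = _blobs(n_classes=2, per_class=2)
        _, _, inertia = kmeans_cluster(prof, prof.shape[0], restarts=5, seed=0)
        assert inertia == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="more clusters"):
            kmeans_cluster(prof, prof.shape[0] + 1)

    def test_discrimination_distance_normalization(self):
        part = pd.Series([0, 0, 1, 1], index=["a1", "a2", "b1", "b2"])
        centroids = np.array([[0.0, 0.0], [4.0, 0.0]])
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = kmeans_eval(part, centroids, labels)
        assert res.discrimination_distance == pytest.approx(1.0)

    def test_random_labels_have_near_zero_ari(self):
        rng = np.random.default_rng(0)
        prof, labels = _blobs(n_classes=2, per_class=6)
        part, cents, _ = kmeans_cluster(prof, 2, seed=0)
        samples = list(part.index)
        aris = []
        for _ in range(300):
            y = rng.permutation([labels[s] for s in samples])
            shuffled = dict(zip(samples, y))
            aris.append(kmeans_eval(part, cents, shuffled).adjusted_rand)
        assert abs(np.mean(aris)) < 0.05


class TestClassifiers:
    def test_rf_separable_and_reproducible(self):
        prof, labels = _blobs(n_classes=2, per_class=6)
        y = [labels[s] for s in prof.index]
        r1 = rf_classify_cv(prof, y, n_folds=3, n_iterations=3, n_trees=30, seed=1)
        r2 = rf_classify_cv(prof, y, n_folds=3, n_iterations=3, n_trees=30, seed=1)
        assert r1.accuracy_mean == 1.0
        assert r1.accuracies == r2.accuracies
        assert 0.0 <= r1.accuracy_mean <= 1.0 and r1.accuracy_sd >= 0.0

    def test_rf_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(
            rng.normal(size=(24, 5)), index=[f"s{i}" for i in range(24)]
        )
        y = rng.permutation(["A", "B"] * 12)
        r = rf_classify_cv(prof, y, n_folds=3, n_iterations=20, n_trees=30, seed=0)
        assert abs(r.accuracy_mean - 0.5) < 0.15

    def test_rf_fold_count_guard(self):
        prof, labels = _blobs(n_classes=2, per_class=2)
        with pytest.raises(ValueError, match="fewer than"):
            rf_classify_cv(prof, [labels[s] for s in prof.index], n_folds=3)

    def test_plsda_separable_two_and_three_class(self):
        for n_classes in (2, 3):
            prof, labels = _blobs(n_classes=n_classes, per_class=6)
            y = [labels[s] for s in prof.index]
            r = plsda_classify_cv(prof, y, n_components=2, n_folds=3,
                                  n_iterations=3, seed=0)
            assert r.accuracy_mean == 1.0

    def test_plsda_component_bounds_and_defaults(self):
        prof, labels = _blobs(n_classes=2, per_class=4, dims=3)
        y = [labels[s] for s in prof.index]
        with pytest.raises(ValueError, match="exceeds"):
            plsda_classify_cv(prof, y, n_components=10)
        assert recommended_plsda_components("MDBI") == 4
        assert recommended_plsda_components("wmdbi") == 6
        assert recommended_plsda_components("degree") == "auto"

    def test_q2_selection_runs_and_is_bounded(self):
        prof, labels = _blobs(n_classes=2, per_class=6, dims=6)
        y = [labels[s] for s in prof.index]
        a = select_components_q2(prof, y, max_components=5, seed=0)
        assert 1 <= a <= 5

    def test_transformer_hook_sees_train_only(self):
        prof, labels = _blobs(n_classes=2, per_class=4)
        y = [labels[s] for s in prof.index]
        seen = []

        def spy(xtr, ytr, xte):
            seen.append((len(xtr), len(xte)))
            assert len(xtr) + len(xte) == len(y)
            return xtr, xte

        rf_classify_cv(prof, y, n_folds=2, n_iterations=1, n_trees=5, seed=0,
                       transformer=spy)
        assert len(seen) == 2


class TestPermutation:
    def test_minimum_p_and_separable_toy(self):
        # three separable classes: only a class-relabeling permutation could
        # tie the observed perfect accuracy, so p sits at/near its floor
        prof, labels = _blobs(n_classes=3, per_class=4, dims=2)
        y = [labels[s] for s in prof.index]
        p = permutation_test(
            plsda_classify_cv, prof, y, n_perm=99, seed=0,
            n_components=2, n_folds=2, n_iterations=1,
        )
        assert 1 / 100 <= p <= 0.05  # the +1 correction bounds p below

    def test_noise_gives_large_p(self):
        rng = np.random.default_rng(8)
        prof = pd.DataFrame(rng.normal(size=(16, 3)),
                            index=[f"s{i}" for i in range(16)])
        y = ["A", "B"] * 8
        p = permutation_test(
            plsda_classify_cv, prof, y, n_perm=49, seed=0,
            n_components=1, n_folds=2, n_iterations=1,
        )
        assert p > 0.05


class TestRoc:
    def test_perfect_separation_auc_one(self):
        prof, labels = _blobs(n_classes=2, per_class=6)
        y = [labels[s] for s in prof.index]
        r = roc_auc_cv(prof, y, classifier="rf", n_folds=3, n_trees=20, seed=0)
        assert r.auc == pytest.approx(1.0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(rng.normal(size=(200, 4)),
                            index=[f"s{i}" for i in range(200)])
        y = ["A", "B"] * 100
        r = roc_auc_cv(prof, y, classifier="rf", n_folds=5, n_trees=30, seed=0)
        assert abs(r.auc - 0.5) < 0.1
        assert 0.0 <= r.auc <= 1.0

    def test_multiclass_rejected(self):
        prof, labels = _blobs(n_classes=3, per_class=3)
        with pytest.raises(ValueError, match="two classes"):
            roc_auc_cv(prof, [labels[s] for s in prof.index])
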