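"""Entropy splitting, reduced-error pruning, cross-validation and risk
classes, with brute-force and simulation oracles."""

import numpy as np
import pytest

from mimicscale.simulate import PlantedTreeProfile, generate_planted_tree_cohort
from mimicscale.tree import (
    DEFAULT_FEATURES,
    ORDERED_FEATURES,
    Split,
    TreeConfig,
    TreeNode,
    best_split,
    cross_validate,
    entropy,
    fit,
    grow,
    predict,
    published_tree,
    reduced_error_prune,
    risk_class,
    _counts,
)


class TestEntropy:
    def test_pure_node(self):
        assert entropy((10, 0)) == 0.0
        assert entropy((0, 3)) == 0.0

    def test_maximal(self):
        assert entropy((5, 5)) == 1.0

    def test_shannon_value(self):
        assert entropy((3, 1)) == pytest.approx(0.8113, abs=5e-5)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            entropy((0, 0))


def brute_force_best_split(records, features, min_node_size=1):
    """Independent exhaustive enumeration of every candidate split."""
    n = len(records)
    parent = entropy(_counts(records))
    best = None
    for f in sorted(set(features)):
        vals = sorted({float(getattr(r, f)) for r in records})
        if f in ORDERED_FEATURES:
            thresholds = [(x + y) / 2 for x, y in zip(vals, vals[1:])]
        else:
            thresholds = [0.5] if len(vals) > 1 else []
        for t in thresholds:
            left = [r for r in records if float(getattr(r, f)) <= t]
            right = [r for r in records if float(getattr(r, f)) > t]
            if min(len(left), len(right)) < min_node_size:
                continue
            wh = (len(left) * entropy(_counts(left)) + len(right) * entropy(_counts(right))) / n
            if wh >= parent - 1e-12:
                continue
            key = (round(wh, 10), f, t)
            if best is None or key < best[0]:
                best = (key, Split(f, t, wh))
    return None if best is None else best[1]


class TestBestSplit:
    def test_perfect_boolean_separator_chosen(self, make_record):
        records = [
            make_record(migraine=m, label="mimic" if m else "stroke")
            for m in [True] * 5 + [False] * 5
        ]
        s = best_split(records, DEFAULT_FEATURES)
        assert s.feature == "migraine"
        assert s.weighted_entropy == pytest.approx(0.0, abs=1e-12)

    def test_pure_labels_give_no_split(self, make_record):
        records = [make_record(age=a) for a in range(30, 60)]
        assert best_split(records, DEFAULT_FEATURES) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        """20-record planted fixtures: chosen split equals exhaustive
        enumeration over every (feature, threshold) candidate."""
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=20, seed=seed)
        got = best_split(cohort.records, DEFAULT_FEATURES)
        want = brute_force_best_split(cohort.records, DEFAULT_FEATURES)
        if want is None:
            assert got is None
        else:
            assert (got.feature, got.threshold) == (want.feature, want.threshold)
            assert got.weighted_entropy == pytest.approx(want.weighted_entropy)

    def test_respects_min_node_size(self, make_record):
        records = [
            make_record(age=a, label="mimic" if a < 25 else "stroke")
            for a in [22, 23, 60, 61, 62, 63, 64, 65]
        ]
        s = best_split(records, ("age",), min_node_size=3)
        assert s is None or min(
            sum(r.age <= s.threshold for r in records),
            sum(r.age > s.threshold for r in records),
        ) >= 3

    def test_accepted_split_reduces_entropy(self):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=60, seed=1)
        s = best_split(cohort.records, DEFAULT_FEATURES)
        assert s is not None
        assert s.weighted_entropy < entropy(_counts(cohort.records))


class TestGrow:
    def test_pure_input_is_single_leaf(self, make_record):
        t = grow([make_record() for _ in range(6)], TreeConfig(seed=0))
        assert t.is_leaf and t.n_mimic == 0

    def test_planted_migraine_effect_recovered_at_root(self):
        profile = PlantedTreeProfile(p_mimic_given_migraine=0.8, p_mimic_baseline=0.03,
                                     p_mimic_given_young=0.03, p_mimic_given_psychiatric=0.03)
        cohort = generate_planted_tree_cohort(profile, n=2000, seed=13)
        t = grow(cohort.records, TreeConfig(seed=0))
        assert t.feature == "migraine"

    @pytest.mark.parametrize("max_depth", [1, 2, 3])
    def test_depth_bound_respected(self, max_depth):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=400, seed=3)
        t = grow(cohort.records, TreeConfig(max_depth=max_depth, seed=0))
        assert t.depth() <= max_depth

    def test_structure_invariant_to_record_order(self):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=300, seed=8)
        t1 = grow(cohort.records, TreeConfig(seed=0))
        shuffled = list(cohort.records)
        np.random.default_rng(99).shuffle(shuffled)
        t2 = grow(shuffled, TreeConfig(seed=0))
        assert t1.to_dict() == t2.to_dict()

    def test_child_entropy_never_exceeds_parent(self):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=500, seed=21)
        t = grow(cohort.records, TreeConfig(seed=0))

        def check(node):
            if node.is_leaf:
                return
            h_parent = entropy((node.n_stroke, node.n_mimic))
            wh = (
                node.left.total * entropy((node.left.n_stroke, node.left.n_mimic))
                + node.right.total * entropy((node.right.n_stroke, node.right.n_mimic))
            ) / node.total
            assert wh <= h_parent + 1e-12
            check(node.left)
            check(node.right)

        check(t)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            grow([], TreeConfig(seed=0))


class TestPredict:
    def test_single_leaf_probability(self, make_record):
        leaf = TreeNode(n_stroke=8, n_mimic=2)
        p, cls = predict(leaf, make_record())
        assert p == 0.2 and cls is False

    def test_pure_stroke_leaf(self, make_record):
        leaf = TreeNode(n_stroke=5, n_mimic=0)
        assert predict(leaf, make_record()) == (0.0, False)

    def test_tie_calls_stroke(self, make_record):
        leaf = TreeNode(n_stroke=3, n_mimic=3)
        assert predict(leaf, make_record())[1] is False

    def test_training_records_get_their_leaf_rate(self):
        """Every training record's predicted probability equals its own
        leaf's empirical mimic fraction (self-consistency scan)."""
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=400, seed=4)
        t = grow(cohort.records, TreeConfig(seed=0))
        leaves = {}
        for r in cohort.records:
            p, _ = predict(t, r)
            leaves.setdefault(round(p, 12), [0, 0])
            leaves[round(p, 12)][r.is_mimic] += 1
        for p, (n_stroke, n_mimic) in leaves.items():
            assert p == pytest.approx(n_mimic / (n_stroke + n_mimic))


class TestPruning:
    def test_single_leaf_unchanged(self, make_record):
        leaf = TreeNode(n_stroke=4, n_mimic=1)
        pruned = reduced_error_prune(leaf, [make_record()])
        assert pruned.is_leaf and (pruned.n_stroke, pruned.n_mimic) == (4, 1)

    def test_identical_children_collapsed(self, make_record):
        node = TreeNode(
            n_stroke=10, n_mimic=0, feature="migraine", threshold=0.5,
            left=TreeNode(n_stroke=5, n_mimic=0), right=TreeNode(n_stroke=5, n_mimic=0),
        )
        pruned = reduced_error_prune(node, [make_record()])
        assert pruned.is_leaf

    def test_never_increases_pruning_set_error(self):
        for seed in range(10):
            cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=300, seed=seed)
            grow_set, prune_set = cohort.records[:200], cohort.records[200:]
            t = grow(grow_set, TreeConfig(seed=0))
            pruned = reduced_error_prune(t, prune_set)
            err = lambda tree: sum(predict(tree, r)[1] != r.is_mimic for r in prune_set)
            assert err(pruned) <= err(t)

    def test_pruning_helps_on_held_out_data_in_most_replicates(self):
        """On noisy planted simulations, with the learner deliberately run
        in an overfitting-prone regime (min node size 1, depth 8, small
        growing set), the pruned tree's error on a third held-out test
        set is <= the unpruned tree's in >= 80% of 100 replicates."""
        noisy = PlantedTreeProfile(
            p_mimic_given_migraine=0.6, p_mimic_given_young=0.25,
            p_mimic_given_psychiatric=0.2, p_mimic_baseline=0.10,
        )
        wins = 0
        config = TreeConfig(min_node_size=1, max_depth=8, seed=0)
        for seed in range(100):
            cohort = generate_planted_tree_cohort(noisy, n=600, seed=seed)
            r = cohort.records
            grow_set, prune_set, test_set = r[:100], r[100:300], r[300:]
            full = grow(grow_set, config)
            pruned = reduced_error_prune(full, prune_set)
            err = lambda tree: sum(predict(tree, x)[1] != x.is_mimic for x in test_set)
            wins += err(pruned) <= err(full)
        assert wins >= 80


class TestCrossValidate:
    def test_perfectly_separable_dataset(self, make_record):
        records = [
            make_record(migraine=m, label="mimic" if m else "stroke")
            for m in [True] * 20 + [False] * 40
        ]
        report = cross_validate(records, TreeConfig(min_node_size=1, seed=5), k=4)
        assert report.misclassification_rate == 0.0
        assert report.sensitivity == report.specificity == 1.0

    def test_same_seed_reproduces_report(self):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=200, seed=2)
        r1 = cross_validate(cohort.records, TreeConfig(seed=42), k=5)
        r2 = cross_validate(cohort.records, TreeConfig(seed=42), k=5)
        assert r1 == r2

    def test_confusion_matrix_consistency(self):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=200, seed=6)
        rep = cross_validate(cohort.records, TreeConfig(seed=1), k=5)
        tp, fn, tn, fp = rep.confusion
        assert tp + fn + tn + fp == 200
        assert rep.misclassification_rate == pytest.approx((fn + fp) / 200)

    def test_k_larger_than_minority_class_rejected(self, make_record):
        records = [
            make_record(label="mimic" if i < 3 else "stroke") for i in range(50)
        ]
        with pytest.raises(ValueError, match="stratification"):
            cross_validate(records, TreeConfig(seed=0), k=5)


class TestRiskClass:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.667, "high"),
            (0.031, "low"),
            (0.60, "uncertain"),  # boundary: strictly greater than 0.60
            (0.05, "uncertain"),  # boundary: strictly less than 0.05
            (1.0, "high"),
            (0.0, "low"),
        ],
    )
    def test_mapping(self, p, expected):
        assert risk_class(p) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            risk_class(p)


class TestPublishedTree:
    def test_structure_and_counts(self):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=500, seed=10)
        t = published_tree(cohort.records)
        assert t.feature == "migraine"
        assert t.left.feature == "age" and t.left.threshold == 45.0
        assert t.left.right.feature == "psychiatric_history"
        assert t.total == 500
        # counts at each split sum to the children
        assert t.left.total + t.right.total == t.total

    def test_leaf_probabilities_are_empirical_rates(self):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=500, seed=10)
        t = published_tree(cohort.records)
        migraine_recs = [r for r in cohort.records if r.migraine]
        assert t.right.mimic_probability == pytest.approx(
            sum(r.is_mimic for r in migraine_recs) / len(migraine_recs)
        )

    def test_serialization_round_trip_structure(self):
        cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=100, seed=0)
        d = published_tree(cohort.records).to_dict()
        assert d["type"] == "split" and d["feature"] == "migraine"
        assert {"left", "right"} <= set(d)


def test_fit_grows_then_prunes_deterministically():
    cohort = generate_planted_tree_cohort(PlantedTreeProfile(), n=300, seed=17)
    t1 = fit(cohort.records, TreeConfig(seed=7))
    t2 = fit(cohort.records, TreeConfig(seed=7))
    assert t1.to_dict() == t2.to_dict()
    with pytest.raises(ValueError, match="seed"):
        fit(cohort.records, TreeConfig())
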