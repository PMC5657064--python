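"""Scenario-aware splitters, ranking metrics and the CV driver."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from combifuse import (
    PairLabelSet,
    SyntheticConfig,
    auc,
    aupr,
    generate,
    null_config,
    run_cv,
    split_s1,
    split_s2,
    split_s3,
)
from conftest import make_universe


def brute_force_auc(scores, labels):
    """Probability a random positive outranks a random negative (ties 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        assert auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_brute_force_estimator(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 30))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])


class TestAUPR:
    def test_perfect_separation(self):
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_first(self):
        assert aupr([0.99, 0.5, 0.4, 0.1], [1, 0, 0, 0]) == 1.0

    def test_worked_example_from_threshold_enumeration(self):
        # step-wise estimator: sum precision-at-k over positive ranks / n_pos
        scores, labels = [0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]
        # positives at ranks 1 and 3 -> (1/1 + 2/3) / 2 = 5/6
        assert aupr(scores, labels) == pytest.approx(5 / 6)
        assert aupr(scores, labels) == pytest.approx(
            average_precision_score(labels, scores)
        )

    def test_no_positives_undefined(self):
        with pytest.raises(ValueError, match="positive"):
            aupr([0.3, 0.2], [0, 0])


def toy_labels(m, n_pos=3, seed=0):
    ids = [f"d{i:02d}" for i in range(m)]
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(ids, 2))
    pos = [pairs[j] for j in rng.choice(len(pairs), n_pos, replace=False)]
    return PairLabelSet.from_pairs(pos, ids), make_universe(
        {d: {"A"} for d in ids}
    )


class TestSplitS1:
    def test_partitions_scope_into_disjoint_folds(self):
        labels, _ = toy_labels(5)  # 10 scope pairs
        splits = split_s1(labels, k=5, seed=0)
        test_sets = [set(s.test_pairs) for s in splits]
        assert all(len(t) == 2 for t in test_sets)
        assert set().union(*test_sets) == labels.scope
        for a, b in itertools.combinations(test_sets, 2):
            assert not a & b
        for s in splits:
            assert not set(s.train_pairs) & set(s.test_pairs)
            assert set(s.train_pairs) | set(s.test_pairs) == labels.scope

    def test_same_seed_reproduces_folds(self):
        labels, _ = toy_labels(6)
        a = split_s1(labels, k=3, seed=42)
        b = split_s1(labels, k=3, seed=42)
        assert [s.test_pairs for s in a] == [s.test_pairs for s in b]

    def test_1904_pairs_k10_fold_sizes(self):
        # explicit 1904-pair scope: fold sizes must be 190 or 191
        ids = [f"d{i:03d}" for i in range(63)]
        scope = list(itertools.combinations(ids, 2))[:1904]
        labels = PairLabelSet.from_pairs([scope[0]], ids, scope=scope)
        sizes = sorted(len(s.test_pairs) for s in split_s1(labels, k=10, seed=1))
        assert sizes == [190] * 6 + [191] * 4

    def test_fewer_positives_than_folds_warns(self):
        labels, _ = toy_labels(6, n_pos=2)
        with pytest.warns(UserWarning, match="positive"):
            split_s1(labels, k=5, seed=0)


class TestDrugWiseSplits:
    def test_s2_four_drug_enumeration(self):
        labels, universe = toy_labels(4, n_pos=2)
        for s in split_s2(labels, universe, k=4, seed=0):
            (d,) = s.test_drugs
            others = set(universe.drug_ids) - {d}
            assert set(s.test_pairs) == {
                tuple(sorted((d, o))) for o in others
            }
            assert set(s.train_pairs) == {
                p for p in labels.scope if d not in p
            }

    def test_s3_test_pairs_lie_within_test_drugs(self):
        labels, universe = toy_labels(4, n_pos=2)
        for s in split_s3(labels, universe, k=2, seed=3):
            for p in s.test_pairs:
                assert set(p) <= s.test_drugs
            for p in s.train_pairs:
                assert not set(p) & s.test_drugs

    def test_no_test_drug_touches_any_train_pair(self):
        labels, universe = toy_labels(12, n_pos=6)
        for splitter in (split_s2, split_s3):
            for s in splitter(labels, universe, k=4, seed=7):
                train_drugs = {d for p in s.train_pairs for d in p}
                assert not train_drugs & s.test_drugs

    def test_s2_fold_union_covers_cross_fold_pairs(self):
        labels, universe = toy_labels(12, n_pos=4)
        splits = split_s2(labels, universe, k=3, seed=5)
        union = set().union(*(set(s.test_pairs) for s in splits))
        fold_of = {d: i for i, s in enumerate(splits) for d in s.test_drugs}
        expected = {p for p in labels.scope if fold_of[p[0]] != fold_of[p[1]]}
        assert union == expected

    def test_s3_singleton_drug_fold_warns(self):
        labels, universe = toy_labels(3, n_pos=1)
        with pytest.warns(UserWarning, match="no test instances"):
            split_s3(labels, universe, k=3, seed=0)

    def test_s2_s3_test_sets_disjoint_for_same_partition(self):
        labels, universe = toy_labels(12, n_pos=4)
        s2 = split_s2(labels, universe, k=3, seed=9)
        s3 = split_s3(labels, universe, k=3, seed=9)
        for a, b in zip(s2, s3):
            assert a.test_drugs == b.test_drugs
            assert not set(a.test_pairs) & set(b.test_pairs)


SMALL = SyntheticConfig(m=60, n_prone=25, n_pos=50, n_targets=150, n_se=300,
                        n_beneficial_se=40, n_adverse_se=80,
                        n_pos_targets=20, n_neg_targets=40)


class TestRunCV:
    def test_planted_signal_detected_in_s1(self):
        universe, network, labels = generate(SMALL, seed=2)
        res = run_cv(universe, network, labels, scenario="S1", k=5, seed=2)
        se = np.std(res.fold_auc) / np.sqrt(len(res.fold_auc))
        assert res.auc > 0.5 + 3 * se
        assert len(res.fold_auc) + res.n_folds_skipped == 5

    def test_null_labels_score_near_chance(self):
        universe, network, labels = generate(
            null_config(m=60, n_prone=25, n_pos=50, n_targets=150, n_se=300,
                        n_beneficial_se=40, n_adverse_se=80,
                        n_pos_targets=20, n_neg_targets=40),
            seed=3,
        )
        res = run_cv(universe, network, labels, scenario="S1", k=5, seed=3)
        assert 0.38 <= res.auc <= 0.62

    def test_fusion_rules_all_run(self):
        universe, network, labels = generate(SMALL, seed=4)
        for rule in ("mean", "direct", "greedy"):
            res = run_cv(universe, network, labels, scenario="S1", k=3, seed=4,
                         rule=rule, grid_step=0.25)
            assert 0.0 <= res.auc <= 1.0
            assert 0.0 <= res.aupr <= 1.0

    def test_pooled_evaluation_gives_single_estimate(self):
        universe, network, labels = generate(SMALL, seed=5)
        res = run_cv(universe, network, labels, scenario="S1", k=3, seed=5, pool=True)
        assert len(res.fold_auc) == 1

    def test_unknown_scenario_and_rule_rejected(self):
        universe, network, labels = generate(SMALL, seed=6)
        with pytest.raises(ValueError, match="scenario"):
            run_cv(universe, network, labels, scenario="S9")
        with pytest.raises(ValueError, match="rule"):
            run_cv(universe, network, labels, rule="stacking")
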