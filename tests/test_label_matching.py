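"""Matching enumeration, confusion matrices and weighted metrics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfslda import (
    ClassWeights,
    ConfusionMatrix,
    LabelVector,
    best_matching,
    confusion_matrix,
    enumerate_matchings,
    weighted_accuracy,
    weighted_metrics,
)
from rfslda.topic_model import TopicAssignment

LEVELS = ("Healthy", "Infection", "Stress")


@pytest.mark.parametrize("T", [1, 2, 3, 4, 5])
def test_unconstrained_count_is_factorial(T):
    assert len(enumerate_matchings(T)) == math.factorial(T)


def test_three_topics_give_six_matchings():
    assert len(enumerate_matchings(3, levels=LEVELS)) == 6


def test_topic_constraint_reduces_six_to_four():
    ms = enumerate_matchings(3, {0: {"Infection", "Stress"}}, levels=LEVELS)
    assert len(ms) == 4
    assert all(m.level_of(0) in {"Infection", "Stress"} for m in ms)


def test_single_topic_single_matching():
    assert len(enumerate_matchings(1, levels=("Healthy",))) == 1


def test_infeasible_constraints_error():
    with pytest.raises(ValueError, match="no bijection"):
        enumerate_matchings(2, {0: {"X"}}, levels=("Healthy", "Stress"))


def test_enumeration_is_lexicographic():
    ms = enumerate_matchings(3, levels=LEVELS)
    orders = [tuple(LEVELS.index(l) for l in m.levels) for m in ms]
    assert orders == sorted(orders)


def _lv(labels):
    return LabelVector(tuple(f"s{i}" for i in range(len(labels))), tuple(labels), LEVELS[: len(set(LEVELS) & set(labels)) or 3])


def test_confusion_matrix_perfect_prediction_diagonal():
    lv = LabelVector(("a", "b", "c"), ("Healthy", "Infection", "Healthy"), LEVELS)
    cm = confusion_matrix(lv, list(lv.labels))
    np.testing.assert_array_equal(cm.matrix, np.diag([2, 1, 0]))


def test_confusion_matrix_orientation_columns_true():
    lv = LabelVector(("a", "b"), ("Healthy", "Infection"), LEVELS)
    cm = confusion_matrix(lv, ["Infection", "Infection"])
    # column Healthy has the misprediction in row Infection
    assert cm.matrix[1, 0] == 1 and cm.matrix[1, 1] == 1
    assert cm.matrix.sum() == 2


def test_confusion_matrix_matches_counting_oracle():
    rng = np.random.default_rng(4)
    true = [LEVELS[i] for i in rng.integers(0, 3, size=200)]
    pred = [LEVELS[i] for i in rng.integers(0, 3, size=200)]
    lv = LabelVector(tuple(f"s{i}" for i in range(200)), tuple(true), LEVELS)
    cm = confusion_matrix(lv, pred)
    for r, c in itertools.product(range(3), range(3)):
        expect = sum(
            p == LEVELS[r] and t == LEVELS[c] for p, t in zip(pred, true)
        )
        assert cm.matrix[r, c] == expect
    np.testing.assert_array_equal(
        cm.true_counts(), [true.count(l) for l in LEVELS]
    )


def test_confusion_matrix_rejects_unknown_level():
    lv = LabelVector(("a",), ("Healthy",), LEVELS)
    with pytest.raises(ValueError, match="Fever"):
        confusion_matrix(lv, ["Fever"])


def test_weighted_accuracy_perfect_is_one():
    cm = ConfusionMatrix(LEVELS, np.diag([10, 3, 5]))
    assert weighted_accuracy(cm, ClassWeights((0.6, 0.15, 0.25))) == pytest.approx(1.0)


def test_weighted_accuracy_one_hot_weight_returns_tpr():
    m = np.array([[8, 1, 0], [2, 3, 1], [0, 2, 4]])
    cm = ConfusionMatrix(LEVELS, m)
    assert weighted_accuracy(cm, ClassWeights((0, 1, 0))) == pytest.approx(3 / 6)


def test_weighted_accuracy_hand_summed_oracle():
    """Study-shaped matrix (columns true: H=(50,8,8), I=(1,4,1), S=(5,3,9))."""
    m = np.array([[50, 1, 5], [8, 4, 3], [8, 1, 9]])
    cm = ConfusionMatrix(LEVELS, m)
    oracle = 0.6 * (50 / 66) + 0.15 * (4 / 6) + 0.25 * (9 / 17)
    got = weighted_accuracy(cm, ClassWeights((0.6, 0.15, 0.25)))
    assert got == pytest.approx(oracle, abs=1e-12)


def test_weighted_accuracy_zero_support_with_weight_errors():
    cm = ConfusionMatrix(LEVELS, np.diag([5, 0, 3]))
    with pytest.raises(ValueError, match="Infection"):
        weighted_accuracy(cm, ClassWeights((0.6, 0.15, 0.25)))
    # zero weight on the empty class is fine
    assert weighted_accuracy(cm, ClassWeights((0.7, 0.0, 0.3))) == pytest.approx(1.0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_weighted_accuracy_invariant_under_joint_permutation(seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(1, 20, size=(3, 3))
    w = rng.dirichlet(np.ones(3))
    perm = rng.permutation(3)
    cm = ConfusionMatrix(LEVELS, m)
    cm_p = ConfusionMatrix(
        tuple(LEVELS[i] for i in perm), m[np.ix_(perm, perm)]
    )
    a = weighted_accuracy(cm, ClassWeights(tuple(w)))
    b = weighted_accuracy(cm_p, ClassWeights(tuple(w[perm])))
    assert 0.0 <= a <= 1.0
    assert a == pytest.approx(b, abs=1e-12)


def test_weighted_metrics_all_predicted_one_class():
    # everyone predicted Healthy: precision = w_H * (true share), recall = w_H * 1
    m = np.zeros((3, 3), dtype=int)
    m[0] = [12, 4, 4]
    cm = ConfusionMatrix(LEVELS, m)
    got = weighted_metrics(cm, ClassWeights((0.6, 0.15, 0.25)))
    assert got["weighted_precision"] == pytest.approx(0.6 * 12 / 20)
    assert got["weighted_recall"] == pytest.approx(0.6)


def test_weighted_metrics_random_matches_per_class_oracle():
    rng = np.random.default_rng(8)
    m = rng.integers(1, 30, size=(3, 3))
    w = rng.dirichlet(np.ones(3))
    cm = ConfusionMatrix(LEVELS, m)
    got = weighted_metrics(cm, ClassWeights(tuple(w)))
    recall = sum(w[t] * m[t, t] / m[:, t].sum() for t in range(3))
    precision = sum(w[t] * m[t, t] / m[t, :].sum() for t in range(3))
    assert got["weighted_recall"] == pytest.approx(recall)
    assert got["weighted_accuracy"] == pytest.approx(recall)
    assert got["weighted_precision"] == pytest.approx(precision)


def _assignment(topics, T):
    topics = np.asarray(topics)
    theta = np.full((topics.size, T), 0.0)
    theta[np.arange(topics.size), topics] = 1.0
    return TopicAssignment(topics=topics, theta=theta)


def _brute_force_best(topics, lv, w):
    best = None
    for perm in itertools.permutations(lv.level_order):
        pred = [perm[t] for t in topics]
        score = weighted_accuracy(confusion_matrix(lv, pred), w)
        if best is None or score > best:
            best = score
    return best


def test_best_matching_identity_wins_on_perfect_labels():
    lv = LabelVector(
        tuple(f"s{i}" for i in range(6)),
        ("Healthy", "Healthy", "Infection", "Infection", "Stress", "Stress"),
        LEVELS,
    )
    topics = [0, 0, 1, 1, 2, 2]
    matching, score, cm = best_matching(_assignment(topics, 3), lv, ClassWeights((0.6, 0.15, 0.25)))
    assert matching.levels == LEVELS
    assert score == pytest.approx(1.0)
    assert np.trace(cm.matrix) == 6


@pytest.mark.parametrize("T", [2, 3, 4])
def test_best_matching_equals_exhaustive(T):
    rng = np.random.default_rng(T)
    levels = LEVELS[:3] + ("Other",)
    levels = levels[:T]
    n = 40
    topics = rng.integers(0, T, size=n)
    true = [levels[i] for i in rng.integers(0, T, size=n)]
    # ensure every class occurs
    for i, l in enumerate(levels):
        true[i] = l
    lv = LabelVector(tuple(f"s{i}" for i in range(n)), tuple(true), levels)
    w = ClassWeights(tuple(rng.dirichlet(np.ones(T))))
    _, score, _ = best_matching(_assignment(topics, T), lv, w)
    assert score == pytest.approx(_brute_force_best(topics, lv, w))


def test_best_matching_respects_constraints():
    rng = np.random.default_rng(2)
    topics = rng.integers(0, 3, size=30)
    true = [LEVELS[i] for i in rng.integers(0, 3, size=30)]
    for i, l in enumerate(LEVELS):
        true[i] = l
    lv = LabelVector(tuple(f"s{i}" for i in range(30)), tuple(true), LEVELS)
    w = ClassWeights((0.6, 0.15, 0.25))
    constraints = {0: {"Infection", "Stress"}}
    m_con, s_con, _ = best_matching(_assignment(topics, 3), lv, w, constraints)
    assert m_con.level_of(0) in {"Infection", "Stress"}
    # the constrained winner is the argmax over exactly the 4 admissible bijections
    scores = []
    for m in enumerate_matchings(3, constraints, levels=LEVELS):
        pred = [m.level_of(t) for t in topics]
        scores.append(weighted_accuracy(confusion_matrix(lv, pred), w))
    assert s_con == pytest.approx(max(scores))
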