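"""Topic→health-status matching by exhaustive enumeration.

Latent topics carry no labels, so the semi-supervised step enumerates every
bijection from the T topics to the C = T health-status levels (optionally
restricted by prior knowledge of which levels a topic may represent) and
scores each with the class-weighted true-positive rate

    A_w = sum_t w_t * TPR_t,    TPR_t = cm[t, t] / (true count of class t).

Confusion matrices here follow the fixed convention rows = predicted,
columns = true, in the order of ``LabelVector.level_order``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_interface import LabelVector
from .topic_model import TopicAssignment

__all__ = [
    "Matching",
    "ConfusionMatrix",
    "ClassWeights",
    "enumerate_matchings",
    "confusion_matrix",
    "weighted_accuracy",
    "weighted_metrics",
    "best_matching",
    "weight_grid_search",
]


@dataclass(frozen=True)
class Matching:
    """Bijection topic index (0-based) → health-status level name."""

    levels: tuple[str, ...]  # levels[t] = level assigned to topic t

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("matching must be a bijection")

    def level_of(self, topic: int) -> str:
        return self.levels[topic]

    def topic_of(self, level: str) -> int:
        return self.levels.index(level)

    def as_dict(self) -> dict[str, str]:
        return {f"topic_{t + 1}": lvl for t, lvl in enumerate(self.levels)}


@dataclass(frozen=True)
class ConfusionMatrix:
    """C×C counts; rows index PREDICTED levels, columns index TRUE levels."""

    levels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.shape != (len(self.levels), len(self.levels)):
            raise ValueError("confusion matrix shape must be C x C")
        if (m < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def true_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def predicted_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


@dataclass(frozen=True)
class ClassWeights:
    """Non-negative per-class weights summing to 1, in level order."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.w)
        object.__setattr__(self, "w", w)
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def enumerate_matchings(
    T: int,
    constraints: Mapping[int, set] | None = None,
    levels: Sequence[str] | None = None,
) -> list[Matching]:
    """All admissible topic→level bijections in lexicographic order of the
    mapping (by level index per topic).

    ``constraints`` maps a 0-based topic index to the set of levels it may be
    matched to; unconstrained topics admit every level.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    lvls = tuple(levels) if levels is not None else tuple(str(i + 1) for i in range(T))
    if len(lvls) != T:
        raise ValueError("number of levels must equal T")
    constraints = constraints or {}
    out = []
    for perm in itertools.permutations(lvls):
        if all(perm[t] in allowed for t, allowed in constraints.items()):
            out.append(Matching(perm))
    if not out:
        raise ValueError("constraints admit no bijection")
    return out


def confusion_matrix(
    true_labels: LabelVector, predicted: Sequence[str]
) -> ConfusionMatrix:
    """Count matrix with cell (r, c) = #{i : predicted_i = level r and
    true_i = level c}."""
    if len(predicted) != len(true_labels.labels):
        raise ValueError("predicted and true label vectors differ in length")
    levels = true_labels.level_order
    pos = {lvl: i for i, lvl in enumerate(levels)}
    unknown = set(predicted) - set(levels)
    if unknown:
        raise ValueError(f"predicted levels not in level_order: {sorted(unknown)}")
    m = np.zeros((len(levels), len(levels)), dtype=np.int64)
    for pred, true in zip(predicted, true_labels.labels):
        m[pos[pred], pos[true]] += 1
    return ConfusionMatrix(levels, m)


def weighted_accuracy(cm: ConfusionMatrix, w: ClassWeights) -> float:
    """Class-weighted mean of per-class true-positive rates (recall)."""
    if len(w.w) != len(cm.levels):
        raise ValueError("weights length must equal the number of levels")
    col = cm.true_counts()
    acc = 0.0
    for t, wt in enumerate(w.w):
        if wt == 0.0:
            continue
        if col[t] == 0:
            raise ValueError(
                f"class {cm.levels[t]!r} has weight {wt} but no true instances"
            )
        acc += wt * cm.matrix[t, t] / col[t]
    return float(acc)


def weighted_metrics(cm: ConfusionMatrix, w: ClassWeights) -> dict[str, float]:
    """Weighted accuracy (= weighted recall) plus weighted precision, where
    per-class precision uses row (predicted) sums with 0/0 -> 0."""
    row = cm.predicted_counts()
    prec = 0.0
    for t, wt in enumerate(w.w):
        if wt == 0.0 or row[t] == 0:
            continue
        prec += wt * cm.matrix[t, t] / row[t]
    a_w = weighted_accuracy(cm, w)
    return {
        "weighted_accuracy": a_w,
        "weighted_precision": float(prec),
        "weighted_recall": a_w,
    }


def best_matching(
    assignments: TopicAssignment,
    labels: LabelVector,
    w: ClassWeights,
    constraints: Mapping[int, set] | None = None,
) -> tuple[Matching, float, ConfusionMatrix]:
    """Exhaustively score every admissible matching and return the winner.

    Ties are broken by enumeration (lexicographic) order.  Requires
    T = number of levels so that the matching is a bijection.
    """
    T = assignments.theta.shape[1]
    if T != labels.n_levels:
        raise ValueError("number of topics must equal the number of levels")
    best: tuple[Matching, float, ConfusionMatrix] | None = None
    for matching in enumerate_matchings(T, constraints, levels=labels.level_order):
        predicted = [matching.level_of(int(t)) for t in assignments.topics]
        cm = confusion_matrix(labels, predicted)
        score = weighted_accuracy(cm, w)
        if best is None or score > best[1]:
            best = (matching, score, cm)
    assert best is not None
    return best


def weight_grid_search(
    assignments: TopicAssignment,
    labels: LabelVector,
    grid: Sequence[Sequence[float]],
    constraints: Mapping[int, set] | None = None,
) -> list[dict]:
    """Score best_matching under each candidate weight vector of a
    user-supplied grid; returns one record per weight vector."""
    out = []
    for w_vec in grid:
        w = ClassWeights(tuple(w_vec))
        matching, score, _ = best_matching(assignments, labels, w, constraints)
        out.append(
            {"weights": tuple(w.w), "weighted_accuracy": score, "matching": matching}
        )
    return out
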