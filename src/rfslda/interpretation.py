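"""Interpreting a fitted, matched model.

Two read-outs: (i) per-health-status taxon profiles — the matched topic's
taxon distribution, ranked; (ii) within-group similarity labels — a subject
whose top matched-topic proportion reaches a threshold λ is "Predominantly
<level>", otherwise it is labelled by its top two matched levels
("<level>-<second level>").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .label_matching import Matching
from .topic_model import TopicModel

__all__ = ["ClassProfile", "SimilarityLabel", "class_feature_profile", "similarity_labels"]


@dataclass(frozen=True)
class ClassProfile:
    """Ranked (taxon, estimated proportion) pairs for one health level."""

    level: str
    ranked_taxa: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class SimilarityLabel:
    subject_id: str
    primary: str
    label: str
    pi1: float
    pi2: float

    def __post_init__(self) -> None:
        if self.pi1 < self.pi2:
            raise ValueError("pi1 must be >= pi2")


def class_feature_profile(
    model: TopicModel, matching: Matching, top_n: int
) -> list[ClassProfile]:
    """For each health level, the matched topic's beta row sorted descending
    and truncated to ``top_n`` taxa (the full row still sums to 1)."""
    if len(matching.levels) != model.T:
        raise ValueError("matching must cover all topics")
    if top_n > model.beta.shape[1]:
        raise ValueError("top_n exceeds the number of taxa")
    profiles = []
    for t in range(model.T):
        row = model.beta[t]
        # descending proportion, stable on ties
        order = np.argsort(-row, kind="stable")[:top_n]
        profiles.append(
            ClassProfile(
                level=matching.level_of(t),
                ranked_taxa=tuple(
                    (model.taxon_names[j], float(row[j])) for j in order
                ),
            )
        )
    return profiles


def similarity_labels(
    theta: np.ndarray,
    matching: Matching,
    lam: float,
    subject_ids: Sequence[str] | None = None,
) -> list[SimilarityLabel]:
    """Within-group similarity labels at threshold λ.

    The primary level is the matched level of the largest topic proportion
    (ties toward the lowest topic index).  If that proportion is >= λ the
    subject is "Predominantly <primary>"; otherwise "<primary>-<second>",
    where second is the matched level of the second-highest topic (ties again
    toward the lowest index).
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("lambda must lie in (0, 1]")
    theta = np.asarray(theta, dtype=float)
    M, T = theta.shape
    if len(matching.levels) != T:
        raise ValueError("matching must cover all topics")
    ids = list(subject_ids) if subject_ids is not None else [str(i + 1) for i in range(M)]
    out = []
    for i in range(M):
        row = theta[i]
        first = int(row.argmax())
        rest = [t for t in range(T) if t != first]
        second = min(rest, key=lambda t: (-row[t], t)) if rest else first
        pi1, pi2 = float(row[first]), float(row[second])
        primary = matching.level_of(first)
        if pi1 >= lam:
            label = f"Predominantly {primary}"
        else:
            label = f"{primary}-{matching.level_of(second)}"
        out.append(SimilarityLabel(ids[i], primary, label, pi1, pi2))
    return out
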