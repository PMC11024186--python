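"""Abundance/prevalence feature filtering.

Each subject's counts are first normalized to proportions.  Per-taxon
abundance (sum of proportions over subjects) and prevalence (number of
subjects where the proportion reaches a detection threshold ω) are then
ranked, and the top-K taxa are kept by a concordance criterion: taxa are
ordered by rank-sum of the two rankings and backward-eliminated from the tail
whenever removal improves the Kendall tau between abundance and prevalence on
the retained set.  Dropped taxa are pooled into a single "Others" column so
per-subject totals are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_interface import CountTable, LabelVector

__all__ = [
    "ProportionTable",
    "FeatureSummary",
    "FeatureSubset",
    "compute_proportions",
    "summarize_features",
    "taupath_rank",
    "aggregate_others",
    "per_class_taupath",
]


@dataclass(frozen=True)
class ProportionTable:
    subject_ids: tuple[str, ...]
    taxon_names: tuple[str, ...]
    proportions: np.ndarray  # rows sum to 1

    def __post_init__(self) -> None:
        P = np.asarray(self.proportions, dtype=float)
        if (P < 0).any() or (P > 1).any():
            raise ValueError("proportions must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every proportion row must sum to 1")
        object.__setattr__(self, "proportions", P)


@dataclass(frozen=True)
class FeatureSummary:
    """Per-taxon abundance and prevalence at detection threshold ω."""

    taxon_names: tuple[str, ...]
    abundance: np.ndarray  # A_l = sum_i p_il
    prevalence: np.ndarray  # P_l = #{i : p_il >= omega}
    omega: float
    indicator: np.ndarray  # I_il = 1[p_il >= omega]


@dataclass(frozen=True)
class FeatureSubset:
    """Ordered taxon subset; ``tau`` is the Kendall concordance between
    abundance and prevalence restricted to the subset (when produced by
    :func:`taupath_rank`)."""

    names: tuple[str, ...]
    tau: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if not self.names:
            raise ValueError("feature subset must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxa in feature subset")


def compute_proportions(counts: CountTable) -> ProportionTable:
    """Row-normalize counts to per-subject proportions."""
    totals = counts.counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(
            f"subject {counts.subject_ids[int(zero[0])]!r} has zero total count"
        )
    return ProportionTable(
        counts.subject_ids,
        counts.taxon_names,
        counts.counts / totals[:, None],
    )


def summarize_features(P: ProportionTable, omega: float) -> FeatureSummary:
    """Column abundance sums and threshold prevalence counts."""
    if not 0.0 <= omega < 1.0:
        raise ValueError("omega must lie in [0, 1)")
    indicator = (P.proportions >= omega).astype(np.int64)
    return FeatureSummary(
        taxon_names=P.taxon_names,
        abundance=P.proportions.sum(axis=0),
        prevalence=indicator.sum(axis=0),
        omega=float(omega),
        indicator=indicator,
    )


def _kendall_tau(a: np.ndarray, p: np.ndarray) -> float:
    # tau on a degenerate (constant or length-<2) pair is trivially concordant
    if a.size < 2 or np.all(a == a[0]) or np.all(p == p[0]):
        return 1.0
    tau = stats.kendalltau(a, p).statistic
    return 1.0 if np.isnan(tau) else float(tau)


def taupath_rank(summary: FeatureSummary, K: int) -> FeatureSubset:
    """Select the K taxa most concordant between abundance and prevalence.

    Taxa are ordered by descending rank-sum of (rank by abundance, rank by
    prevalence), ties broken lexicographically by name; then, while more than
    K remain, the first taxon from the tail whose removal strictly increases
    the Kendall tau of the retained set is eliminated (the tail-most taxon is
    eliminated when no removal helps).
    """
    B = len(summary.taxon_names)
    if not 1 <= K <= B:
        raise ValueError(f"K={K} must lie in [1, {B}]")
    names = np.array(summary.taxon_names)
    # ascending ranks: larger value -> larger rank; lexicographic tie-break
    order_a = np.lexsort((names, summary.abundance))
    order_p = np.lexsort((names, summary.prevalence))
    rank_a = np.empty(B, dtype=np.int64)
    rank_p = np.empty(B, dtype=np.int64)
    rank_a[order_a] = np.arange(B)
    rank_p[order_p] = np.arange(B)
    rank_sum = rank_a + rank_p
    # descending rank-sum, lexicographic names on ties
    ordered = sorted(range(B), key=lambda l: (-rank_sum[l], names[l]))

    retained = list(ordered)
    while len(retained) > K:
        base = _kendall_tau(
            summary.abundance[retained], summary.prevalence[retained]
        )
        victim = retained[-1]
        for cand in reversed(retained):
            rest = [l for l in retained if l != cand]
            if _kendall_tau(summary.abundance[rest], summary.prevalence[rest]) > base:
                victim = cand
                break
        retained.remove(victim)
    tau = _kendall_tau(summary.abundance[retained], summary.prevalence[retained])
    return FeatureSubset(tuple(names[l] for l in retained), tau=tau)


def aggregate_others(
    counts: CountTable, keep, others_name: str = "Others"
) -> CountTable:
    """Keep the given taxa and pool every dropped taxon into ``others_name``.

    Per-subject totals are conserved exactly; the output always has
    ``len(keep) + 1`` columns (the pooled column is all zeros when nothing is
    dropped).
    """
    names = keep.names if isinstance(keep, FeatureSubset) else tuple(keep)
    missing = set(names) - set(counts.taxon_names)
    if missing:
        raise ValueError(f"kept taxa not in table: {sorted(missing)}")
    if others_name in names:
        raise ValueError(f"{others_name!r} collides with a kept taxon name")
    keep_idx = [counts.taxon_names.index(n) for n in names]
    drop_idx = [l for l in range(counts.n_taxa) if l not in set(keep_idx)]
    others = counts.counts[:, drop_idx].sum(axis=1) if drop_idx else np.zeros(
        counts.n_subjects, dtype=np.int64
    )
    out = np.column_stack([counts.counts[:, keep_idx], others])
    return CountTable(counts.subject_ids, names + (others_name,), out)


def per_class_taupath(
    counts: CountTable, labels: LabelVector, K: int, omega: float
) -> tuple[str, ...]:
    """Apply the top-K concordance filter within each health-status class and
    union the selections (alternative preprocessing mode)."""
    selected: list[str] = []
    for level in labels.level_order:
        ids = [s for s, lab in zip(labels.subject_ids, labels.labels) if lab == level]
        if not ids:
            continue
        sub = counts.select_subjects(ids)
        summary = summarize_features(compute_proportions(sub), omega)
        for name in taupath_rank(summary, min(K, sub.n_taxa)).names:
            if name not in selected:
                selected.append(name)
    return tuple(selected)
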