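"""SCUT-style hybrid class balancing of the count table.

Minority classes are oversampled with SMOTE (synthetic rows interpolated
between a class member and one of its k nearest same-class neighbours,
rounded back to non-negative integer counts) and majority classes are
undersampled by seeded k-means clustering, keeping at least one
representative per sub-cluster, so that every class ends up with exactly the
target number of subjects (default round(M / C)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .io_interface import CountTable, LabelVector

__all__ = ["BalanceConfig", "smote_oversample", "cluster_undersample", "scut_balance"]


@dataclass(frozen=True)
class BalanceConfig:
    target: int
    k: int = 5  # SMOTE neighbour count (clamped to class size - 1)
    n_clusters: int | None = None  # undersampling clusters; default = target
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target < 1:
            raise ValueError("target must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


def smote_oversample(
    X: np.ndarray, target: int, k: int, seed: int, return_provenance: bool = False
):
    """Grow a class to ``target`` rows with SMOTE interpolation.

    Each synthetic row is x + delta * (x_nn - x) with delta ~ U[0, 1] and
    x_nn one of x's k nearest same-class neighbours (Euclidean), rounded to
    non-negative integers.  Original rows are returned unmodified, first.
    """
    X = np.asarray(X)
    n = X.shape[0]
    if n < 1:
        raise ValueError("class must have at least one row")
    if target < n:
        raise ValueError("target below current class size; undersample instead")
    if target == n:
        return (X.copy(), []) if return_provenance else X.copy()
    rng = np.random.default_rng(seed)
    n_syn = target - n
    if n == 1:
        # no neighbour exists: replicate the lone row
        seeds = np.zeros(n_syn, dtype=int)
        neighbours = np.zeros(n_syn, dtype=int)
    else:
        k_eff = min(k, n - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
        _, idx = nn.kneighbors(X)  # column 0 is the row itself
        seeds = rng.integers(0, n, size=n_syn)
        neighbours = np.array(
            [idx[s, 1 + rng.integers(0, k_eff)] for s in seeds], dtype=int
        )
    deltas = rng.random(n_syn)
    raw = X[seeds] + deltas[:, None] * (X[neighbours] - X[seeds])
    synthetic = np.maximum(np.rint(raw), 0).astype(X.dtype)
    out = np.vstack([X, synthetic])
    if return_provenance:
        prov = [
            {"seed_row": int(s), "neighbour_row": int(t), "delta": float(d)}
            for s, t, d in zip(seeds, neighbours, deltas)
        ]
        return out, prov
    return out


def cluster_undersample(X: np.ndarray, target: int, seed: int) -> np.ndarray:
    """Shrink a class to ``target`` rows, keeping cluster representatives.

    Rows are partitioned into min(target, #distinct rows) seeded k-means
    clusters; the row nearest each centroid is kept, and remaining slots are
    filled with the next-nearest rows cycling over clusters.  Every kept row
    is an original row (indices into X are returned implicitly by value).
    """
    X = np.asarray(X)
    n = X.shape[0]
    if target > n:
        raise ValueError("target above current class size; oversample instead")
    if target == n:
        return X.copy()
    n_distinct = np.unique(X, axis=0).shape[0]
    n_clusters = min(target, n_distinct)
    km = KMeans(n_clusters=n_clusters, n_init=5, random_state=seed).fit(
        X.astype(float)
    )
    dist = km.transform(X.astype(float))
    kept: list[int] = []
    # per-cluster rows ordered by distance to their centroid
    per_cluster = [
        sorted(np.where(km.labels_ == c)[0], key=lambda i: (dist[i, c], i))
        for c in range(n_clusters)
    ]
    depth = 0
    while len(kept) < target:
        for rows in per_cluster:
            if depth < len(rows) and len(kept) < target:
                kept.append(int(rows[depth]))
        depth += 1
    return X[sorted(kept)]


def scut_balance(
    counts: CountTable, labels: LabelVector, cfg: BalanceConfig
) -> tuple[CountTable, LabelVector]:
    """Balance every class to exactly ``cfg.target`` subjects.

    Classes below target are SMOTE-oversampled (synthetic subject IDs get a
    "_syn<k>" suffix), classes above target are cluster-undersampled, classes
    at target pass through unchanged.
    """
    sizes = labels.class_sizes()
    for lvl, n in sizes.items():
        if n == 0:
            raise ValueError(f"class {lvl!r} is empty")
    ids_out: list[str] = []
    labels_out: list[str] = []
    rows_out: list[np.ndarray] = []
    for ci, level in enumerate(labels.level_order):
        ids = [s for s, lab in zip(labels.subject_ids, labels.labels) if lab == level]
        X = counts.select_subjects(ids).counts
        seed = (cfg.seed + ci) % (2**31)
        if len(ids) < cfg.target:
            X_new = smote_oversample(X, cfg.target, cfg.k, seed)
            new_ids = list(ids) + [
                f"{level}_syn{k + 1}" for k in range(cfg.target - len(ids))
            ]
        elif len(ids) > cfg.target:
            X_new = cluster_undersample(X, cfg.target, seed)
            # recover which original rows survived (undersampling keeps rows verbatim)
            new_ids = _match_rows(X, X_new, ids)
        else:
            X_new, new_ids = X.copy(), list(ids)
        ids_out.extend(new_ids)
        labels_out.extend([level] * cfg.target)
        rows_out.append(X_new)
    out_counts = CountTable(
        tuple(ids_out), counts.taxon_names, np.vstack(rows_out)
    )
    out_labels = LabelVector(tuple(ids_out), tuple(labels_out), labels.level_order)
    return out_counts, out_labels


def _match_rows(X: np.ndarray, X_kept: np.ndarray, ids: list[str]) -> list[str]:
    """Map kept rows back to subject IDs (first unused exact match wins)."""
    used = np.zeros(len(ids), dtype=bool)
    out = []
    for row in X_kept:
        for i in range(len(ids)):
            if not used[i] and np.array_equal(X[i], row):
                used[i] = True
                out.append(ids[i])
                break
        else:  # pragma: no cover - undersampling returns original rows
            raise AssertionError("kept row not found among originals")
    return out
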