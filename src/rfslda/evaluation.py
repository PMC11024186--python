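"""Train/test and k-fold evaluation protocols.

LDA fitting and topic→status matching happen on training subjects only; test
subjects are classified by fold-in inference (beta held fixed from training),
hard topic assignment, and the *trained* matching.  The 80-20 split uses
per-class floor rounding: class c contributes floor(train_fraction * n_c)
subjects to training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io_interface import CountTable, LabelVector, RunConfig, spawn_seed
from .label_matching import ClassWeights, best_matching, confusion_matrix, weighted_metrics
from .topic_model import assign_topics, fit_lda, infer_theta

__all__ = ["EvalReport", "stratified_split", "stratified_folds", "evaluate_semisupervised"]


@dataclass(frozen=True)
class EvalReport:
    """Per-fold and aggregate weighted metrics for train and test."""

    folds: tuple[dict, ...]
    train: dict[str, float]
    test: dict[str, float]
    seed: int


def stratified_split(
    labels: LabelVector, train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Per class, exactly floor(train_fraction * n_c) subjects go to train,
    chosen uniformly at random; the rest go to test."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for level in labels.level_order:
        ids = [s for s, lab in zip(labels.subject_ids, labels.labels) if lab == level]
        n_train = int(np.floor(train_fraction * len(ids)))
        if n_train == 0:
            warnings.warn(
                f"class {level!r} has no training members at fraction "
                f"{train_fraction}", stacklevel=2
            )
        if n_train == len(ids):
            warnings.warn(f"class {level!r} has no test members", stacklevel=2)
        picked = rng.choice(len(ids), size=n_train, replace=False)
        chosen = {ids[i] for i in picked}
        train.extend(s for s in ids if s in chosen)
        test.extend(s for s in ids if s not in chosen)
    return train, test


def stratified_folds(
    labels: LabelVector, k: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """k stratified folds; test sets partition the subjects exactly."""
    ids = np.array(labels.subject_ids)
    y = labels.level_indices()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (list(ids[tr]), list(ids[te])) for tr, te in skf.split(ids, y)
    ]


def _fit_and_score(
    counts: CountTable,
    labels: LabelVector,
    train_ids: list[str],
    test_ids: list[str],
    cfg: RunConfig,
    seed: int,
) -> dict:
    tr_counts = counts.select_subjects(train_ids)
    tr_labels = labels.select_subjects(train_ids)
    te_counts = counts.select_subjects(test_ids)
    te_labels = labels.select_subjects(test_ids)
    missing = [
        lvl for lvl, n in tr_labels.class_sizes().items()
        if n == 0 and lvl in te_labels.labels
    ]
    if missing:
        raise ValueError(
            f"test classes absent from training (matching undefined): {missing}"
        )
    w = ClassWeights(cfg.weights)
    model = fit_lda(tr_counts, cfg.T, alpha=cfg.alpha, seed=seed)
    matching, _, cm_train = best_matching(
        assign_topics(model.theta), tr_labels, w
    )
    theta_te = infer_theta(model, te_counts)
    predicted = [
        matching.level_of(int(t)) for t in assign_topics(theta_te).topics
    ]
    cm_test = confusion_matrix(te_labels, predicted)
    return {
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "train": weighted_metrics(cm_train, w),
        "test": weighted_metrics(cm_test, w),
    }


def evaluate_semisupervised(
    counts: CountTable,
    labels: LabelVector,
    cfg: RunConfig,
    folds: list[tuple[list[str], list[str]]] | None = None,
) -> EvalReport:
    """Run the train-only fit/match protocol over the given folds (default:
    cfg.n_folds stratified folds) and aggregate metrics by the mean."""
    if folds is None:
        folds = stratified_folds(labels, cfg.n_folds, spawn_seed(cfg.seed, 10))
    records = []
    for f, (train_ids, test_ids) in enumerate(folds):
        records.append(
            _fit_and_score(
                counts, labels, train_ids, test_ids, cfg, seed=spawn_seed(cfg.seed, 11, f)
            )
        )
    agg = {
        role: {
            key: float(np.mean([r[role][key] for r in records]))
            for key in records[0][role]
        }
        for role in ("train", "test")
    }
    return EvalReport(
        folds=tuple(records), train=agg["train"], test=agg["test"], seed=cfg.seed
    )
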