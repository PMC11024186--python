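"""Input/output layer: count tables, label files, run configuration, pipeline.

A count table is a subjects × taxa matrix of non-negative integer 16S read
counts (subjects in rows).  Labels are fuzzy health-status levels, one per
subject.  ``run_pipeline`` orchestrates the full method: abundance/prevalence
filtering, LDA fit, topic→status matching, randomized feature selection and
interpretation, and is deterministic given (inputs, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("rfslda")

__all__ = [
    "CountTable",
    "LabelVector",
    "RunConfig",
    "read_counts",
    "write_counts",
    "read_labels",
    "read_config",
    "run_pipeline",
    "write_report",
    "spawn_seed",
]


def spawn_seed(master: int, *path: int) -> int:
    """Deterministic per-stage child seed (< 2**31) from a master seed.

    ``path`` identifies the stage (and, if needed, sub-stage) so that
    independent stages never share an RNG stream.
    """
    ss = np.random.SeedSequence([int(master), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountTable:
    """Subjects × taxa integer read counts.

    ``counts[i, l]`` is the number of reads of taxon ``taxon_names[l]``
    observed in subject ``subject_ids[i]``.
    """

    subject_ids: tuple[str, ...]
    taxon_names: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "subject_ids", tuple(map(str, self.subject_ids)))
        object.__setattr__(self, "taxon_names", tuple(map(str, self.taxon_names)))
        m, b = counts.shape
        if m < 1 or b < 1:
            raise ValueError("count table must have at least one subject and one taxon")
        if len(self.subject_ids) != m or len(self.taxon_names) != b:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.subject_ids)) != m:
            raise ValueError("duplicate subject IDs")
        if len(set(self.taxon_names)) != b:
            raise ValueError("duplicate taxon names")
        if (counts < 0).any():
            i, l = map(int, np.argwhere(counts < 0)[0])
            raise ValueError(
                f"negative count at subject {self.subject_ids[i]!r}, "
                f"taxon {self.taxon_names[l]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.subject_ids), columns=list(self.taxon_names)
        )

    def select_taxa(self, names: Sequence[str]) -> "CountTable":
        """Restrict to the given taxa, preserving their given order."""
        idx = [self.taxon_names.index(n) for n in names]
        return CountTable(self.subject_ids, tuple(names), self.counts[:, idx])

    def select_subjects(self, ids: Sequence[str]) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in ids]
        return CountTable(tuple(ids), self.taxon_names, self.counts[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.taxon_names == other.taxon_names
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class LabelVector:
    """Per-subject health-status labels with a fixed level order.

    ``level_order`` fixes the C distinct levels and is the convention used by
    every confusion matrix and weight vector downstream.
    """

    subject_ids: tuple[str, ...]
    labels: tuple[str, ...]
    level_order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", tuple(map(str, self.subject_ids)))
        object.__setattr__(self, "labels", tuple(map(str, self.labels)))
        object.__setattr__(self, "level_order", tuple(map(str, self.level_order)))
        if len(self.subject_ids) != len(self.labels):
            raise ValueError("subject_ids and labels length mismatch")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject IDs in labels")
        if len(set(self.level_order)) != len(self.level_order):
            raise ValueError("duplicate levels in level_order")
        if len(self.level_order) < 2:
            raise ValueError("need at least two health-status levels")
        unknown = set(self.labels) - set(self.level_order)
        if unknown:
            raise ValueError(f"labels not in level_order: {sorted(unknown)}")

    @property
    def n_levels(self) -> int:
        return len(self.level_order)

    def level_indices(self) -> np.ndarray:
        pos = {lvl: i for i, lvl in enumerate(self.level_order)}
        return np.array([pos[x] for x in self.labels], dtype=np.int64)

    def class_sizes(self) -> dict[str, int]:
        return {lvl: self.labels.count(lvl) for lvl in self.level_order}

    def select_subjects(self, ids: Sequence[str]) -> "LabelVector":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        return LabelVector(
            tuple(ids), tuple(self.labels[pos[s]] for s in ids), self.level_order
        )


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; mirrors the config-file keys one to one."""

    T: int = 3
    K: int = 50
    omega: float = 0.001  # prevalence detection threshold on proportions
    weights: tuple[float, ...] = (0.6, 0.15, 0.25)
    alpha: float | str = "estimate"
    # randomized feature search
    run_rfs: bool = True
    rfs_c: int = 1
    rfs_p: int | None = None  # default ceil(n/2), resolved at run time
    rfs_t0: float = 0.0001
    rfs_u: float = 0.5
    rfs_R: int = 50
    rfs_patience: int = 100
    rfs_max_moves: int = 2000
    # interpretation
    similarity_lambda: float = 0.7
    top_n_profile: int = 10
    # balancing
    balance: bool = False
    balance_target: int | None = None  # default round(M / C)
    smote_k: int = 5
    # evaluation
    train_fraction: float = 0.8
    n_folds: int = 5
    per_class_taupath: bool = False
    seed: int = 13

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(x) for x in self.weights))
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for name in ("omega", "rfs_u", "train_fraction"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if self.rfs_t0 < 0:
            raise ValueError("rfs_t0 must be >= 0")
        if not 0.0 < self.similarity_lambda <= 1.0:
            raise ValueError("similarity_lambda must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in head else ","


def read_counts(
    path: str | Path, dialect: str | None = None, transpose: bool = False
) -> CountTable:
    """Read a delimited count table: header row of taxon names, first column
    of subject IDs.  ``dialect`` is the delimiter ("\\t" or ","); sniffed from
    the header when omitted.  ``transpose=True`` reads taxa-in-rows exports.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    sep = dialect or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"ragged or missing cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if transpose:
        df = df.T
    counts = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        try:
            v = float(cell)
        except ValueError:
            raise ValueError(
                f"non-numeric count {cell!r} at subject {df.index[i]!r}, "
                f"taxon {df.columns[j]!r}"
            ) from None
        if v != int(v):
            raise ValueError(
                f"non-integer count {cell!r} at subject {df.index[i]!r}, "
                f"taxon {df.columns[j]!r}"
            )
        if v < 0:
            raise ValueError(
                f"negative count {cell!r} at subject {df.index[i]!r}, "
                f"taxon {df.columns[j]!r}"
            )
        counts[i, j] = int(v)
    return CountTable(tuple(df.index), tuple(df.columns), counts)


def write_counts(table: CountTable, path: str | Path, dialect: str = "\t") -> None:
    table.to_dataframe().to_csv(path, sep=dialect, index_label="subject_id")


def read_labels(
    path: str | Path,
    counts: CountTable,
    dialect: str | None = None,
    level_order: Sequence[str] | None = None,
) -> LabelVector:
    """Read a two-column subject→label file and align it to ``counts``.

    Level order defaults to first-appearance order in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    sep = dialect or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("label file must have exactly two columns: subject_id, label")
    mapping: dict[str, str] = {}
    order: list[str] = []
    for sid, lab in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sid, lab = str(sid), str(lab)
        if sid in mapping and mapping[sid] != lab:
            raise ValueError(f"conflicting labels for subject {sid!r}")
        mapping[sid] = lab
        if lab not in order:
            order.append(lab)
    unknown = set(mapping) - set(counts.subject_ids)
    if unknown:
        raise ValueError(f"labels for unknown subjects: {sorted(unknown)}")
    missing = [s for s in counts.subject_ids if s not in mapping]
    if missing:
        raise ValueError(f"subjects missing a label: {missing}")
    levels = tuple(level_order) if level_order is not None else tuple(order)
    return LabelVector(
        counts.subject_ids,
        tuple(mapping[s] for s in counts.subject_ids),
        levels,
    )


_CONFIG_KEYS = {f.name for f in fields(RunConfig)}


def read_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config file must be a flat key/value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "weights" in raw:
        raw = dict(raw, weights=tuple(raw["weights"]))
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _stage(name: str, shape: tuple[int, ...], seed: int | None, t0: float) -> None:
    log.info(
        "stage=%s shape=%s seed=%s elapsed=%.3fs", name, shape, seed, time.perf_counter() - t0
    )


def run_pipeline(
    config: RunConfig, counts: CountTable, labels: LabelVector
) -> dict:
    """Run the full method end to end and return the report bundle.

    Stages: proportion/abundance/prevalence filtering to the top-K taxa plus
    "Others"; optional SCUT balancing; LDA fit; exhaustive topic→status
    matching by weighted accuracy; randomized feature-subset search; per-class
    taxon profiles and within-group similarity labels.  Deterministic given
    (inputs, config.seed).
    """
    from . import class_balance, feature_search, interpretation, label_matching
    from . import preprocess, topic_model

    if config.K > counts.n_taxa:
        raise ValueError(
            f"K={config.K} exceeds the number of taxa B={counts.n_taxa}"
        )
    if config.T != labels.n_levels:
        raise ValueError(
            f"T={config.T} must equal the number of health-status levels "
            f"C={labels.n_levels} for topic matching"
        )
    master = config.seed
    report: dict = {"config": _config_dict(config)}

    # -- preprocess -----------------------------------------------------
    t0 = time.perf_counter()
    P = preprocess.compute_proportions(counts)
    if config.per_class_taupath:
        keep = preprocess.per_class_taupath(counts, labels, config.K, config.omega)
        tau = None
    else:
        summary = preprocess.summarize_features(P, config.omega)
        ranked = preprocess.taupath_rank(summary, min(config.K, counts.n_taxa))
        keep, tau = ranked.names, ranked.tau
    Z = preprocess.aggregate_others(counts, keep)
    report["preprocess"] = {
        "kept_taxa": list(keep),
        "tau": tau,
        "n_taxa_after": Z.n_taxa,
    }
    _stage("preprocess", Z.counts.shape, None, t0)

    # -- optional class balancing --------------------------------------
    if config.balance:
        t0 = time.perf_counter()
        cfg_b = class_balance.BalanceConfig(
            target=config.balance_target
            or round(counts.n_subjects / labels.n_levels),
            k=config.smote_k,
            seed=spawn_seed(master, 1),
        )
        Z, labels = class_balance.scut_balance(Z, labels, cfg_b)
        report["balance"] = {"class_sizes": labels.class_sizes()}
        _stage("balance", Z.counts.shape, cfg_b.seed, t0)

    # -- unsupervised LDA + semi-supervised matching --------------------
    t0 = time.perf_counter()
    lda_seed = spawn_seed(master, 2)
    model = topic_model.fit_lda(Z, config.T, alpha=config.alpha, seed=lda_seed)
    assign = topic_model.assign_topics(model.theta)
    w = label_matching.ClassWeights(config.weights)
    matching, a_w, cm = label_matching.best_matching(assign, labels, w)
    report["semisupervised"] = {
        "weighted_accuracy": a_w,
        "matching": matching.as_dict(),
        "perplexity": topic_model.perplexity(model, Z),
    }
    _stage("fit+match", model.theta.shape, lda_seed, t0)

    # -- randomized feature selection -----------------------------------
    if config.run_rfs:
        t0 = time.perf_counter()
        rfs_seed = spawn_seed(master, 3)
        cfg_r = feature_search.RFSConfig(
            n=Z.n_taxa,
            c=config.rfs_c,
            p=config.rfs_p or -(-Z.n_taxa // 2),
            t0=config.rfs_t0,
            u=config.rfs_u,
            R=config.rfs_R,
            patience=config.rfs_patience,
            max_moves=config.rfs_max_moves,
            seed=rfs_seed,
        )
        scorer = feature_search.make_pipeline_scorer(
            Z, labels, T=config.T, weights=w, alpha=config.alpha, seed=lda_seed
        )
        result = feature_search.rfs_multi_restart(Z, labels, cfg_r, scorer)
        selected = [Z.taxon_names[i] for i in result.best_subset.indices]
        Z_sel = Z.select_taxa(selected)
        model = topic_model.fit_lda(Z_sel, config.T, alpha=config.alpha, seed=lda_seed)
        assign = topic_model.assign_topics(model.theta)
        matching, a_w, cm = label_matching.best_matching(assign, labels, w)
        report["rfs"] = {
            "selected_taxa": selected,
            "weighted_accuracy": a_w,
            "winning_restart": result.winning_restart,
            "matching": matching.as_dict(),
        }
        Z = Z_sel
        _stage("rfs", (len(selected),), rfs_seed, t0)

    # -- interpretation -------------------------------------------------
    t0 = time.perf_counter()
    profiles = interpretation.class_feature_profile(
        model, matching, min(config.top_n_profile, Z.n_taxa)
    )
    sim = interpretation.similarity_labels(
        model.theta, matching, config.similarity_lambda, subject_ids=Z.subject_ids
    )
    report["interpretation"] = {
        "class_profiles": {
            p.level: [[t, float(v)] for t, v in p.ranked_taxa] for p in profiles
        },
        "similarity_labels": [
            [s.subject_id, s.primary, s.label, float(s.pi1), float(s.pi2)]
            for s in sim
        ],
    }
    report["metrics"] = label_matching.weighted_metrics(cm, w)
    report["final"] = {
        "weighted_accuracy": a_w,
        "confusion_matrix": cm.matrix.tolist(),
        "level_order": list(labels.level_order),
    }
    report["_artifacts"] = {
        "theta": model.theta,
        "beta": model.beta,
        "taxa": list(Z.taxon_names),
        "subjects": list(Z.subject_ids),
        "cm": cm,
        "similarity": sim,
    }
    _stage("interpret", model.beta.shape, None, t0)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = {}
    for f in fields(RunConfig):
        v = getattr(config, f.name)
        d[f.name] = list(v) if isinstance(v, tuple) else v
    return d


def write_report(report: dict, outdir: str | Path) -> None:
    """Write report.json plus TSV artifacts (theta, beta, confusion matrix,
    similarity labels).  Byte-deterministic for a deterministic report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    art = report.pop("_artifacts", None)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    if art is None:
        return
    taxa, subjects = art["taxa"], art["subjects"]
    theta_df = pd.DataFrame(
        art["theta"],
        index=subjects,
        columns=[f"topic_{t + 1}" for t in range(art["theta"].shape[1])],
    )
    theta_df.to_csv(outdir / "theta.tsv", sep="\t", index_label="subject_id")
    beta_df = pd.DataFrame(
        art["beta"],
        index=[f"topic_{t + 1}" for t in range(art["beta"].shape[0])],
        columns=taxa,
    )
    beta_df.to_csv(outdir / "beta.tsv", sep="\t", index_label="topic")
    cm = art["cm"]
    cm_df = pd.DataFrame(cm.matrix, index=cm.levels, columns=cm.levels)
    with open(outdir / "confusion_matrix.tsv", "w") as fh:
        fh.write("# rows=predicted, columns=true\n")
        cm_df.to_csv(fh, sep="\t", index_label="predicted\\true")
    with open(outdir / "similarity_labels.tsv", "w") as fh:
        fh.write("subject_id\tprimary\tlabel\tpi1\tpi2\n")
        for s in art["similarity"]:
            fh.write(f"{s.subject_id}\t{s.primary}\t{s.label}\t{s.pi1!r}\t{s.pi2!r}\n")
    report["_artifacts"] = art
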