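"""Synthetic corpora from the LDA generative process.

Each subject draws a total read count N ~ Poisson(lam) (resampled if 0), a
topic mixture theta ~ Dir(alpha) (symmetric), then each read draws a topic
from theta and a taxon from that topic's distribution.  Optional extras match
the structure of real 16S studies: unbalanced classes (exact class sizes via
rejection sampling on the dominant topic), fuzzy labels (a noise rate that
flips a label to a random other level), zero-inflation (independent cell
zeroing after aggregation), and a planted-feature design for benchmarking the
feature search (informative taxa carry topic-specific mass; noise taxa are
identically distributed across topics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_interface import CountTable, LabelVector
from .label_matching import Matching

__all__ = [
    "SimConfig",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_labels",
    "plant_informative_features",
    "study_preset",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``beta`` may be an explicit T×B matrix; otherwise rows are drawn from a
    sparse Dirichlet and re-drawn until every topic pair is at least
    ``separation`` apart in total variation.  ``n_informative``/``n_noise``
    switch to the planted-feature design instead.
    """

    M: int = 89
    B: int = 109
    T: int = 3
    lam: float = 5000.0  # Poisson mean reads per subject
    alpha: float = 0.1  # symmetric Dirichlet for theta
    beta: np.ndarray | None = None
    separation: float = 0.5  # min pairwise total variation between beta rows
    n_informative: int = 0
    n_noise: int = 0
    informative_mass: float = 0.7  # beta mass on a topic's own informative block
    label_noise: float = 0.0  # rho: P(label flipped to a random other level)
    zero_inflation: float = 0.0  # pi0: P(a count cell is zeroed)
    class_sizes: tuple[int, ...] | None = None  # exact dominant-topic counts
    levels: tuple[str, ...] = ("Healthy", "Infection", "Stress")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.B < 1 or self.T < 1:
            raise ValueError("M, B, T must be >= 1")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("label_noise", "zero_inflation"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_informative + self.n_noise > self.B:
            raise ValueError("n_informative + n_noise must not exceed B")
        if self.n_informative and self.n_informative < self.T:
            raise ValueError("need at least one informative taxon per topic")
        if self.class_sizes is not None:
            if len(self.class_sizes) != self.T:
                raise ValueError("class_sizes must have one entry per topic")
            if sum(self.class_sizes) != self.M:
                raise ValueError("class_sizes must sum to M")
        if len(self.levels) < self.T:
            raise ValueError("need at least T level names")


@dataclass(frozen=True)
class SyntheticCorpus:
    counts: CountTable
    theta: np.ndarray  # M x T ground truth
    beta: np.ndarray  # T x B ground truth
    dominant_topic: np.ndarray  # argmax of theta per subject
    labels: LabelVector
    config: SimConfig


def plant_informative_features(cfg: SimConfig) -> np.ndarray:
    """Topic-taxon matrix for the planted-feature benchmark.

    The first ``n_informative`` taxa are split into T contiguous blocks; topic
    t puts ``informative_mass`` uniformly on its own block, so restricted to
    the informative taxa any two rows are >= informative_mass apart in total
    variation.  The remaining mass is spread identically (uniformly) over the
    noise taxa (and any leftover taxa), making them useless for separating
    topics.
    """
    if cfg.n_informative < cfg.T:
        raise ValueError("n_informative must be >= T")
    B, T = cfg.B, cfg.T
    blocks = np.array_split(np.arange(cfg.n_informative), T)
    rest = np.arange(cfg.n_informative, B)
    if rest.size == 0 and cfg.informative_mass < 1.0:
        raise ValueError("no taxa left to carry the non-informative mass")
    beta = np.zeros((T, B))
    for t, block in enumerate(blocks):
        beta[t, block] = cfg.informative_mass / block.size
        if rest.size:
            beta[t, rest] = (1.0 - cfg.informative_mass) / rest.size
        else:
            beta[t, block] = 1.0 / block.size
    return beta


def _draw_beta(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.beta is not None:
        beta = np.asarray(cfg.beta, dtype=float)
        if beta.shape != (cfg.T, cfg.B):
            raise ValueError("explicit beta must be T x B")
        if (beta < 0).any() or not np.allclose(beta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("explicit beta rows must be probability vectors")
        return beta
    if cfg.n_informative:
        return plant_informative_features(cfg)
    for _ in range(1000):
        beta = rng.dirichlet(np.full(cfg.B, 0.1), size=cfg.T)
        tv = min(
            0.5 * np.abs(beta[i] - beta[j]).sum()
            for i in range(cfg.T)
            for j in range(i + 1, cfg.T)
        ) if cfg.T > 1 else 1.0
        if tv >= cfg.separation:
            return beta
    raise ValueError("could not draw beta rows at the requested separation")


def _draw_theta(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet mixtures; with class_sizes, rejection-sample on the dominant
    topic until each topic's quota of subjects is met exactly."""
    if cfg.class_sizes is None:
        return rng.dirichlet(np.full(cfg.T, cfg.alpha), size=cfg.M)
    quota = list(cfg.class_sizes)
    rows: list[np.ndarray] = []
    guard = 0
    while len(rows) < cfg.M:
        th = rng.dirichlet(np.full(cfg.T, cfg.alpha))
        t = int(th.argmax())
        if quota[t] > 0:
            quota[t] -= 1
            rows.append(th)
        guard += 1
        if guard > 1_000_000:  # pragma: no cover
            raise RuntimeError("rejection sampling failed to meet class sizes")
    return np.vstack(rows)


def generate_corpus(cfg: SimConfig) -> SyntheticCorpus:
    """Draw a full corpus (counts, ground-truth theta/beta, labels).

    Labels are the level matched to each subject's dominant topic under the
    identity matching, with ``cfg.label_noise`` applied; regenerate with
    :func:`generate_labels` for other matchings or noise rates.
    """
    rng = np.random.default_rng(cfg.seed)
    beta = _draw_beta(cfg, rng)
    theta = _draw_theta(cfg, rng)
    counts = np.zeros((cfg.M, cfg.B), dtype=np.int64)
    for i in range(cfg.M):
        n = 0
        while n == 0:  # zero-read subjects are resampled
            n = int(rng.poisson(cfg.lam))
        z = rng.choice(cfg.T, size=n, p=theta[i])
        for t in range(cfg.T):
            n_t = int((z == t).sum())
            if n_t:
                counts[i] += rng.multinomial(n_t, beta[t])
    if cfg.zero_inflation > 0.0:
        for i in range(cfg.M):
            row = counts[i]
            while True:
                mask = rng.random(cfg.B) < cfg.zero_inflation
                if (row * ~mask).sum() > 0:
                    counts[i] = row * ~mask
                    break
    table = CountTable(
        tuple(f"S{i + 1}" for i in range(cfg.M)),
        tuple(f"taxon_{l + 1}" for l in range(cfg.B)),
        counts,
    )
    dominant = theta.argmax(axis=1)
    identity = Matching(cfg.levels[: cfg.T])
    # level_order keeps at least two levels even for degenerate T=1 corpora
    level_order = cfg.levels[: max(cfg.T, 2)]
    corpus = SyntheticCorpus(
        counts=table,
        theta=theta,
        beta=beta,
        dominant_topic=dominant,
        labels=LabelVector(  # placeholder, replaced below
            table.subject_ids,
            tuple(cfg.levels[t] for t in dominant),
            level_order,
        ),
        config=cfg,
    )
    labels = generate_labels(corpus, identity, cfg.label_noise, seed=cfg.seed + 1)
    return replace_labels(corpus, labels)


def replace_labels(corpus: SyntheticCorpus, labels: LabelVector) -> SyntheticCorpus:
    return SyntheticCorpus(
        counts=corpus.counts,
        theta=corpus.theta,
        beta=corpus.beta,
        dominant_topic=corpus.dominant_topic,
        labels=labels,
        config=corpus.config,
    )


def generate_labels(
    corpus: SyntheticCorpus, matching: Matching, rho: float, seed: int
) -> LabelVector:
    """Fuzzy labels: the matched level of each subject's dominant topic,
    flipped to a uniformly random OTHER level with probability rho."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    level_order = corpus.labels.level_order
    out = []
    for t in corpus.dominant_topic:
        lab = matching.level_of(int(t))
        if rho > 0.0 and rng.random() < rho:
            others = [x for x in matching.levels if x != lab]
            if others:
                lab = others[int(rng.integers(len(others)))]
        out.append(lab)
    return LabelVector(corpus.counts.subject_ids, tuple(out), level_order)


def study_preset(seed: int = 0, **overrides) -> SimConfig:
    """Study-shaped corpus: M=89 subjects, B=109 taxa, T=3 topics, unbalanced
    classes (66, 6, 17), ~5000 reads per subject, 30% zero-inflation."""
    base = dict(
        M=89,
        B=109,
        T=3,
        lam=5000.0,
        alpha=0.1,
        separation=0.5,
        zero_inflation=0.3,
        class_sizes=(66, 6, 17),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
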