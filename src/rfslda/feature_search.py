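"""Randomized wrapper feature selection over taxon subsets.

A local search over subsets of the (already filtered) taxa: each move flips a
fair three-sided coin — (1) swap a member for a non-member, (2) remove a
member, (3) add a non-member — scores the proposal by refitting the whole
semi-supervised pipeline on the restricted table, and accepts improving moves
always, non-improving moves with probability 1 - u.  The search stops when
the best score has not improved by more than t0 for `patience` consecutive
moves (or at a hard move cap), and the whole run is restarted R times from
independent random initial subsets to wash out initialization sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

from .io_interface import CountTable, LabelVector, spawn_seed

__all__ = [
    "RFSConfig",
    "SubsetState",
    "MoveRecord",
    "RunTrace",
    "RFSResult",
    "propose_move",
    "accept_move",
    "rfs_single_run",
    "rfs_multi_restart",
    "make_pipeline_scorer",
]


@dataclass(frozen=True)
class RFSConfig:
    """Search parameters.  Defaults follow the method's published settings
    (c=1, p=ceil(n/2), t0=1e-4, R=50); u is the stay probability on a
    non-improving move and was left unspecified, defaulting to 1/2."""

    n: int
    c: int = 1
    p: int | None = None
    t0: float = 0.0001
    u: float = 0.5
    R: int = 50
    patience: int = 100
    max_moves: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p is None:
            object.__setattr__(self, "p", -(-self.n // 2))  # ceil(n/2)
        if not 1 <= self.p <= self.n:
            raise ValueError("p must lie in [1, n]")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("u must lie in [0, 1]")
        if self.R < 1:
            raise ValueError("R must be >= 1")


@dataclass(frozen=True)
class SubsetState:
    """A feature subset as sorted 0-based indices into the full feature list."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(self.indices))
        if not idx:
            raise ValueError("subset must be non-empty")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate indices in subset")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


class ProposedMove(NamedTuple):
    subset: SubsetState
    coin: int  # effective coin after feasibility redraw


class MoveRecord(NamedTuple):
    move: int
    coin: int
    accepted: bool
    score: float
    best: float


@dataclass
class RunTrace:
    seed: int
    initial: SubsetState
    records: list[MoveRecord] = field(default_factory=list)
    best_subset: SubsetState | None = None
    best_score: float = -np.inf


@dataclass
class RFSResult:
    best_subset: SubsetState
    best_score: float
    traces: list[RunTrace]
    winning_restart: int


def _feasible_coins(size: int, n: int, c: int) -> list[int]:
    coins = []
    if size >= c and n - size >= c:
        coins.append(1)
    if size - c >= 1:
        coins.append(2)
    if size + c <= n:
        coins.append(3)
    return coins


def propose_move(
    current: SubsetState,
    n: int,
    coin: int,
    c: int,
    rng: np.random.Generator,
) -> ProposedMove:
    """Apply one coin move; an infeasible coin (the resulting size would
    leave [1, n]) is redrawn uniformly among the feasible coins.

    coin 1: remove c uniformly-chosen members and add c uniformly-chosen
    non-members (size preserved); coin 2: remove c members; coin 3: add c
    non-members.
    """
    if coin not in (1, 2, 3):
        raise ValueError("coin must be 1, 2 or 3")
    feasible = _feasible_coins(len(current), n, c)
    if not feasible:
        return ProposedMove(current, 0)  # n == 1: nothing can move
    if coin not in feasible:
        coin = int(rng.choice(feasible))
    members = np.array(current.indices)
    non_members = np.setdiff1d(np.arange(n), members)
    if coin == 1:
        out = np.setdiff1d(members, rng.choice(members, size=c, replace=False))
        out = np.concatenate([out, rng.choice(non_members, size=c, replace=False)])
    elif coin == 2:
        out = np.setdiff1d(members, rng.choice(members, size=c, replace=False))
    else:
        out = np.concatenate(
            [members, rng.choice(non_members, size=c, replace=False)]
        )
    return ProposedMove(SubsetState(tuple(int(i) for i in out)), coin)


def accept_move(
    new_score: float, old_score: float, u: float, rng: np.random.Generator
) -> bool:
    """True = move to the proposal.  Improving proposals are always taken;
    otherwise stay with probability u, move with probability 1 - u."""
    if new_score > old_score:
        return True
    return bool(rng.random() >= u)


def rfs_single_run(
    cfg: RFSConfig,
    scorer: Callable[[SubsetState], float],
    seed: int,
    cache: dict | None = None,
) -> RunTrace:
    """One randomized local-search run from a uniform random size-p subset.

    The scorer must be deterministic per subset; scores are cached by subset.
    Scorer failures score -inf (logged in the trace as a non-improving move).
    """
    rng = np.random.default_rng(seed)
    cache = cache if cache is not None else {}

    def score(s: SubsetState) -> float:
        key = s.indices
        if key not in cache:
            try:
                cache[key] = float(scorer(s))
            except Exception:  # noqa: BLE001 - any scorer failure is non-fatal
                cache[key] = -np.inf
        return cache[key]

    init = SubsetState(
        tuple(int(i) for i in rng.choice(cfg.n, size=cfg.p, replace=False))
    )
    trace = RunTrace(seed=seed, initial=init)
    current, a = init, score(init)
    trace.best_subset, trace.best_score = current, a
    stall = 0
    for move in range(cfg.max_moves):
        if cfg.n == 1:
            break
        coin = int(rng.integers(1, 4))
        proposal, coin = propose_move(current, cfg.n, coin, cfg.c, rng)
        a_new = score(proposal)
        moved = accept_move(a_new, a, cfg.u, rng)
        if moved:
            current, a = proposal, a_new
        if a_new > trace.best_score + cfg.t0:
            stall = 0
        else:
            stall += 1
        if a_new > trace.best_score:
            trace.best_subset, trace.best_score = proposal, a_new
        assert 1 <= len(current) <= cfg.n
        trace.records.append(MoveRecord(move, coin, moved, a_new, trace.best_score))
        if stall >= cfg.patience:
            break
    return trace


def rfs_multi_restart(
    counts: CountTable,
    labels: LabelVector,
    cfg: RFSConfig,
    scorer: Callable[[SubsetState], float],
) -> RFSResult:
    """R independent restarts with deterministic child seeds; the winner is
    the restart with the highest best score (ties: lowest restart index).
    The score cache is shared across restarts (the scorer is deterministic)."""
    if cfg.n != counts.n_taxa:
        raise ValueError("cfg.n must equal the number of taxa in the table")
    cache: dict = {}
    traces = []
    for r in range(cfg.R):
        traces.append(
            rfs_single_run(cfg, scorer, seed=spawn_seed(cfg.seed, r), cache=cache)
        )
    winner = max(range(cfg.R), key=lambda r: (traces[r].best_score, -r))
    best = traces[winner]
    assert best.best_subset is not None
    return RFSResult(
        best_subset=best.best_subset,
        best_score=best.best_score,
        traces=traces,
        winning_restart=winner,
    )


def make_pipeline_scorer(
    counts: CountTable,
    labels: LabelVector,
    T: int,
    weights,
    alpha: float | str = "estimate",
    seed: int = 0,
    **lda_kwargs,
) -> Callable[[SubsetState], float]:
    """Subset → weighted accuracy of the semi-supervised fit on the
    subset-restricted table.  Dropped taxa are simply excluded (no
    re-aggregation); the LDA seed is held fixed so the scorer is
    deterministic per subset."""
    from .label_matching import ClassWeights, best_matching
    from .topic_model import assign_topics, fit_lda

    w = weights if isinstance(weights, ClassWeights) else ClassWeights(tuple(weights))

    def scorer(subset: SubsetState) -> float:
        names = [counts.taxon_names[i] for i in subset.indices]
        sub = counts.select_taxa(names)
        model = fit_lda(sub, T, alpha=alpha, seed=seed, **lda_kwargs)
        _, score, _ = best_matching(assign_topics(model.theta), labels, w)
        return score

    return scorer
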