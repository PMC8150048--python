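"""Markov chains over n-tuples of action profiles.

A joint memory-``n`` strategy profile induces a Markov chain whose states
are the ``n``-tuples of the last action profiles, flat-indexed with the most
recent profile most significant.  A transition appends the new profile and
drops the oldest, so each state has at most ``M**N`` successors; the
transition probability is the product of the players' conditional action
probabilities.  The chain may be reducible (deterministic strategies make
this common), so stationary distributions are computed per closed
communicating class and never averaged across classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .catalog import StrategyTable
from .game import Game, extended_payoff, profile_unflatten

__all__ = [
    "TransitionMatrix",
    "TupleDistribution",
    "build_transition",
    "recurrent_classes",
    "stationary",
    "correlation",
    "lag_correlations",
    "extend_distribution",
]

#: Refuse chains larger than this many states.
MAX_STATES = 65536

#: Below this size the transition matrix is kept dense.
DENSE_CUTOFF = 256

_STAT_TOL = 1e-10


def _check_size(n_states: int) -> None:
    if n_states > MAX_STATES:
        raise ValueError(
            f"state space of size {n_states} exceeds the supported maximum "
            f"{MAX_STATES}; reduce memory, players or actions"
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix of the tuple chain."""

    order: int
    n_players: int
    n_actions: int
    matrix: np.ndarray | sp.csr_matrix = field(repr=False)
    #: per-player action probabilities over states, shape (M, n_states) each
    strategy_probs: tuple[np.ndarray, ...] = field(repr=False, default=())

    @property
    def n_profiles(self) -> int:
        return self.n_actions**self.n_players

    @property
    def n_states(self) -> int:
        return self.n_profiles**self.order

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)


@dataclass(frozen=True)
class TupleDistribution:
    """A probability distribution over ``n``-tuples of action profiles."""

    order: int
    n_players: int
    n_actions: int
    probs: np.ndarray = field(repr=False)
    #: flat state indices the distribution is supported on
    support: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        n_states = (self.n_actions**self.n_players) ** self.order
        if p.shape != (n_states,):
            raise ValueError(
                f"distribution has shape {p.shape}, expected ({n_states},)"
            )
        if np.any(p < -1e-12):
            raise ValueError("distribution has negative entries")
        if abs(p.sum() - 1) > 1e-12:
            raise ValueError(f"distribution sums to {p.sum()!r}, not 1")
        p = np.clip(p, 0.0, None)
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)
        if self.support is None:
            object.__setattr__(self, "support", np.flatnonzero(p > 0))

    @property
    def n_profiles(self) -> int:
        return self.n_actions**self.n_players

    def profile_at(self, lag: int) -> np.ndarray:
        """Flat profile index at the given lag (0 = most recent) per state."""
        if not 0 <= lag < self.order:
            raise ValueError(f"lag {lag} outside {{0..{self.order - 1}}}")
        P = self.n_profiles
        states = np.arange(len(self.probs))
        return (states // P ** (self.order - 1 - lag)) % P


def build_transition(strategies: list[StrategyTable], game: Game) -> TransitionMatrix:
    """Chain over ``n``-tuples induced by one strategy table per player."""
    if len(strategies) != game.n_players:
        raise ValueError(
            f"need {game.n_players} strategies, got {len(strategies)}"
        )
    n = strategies[0].memory
    for a, s in enumerate(strategies, start=1):
        if s.memory != n:
            raise ValueError(
                f"strategy at position {a} has memory {s.memory}, expected {n}"
            )
        if s.n_players != game.n_players or s.n_actions != game.n_actions:
            raise ValueError(
                f"strategy at position {a} sized for "
                f"N={s.n_players}, M={s.n_actions}; game has "
                f"N={game.n_players}, M={game.n_actions}"
            )
    P = game.n_profiles
    n_states = P**n
    _check_size(n_states)

    states = np.arange(n_states)
    dest_tail = states // P  # drop the oldest profile
    rows, cols, vals = [], [], []
    profile_actions = [
        profile_unflatten(f, game.n_players, game.n_actions) for f in range(P)
    ]
    for f in range(P):
        prob = np.ones(n_states)
        for a, strat in enumerate(strategies):
            prob = prob * strat.probs[profile_actions[f][a] - 1]
        rows.append(states)
        cols.append(f * P ** (n - 1) + dest_tail)
        vals.append(prob)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    keep = vals > 0  # impossible transitions must not appear as graph edges
    mat = sp.csr_matrix(
        (vals[keep], (rows[keep], cols[keep])), shape=(n_states, n_states)
    )
    if n_states < DENSE_CUTOFF:
        mat = mat.toarray()
    return TransitionMatrix(
        order=n,
        n_players=game.n_players,
        n_actions=game.n_actions,
        matrix=mat,
        strategy_probs=tuple(s.probs for s in strategies),
    )


def recurrent_classes(tm: TransitionMatrix) -> list[np.ndarray]:
    """Closed communicating classes of the chain, sorted by smallest state.

    Every finite chain has at least one; a class is recurrent when no
    transition leaves it.
    """
    adj = sp.csr_matrix(tm.matrix != 0) if not sp.issparse(tm.matrix) else (
        sp.csr_matrix((np.ones_like(tm.matrix.data), tm.matrix.indices,
                       tm.matrix.indptr), shape=tm.matrix.shape)
    )
    n_comp, labels = connected_components(adj, connection="strong")
    dense = tm.dense()
    closed = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        outside = np.setdiff1d(np.arange(tm.n_states), members, assume_unique=True)
        if dense[np.ix_(members, outside)].sum() == 0:
            closed.append(members)
    closed.sort(key=lambda m: int(m[0]))
    return closed


def stationary(tm: TransitionMatrix, class_id: int = 0,
               classes: list[np.ndarray] | None = None) -> TupleDistribution:
    """Stationary distribution supported on one recurrent class.

    Solves the fixed point ``p = p T`` restricted to the class by a direct
    dense linear solve with one row replaced by the normalization
    ``sum(p) = 1``; the residual of the fixed-point equation must come out
    below 1e-10 or the solve is reported as failed.
    """
    if classes is None:
        classes = recurrent_classes(tm)
    if not 0 <= class_id < len(classes):
        raise ValueError(
            f"class_id {class_id} out of range; chain has {len(classes)} "
            "recurrent classes"
        )
    members = classes[class_id]
    sub = tm.dense()[np.ix_(members, members)]
    k = len(members)
    A = sub.T - np.eye(k)
    A[-1, :] = 1.0
    b = np.zeros(k)
    b[-1] = 1.0
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(
            f"stationary solve failed on recurrent class {class_id} "
            f"(states {members.tolist()}): {exc}"
        ) from exc
    resid = np.max(np.abs(p @ sub - p))
    if resid > _STAT_TOL or abs(p.sum() - 1) > _STAT_TOL:
        raise ArithmeticError(
            f"stationary solve on class {class_id} has residual {resid:.3e}"
        )
    full = np.zeros(tm.n_states)
    full[members] = np.clip(p, 0.0, None)
    full /= full.sum()
    return TupleDistribution(
        order=tm.order,
        n_players=tm.n_players,
        n_actions=tm.n_actions,
        probs=full,
        support=members,
    )


def correlation(dist: TupleDistribution, game: Game, b: int, c: int) -> float:
    """Stationary expectation ``<s_b(t+1) s_c(t)>``.

    ``s_b`` is evaluated on the most recent profile of the tuple and ``s_c``
    on the one before; ``b = 0`` or ``c = 0`` uses the constant payoff
    ``s_0 = 1``, reducing to a plain stationary average.
    """
    for idx in (b, c):
        if not 0 <= idx <= game.n_players:
            raise ValueError(f"payoff index {idx} outside {{0..{game.n_players}}}")
    if dist.order < 2 and not (b == 0 or c == 0):
        raise ValueError("lag-1 correlation needs a distribution of order >= 2")
    sb = extended_payoff(game, b)
    sc = extended_payoff(game, c)
    vb = sb[dist.profile_at(0)]
    vc = sc[dist.profile_at(1)] if dist.order >= 2 else sc[dist.profile_at(0)]
    return float(np.dot(dist.probs, vb * vc))


def lag_correlations(dist: TupleDistribution, game: Game, lags: int) -> np.ndarray:
    """All product moments across a window of ``lags + 1`` rounds.

    Returns an array of shape ``(N+1,) * (lags+1)`` whose entry
    ``[b_0, ..., b_k]`` is ``<s_{b_0}(t+k) s_{b_1}(t+k-1) ... s_{b_k}(t)>``,
    i.e. index 0 refers to the most recent round in the window.
    """
    if not 0 <= lags <= dist.order - 1:
        raise ValueError(
            f"lag window {lags} exceeds distribution order {dist.order}"
        )
    N = game.n_players
    k = lags + 1
    payoff_by_lag = []
    for j in range(k):
        prof = dist.profile_at(j)
        payoff_by_lag.append(
            np.stack([extended_payoff(game, b)[prof] for b in range(N + 1)])
        )
    out = np.empty((N + 1,) * k)
    for btuple in itertools.product(range(N + 1), repeat=k):
        v = dist.probs.copy()
        for j, b in enumerate(btuple):
            v = v * payoff_by_lag[j][b]
        out[btuple] = v.sum()
    return out


def extend_distribution(tm: TransitionMatrix, dist: TupleDistribution) -> TupleDistribution:
    """One-step extension: joint law of ``(new profile, current tuple)``.

    For a stationary ``dist`` of order ``n`` this is the stationary law of
    the order-``n+1`` tuple, e.g. it turns a memory-one stationary state
    into the pair distribution needed for lag-1 correlations.
    """
    if tm.order != dist.order:
        raise ValueError("transition matrix and distribution orders differ")
    if not tm.strategy_probs:
        raise ValueError("transition matrix lacks per-player strategy tables")
    P = tm.n_profiles
    n_states = tm.n_states
    _check_size(n_states * P)
    out = np.zeros(P * n_states)
    states = np.arange(n_states)
    for f in range(P):
        prob = np.ones(n_states)
        actions = profile_unflatten(f, tm.n_players, tm.n_actions)
        for a in range(tm.n_players):
            prob = prob * tm.strategy_probs[a][actions[a] - 1]
        out[f * n_states + states] = prob * dist.probs
    return TupleDistribution(
        order=dist.order + 1,
        n_players=tm.n_players,
        n_actions=tm.n_actions,
        probs=out / out.sum(),
    )
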