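"""Monte-Carlo match runner with exact-value comparison.

Replays a repeated game between explicit strategy tables with a single
seeded RNG stream (player 1 draws before player 2 each round, so runs are
bitwise reproducible), accumulates the time-average payoff and lag-1
correlation estimators, and compares them against exact stationary values
with batch-means standard errors — the chain is autocorrelated, so i.i.d.
error formulas would be wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import StrategyTable
from .game import Game, extended_payoff
from .markov import TupleDistribution
from .zd import RelationCoefficients

__all__ = ["SimResult", "run_match", "compare_exact", "relation_se",
           "ClassMismatchError"]

#: Number of batches used for batch-means standard errors.
N_BATCHES = 100


class ClassMismatchError(ValueError):
    """The simulation settled in a different recurrent class than compared."""


@dataclass(frozen=True)
class SimResult:
    """Summary of one simulated match.

    ``horizon`` counts rounds after the initial uniformly drawn round; the
    first ``n`` rounds of play (indices ``0..n-1``) are uniform, matching
    the convention that the lag-1 estimator at its first term pairs round 1
    with the uniformly drawn round 0.  ``time_avg_lag1[b, c]`` estimates
    ``<s_b(t+1) s_c(t)>`` as ``sum_{t'=1..t} s_b(sigma(t')) s_c(sigma(t'-1)) / t``.
    """

    horizon: int
    seed: int
    visit_counts: np.ndarray = field(repr=False)
    time_avg_payoffs: np.ndarray = field(repr=False)
    time_avg_lag1: np.ndarray = field(repr=False)
    final_state: int
    relation_value: float | None = None
    # per-batch means, for batch-means standard errors
    batch_payoffs: np.ndarray = field(repr=False, default=None)
    batch_lag1: np.ndarray = field(repr=False, default=None)


def run_match(
    strategies: list[StrategyTable],
    game: Game,
    horizon: int = 100_000,
    seed: int = 0,
    alpha: RelationCoefficients | None = None,
) -> SimResult:
    """Simulate one match and return time-average estimators.

    The first ``n`` rounds (n the strategies' memory) draw every player's
    action uniformly; afterwards each player samples independently from its
    conditional table given the current history.  Identical seeds give
    bitwise-identical results.
    """
    n = strategies[0].memory
    N, M = game.n_players, game.n_actions
    for s in strategies:
        if (s.memory, s.n_players, s.n_actions) != (n, N, M):
            raise ValueError("strategies disagree in memory or dimensions")
    if len(strategies) != N:
        raise ValueError(f"need {N} strategies, got {len(strategies)}")
    if horizon < n:
        raise ValueError(f"horizon {horizon} shorter than memory {n}")
    P = game.n_profiles
    rng = np.random.default_rng(seed)

    cum = [np.cumsum(s.probs, axis=0) for s in strategies]
    profiles = np.empty(horizon + 1, dtype=np.int64)
    # uniform initial rounds 0..n-1, drawn player by player
    for t in range(n):
        f = 0
        for a in range(N):
            f = f * M + int(rng.integers(M))
        profiles[t] = f
    # history flat index: most recent profile most significant
    h = sum(profiles[n - 1 - k] * P**k for k in range(n))
    for t in range(n, horizon + 1):
        f = 0
        for a in range(N):
            u = rng.random()
            act = int(np.searchsorted(cum[a][:, h], u, side="right"))
            f = f * M + min(act, M - 1)
        profiles[t] = f
        h = f * P ** (n - 1) + h // P

    # vectorized post-processing over rounds 1..horizon
    svec = np.stack([extended_payoff(game, b) for b in range(N + 1)])  # (N+1, P)
    cur = profiles[1:]
    prev = profiles[:-1]
    visit_counts = np.bincount(cur, minlength=P)
    s_cur = svec[:, cur]  # (N+1, horizon)
    s_prev = svec[:, prev]
    time_avg_payoffs = s_cur[1:].mean(axis=1)
    lag_series = np.einsum("bt,ct->bct", s_cur, s_prev)
    time_avg_lag1 = lag_series.mean(axis=2)

    edges = np.linspace(0, horizon, N_BATCHES + 1).astype(int)
    batch_payoffs = np.stack(
        [s_cur[1:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])]
    )
    batch_lag1 = np.stack(
        [lag_series[:, :, a:b].mean(axis=2) for a, b in zip(edges[:-1], edges[1:])]
    )

    relation_value = None
    if alpha is not None:
        if alpha.order != 2:
            raise ValueError("simulated relation values support order 2 only")
        relation_value = float(np.sum(alpha.alpha * time_avg_lag1))

    return SimResult(
        horizon=horizon,
        seed=seed,
        visit_counts=visit_counts,
        time_avg_payoffs=time_avg_payoffs,
        time_avg_lag1=time_avg_lag1,
        final_state=int(sum(profiles[horizon - k] * P**k for k in range(n))),
        relation_value=relation_value,
        batch_payoffs=batch_payoffs,
        batch_lag1=batch_lag1,
    )


def relation_se(sim: SimResult, alpha: RelationCoefficients) -> tuple[float, float]:
    """Time-average relation value and its batch-means standard error."""
    if alpha.order != 2:
        raise ValueError("simulated relation values support order 2 only")
    value = float(np.sum(alpha.alpha * sim.time_avg_lag1))
    batch_vals = np.einsum("bc,kbc->k", alpha.alpha, sim.batch_lag1)
    se = float(batch_vals.std(ddof=1) / np.sqrt(len(batch_vals)))
    return value, se


def compare_exact(sim: SimResult, dist: TupleDistribution, game: Game) -> pd.DataFrame:
    """z-scores of the simulated averages against exact stationary values.

    Standard errors come from batch means over 100 batches.  Raises
    :class:`ClassMismatchError` when the simulation's final state lies
    outside the support of ``dist`` — comparing against the wrong recurrent
    class would be silently meaningless.
    """
    from .markov import correlation

    N = game.n_players
    if dist.probs[sim.final_state] <= 0:
        raise ClassMismatchError(
            f"simulation ended in state {sim.final_state}, which has zero "
            "stationary probability in the supplied distribution"
        )
    rows = []
    nb = sim.batch_payoffs.shape[0]
    for a in range(1, N + 1):
        exact = correlation(dist, game, a, 0)
        se = sim.batch_payoffs[:, a - 1].std(ddof=1) / np.sqrt(nb)
        simv = sim.time_avg_payoffs[a - 1]
        rows.append(
            ("payoff", a, 0, simv, exact, se,
             (simv - exact) / se if se > 0 else 0.0 if simv == exact else np.inf)
        )
    for b in range(N + 1):
        for c in range(N + 1):
            exact = correlation(dist, game, b, c)
            se = sim.batch_lag1[:, b, c].std(ddof=1) / np.sqrt(nb)
            simv = sim.time_avg_lag1[b, c]
            rows.append(
                ("lag1", b, c, simv, exact, se,
                 (simv - exact) / se if se > 0 else 0.0 if simv == exact else np.inf)
            )
    return pd.DataFrame(
        rows, columns=["kind", "b", "c", "simulated", "exact", "se", "z"]
    )
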