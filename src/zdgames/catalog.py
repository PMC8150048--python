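"""Strategy tables and the built-in strategy catalog.

A memory-``n`` strategy of player ``a`` is the conditional probability
``T_a(sigma_a | sigma^(-1), ..., sigma^(-n))`` of each own action given the
joint action profiles of the last ``n`` rounds.  Histories are flat-indexed
with the most recent profile most significant, so for memory two the
probability table for one own action reads as the 4x4 matrix with rows
``sigma'`` (last round) and columns ``sigma''`` (second-to-last round), both
in profile order ``(1,1), (1,2), (2,1), (2,2)``.

The catalog provides the standard repeated-Prisoner's-Dilemma strategies used
throughout: tit-for-tat (TFT) and its memory-two relatives (ETFT, ETFT-2,
FTFT, TFT-ATFT), the zero-sum strategy (ZSS) and its memory-two extension
(EZSS), a correlation-enforcing example strategy, the probe opponent, all-D
and Repeat.  Payoff-dependent tables are generated from their symbolic entry
formulas evaluated at the supplied payoffs, so a violated feasibility
condition surfaces as an out-of-range probability rather than a silently
clipped one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import Game, profile_flatten, profile_unflatten
from .zd import RelationCoefficients

__all__ = [
    "StrategyTable",
    "embed_memory",
    "example1",
    "etft",
    "etft2",
    "ftft",
    "zss",
    "ezss",
    "fixed_catalog",
    "probe",
    "enforced_relation",
    "CATALOG_NAMES",
]

_ENTRY_TOL = 1e-12
_ROW_TOL = 1e-9


@dataclass(frozen=True)
class StrategyTable:
    """Conditional action probabilities of one player.

    Parameters
    ----------
    player : int
        1-based player label (metadata; engines use list position).
    memory : int
        Memory length ``n >= 1``.
    n_players, n_actions : int
        Dimensions ``N`` and ``M`` of the game the table is written for.
    probs : ndarray, shape (M, M**(n*N))
        ``probs[sigma_a - 1, h]`` is the probability of own action
        ``sigma_a`` after history ``h`` (most recent profile most
        significant).
    """

    player: int
    memory: int
    n_players: int
    n_actions: int
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.memory < 1:
            raise ValueError("memory must be >= 1")
        if self.player < 1:
            raise ValueError("player labels are 1-based")
        n_hist = self.n_actions ** (self.memory * self.n_players)
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.n_actions, n_hist):
            raise ValueError(
                f"probability table has shape {p.shape}, expected "
                f"({self.n_actions}, {n_hist})"
            )
        if np.any(p < -_ENTRY_TOL) or np.any(p > 1 + _ENTRY_TOL):
            bad = int(np.argmax((p < -_ENTRY_TOL) | (p > 1 + _ENTRY_TOL), axis=None))
            raise ValueError(
                f"probability out of [0, 1] at flat position {bad}: "
                f"{p.ravel()[bad]!r}"
            )
        sums = p.sum(axis=0)
        if np.any(np.abs(sums - 1) > _ROW_TOL):
            h = int(np.argmax(np.abs(sums - 1)))
            raise ValueError(
                f"action probabilities for history {h} sum to {sums[h]!r}, not 1"
            )
        p = np.clip(p, 0.0, 1.0)
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    @property
    def n_histories(self) -> int:
        return self.n_actions ** (self.memory * self.n_players)

    def coop_matrix(self) -> np.ndarray:
        """Cooperation probabilities as an (older-history x last-round) grid.

        For a two-player binary memory-two table this is the familiar 4x4
        matrix with rows ``sigma'`` and columns ``sigma''``.
        """
        n_prof = self.n_actions**self.n_players
        return self.probs[0].reshape(n_prof, -1)

    @classmethod
    def from_coop(
        cls,
        coop,
        player: int = 1,
        memory: int | None = None,
        n_players: int = 2,
    ) -> "StrategyTable":
        """Build a binary-action table from cooperation probabilities.

        ``coop`` may be a flat vector over histories or, for memory two, the
        4x4 matrix (rows ``sigma'``, columns ``sigma''``).  The defection row
        is ``1 - coop``.
        """
        coop = np.asarray(coop, dtype=float).ravel()
        if memory is None:
            n_prof = 2**n_players
            memory = max(1, round(np.log(coop.size) / np.log(n_prof)))
        return cls(
            player=player,
            memory=memory,
            n_players=n_players,
            n_actions=2,
            probs=np.vstack([coop, 1.0 - coop]),
        )


def embed_memory(strategy: StrategyTable, memory: int) -> StrategyTable:
    """Lift a memory-``n`` table to memory ``m >= n`` by ignoring older rounds.

    The lifted table is constant across the profiles beyond the original
    window, so every stationary marginal and lag correlation is unchanged.
    """
    if memory < strategy.memory:
        raise ValueError("can only embed into a longer memory")
    if memory == strategy.memory:
        return strategy
    reps = strategy.n_actions ** (
        (memory - strategy.memory) * strategy.n_players
    )
    probs = np.repeat(strategy.probs, reps, axis=1)
    return StrategyTable(
        player=strategy.player,
        memory=memory,
        n_players=strategy.n_players,
        n_actions=strategy.n_actions,
        probs=probs,
    )


def _pd_params(game: Game) -> tuple[float, float, float, float]:
    if game.n_players != 2 or game.n_actions != 2:
        raise ValueError("catalog strategies are for 2-player, 2-action games")
    s1 = game.payoffs[0]
    R, S, T, P = s1[0], s1[1], s1[2], s1[3]
    s2_expect = np.array([R, T, S, P])
    if not np.array_equal(game.payoffs[1], s2_expect):
        raise ValueError("game is not a symmetric (R,S,T,P) Prisoner's Dilemma")
    return float(R), float(S), float(T), float(P)


def example1(game: Game) -> StrategyTable:
    """Memory-two ZD strategy tying ``<s2(t+1) s1(t)>`` to the average payoffs.

    Enforces ``<s2(t+1) s1(t)> = S <s2> + P <s1> - P S``.  Requires
    ``T - P >= P - S``; for the opposite ordering the analogous table with
    these coefficients leaves the probability range and the constructor
    rejects rather than guessing a repair.
    """
    R, S, T, P = _pd_params(game)
    if T - P < P - S:
        raise ValueError(
            "example1 requires T - P >= P - S; "
            f"got T - P = {T - P}, P - S = {P - S}"
        )
    d = (T - P) * (T - S)
    coop = np.array(
        [
            [1 - (R - P) * (R - S) / d, 1, 1 - (R - P) / (T - P), 1 - (R - P) * (P - S) / d],
            [1 - (R - S) / (T - S), 1, 0, 1 - (P - S) / (T - S)],
            [(P - S) * (R - S) / d, 0, (P - S) / (T - P), (P - S) ** 2 / d],
            [0, 0, 0, 0],
        ]
    )
    return StrategyTable.from_coop(coop, player=1, memory=2)


def etft() -> StrategyTable:
    """Extended tit-for-tat: a payoff-independent memory-two ZD strategy.

    Behaves as TFT after unanimous rounds; after a unilateral defection it
    either forgives at random, punishes, or generously cooperates depending
    on how the asymmetry arose.  Enforces a fairness relation between the
    lag-1 payoff correlations and the average payoff difference.
    """
    coop = np.array(
        [
            [1, 1, 1, 1],
            [0.5, 0, 1, 0.5],
            [0.5, 1, 0, 0.5],
            [0, 0, 0, 0],
        ]
    )
    return StrategyTable.from_coop(coop, player=1, memory=2)


def etft2() -> StrategyTable:
    """Type-2 extended tit-for-tat (middle entries of the ETFT rows swapped)."""
    coop = np.array(
        [
            [1, 1, 1, 1],
            [0.5, 1, 0, 0.5],
            [0.5, 0, 1, 0.5],
            [0, 0, 0, 0],
        ]
    )
    return StrategyTable.from_coop(coop, player=1, memory=2)


def ftft(game: Game) -> StrategyTable:
    """Fickle tit-for-tat, requiring ``2R > T + S``.

    May deviate from TFT with finite probability after asymmetric rounds;
    enforces the antisymmetric correlation relation
    ``<s1(t+1)s2(t)> - <s2(t+1)s1(t)> + <s1(t+1)s1(t)> - <s2(t+1)s2(t)> = 0``.
    """
    R, S, T, P = _pd_params(game)
    if not 2 * R > T + S:
        raise ValueError(f"ftft requires 2R > T + S; got 2R = {2 * R}, T + S = {T + S}")
    u = (T + S) / (2 * R)
    coop = np.array(
        [
            [1, 1, 1, 1],
            [0, 1 - u, 1 - u, 1 - P / R],
            [1, u, u, P / R],
            [0, 0, 0, 0],
        ]
    )
    return StrategyTable.from_coop(coop, player=1, memory=2)


def _zss_coop_m1(game: Game) -> tuple[np.ndarray, float]:
    R, S, T, P = _pd_params(game)
    if not (2 * R > T + S and 2 * P < T + S):
        raise ValueError(
            "zero-sum strategies require 2R > T + S and 2P < T + S; got "
            f"2R = {2 * R}, T + S = {T + S}, 2P = {2 * P}"
        )
    A = max(2 * R - (T + S), (T + S) - 2 * P)
    coop = np.array([1 - (2 * R - (T + S)) / A, 1, 0, ((T + S) - 2 * P) / A])
    return coop, A


def zss(game: Game, memory: int = 2) -> StrategyTable:
    """Memory-one zero-sum strategy: fixes ``<s1> + <s2> = T + S``.

    Stored as a memory-two table constant in the older round by default.
    Requires ``2R > T + S`` and ``2P < T + S``; the normalizer is
    ``A = max(2R - (T + S), (T + S) - 2P)``.
    """
    coop, _ = _zss_coop_m1(game)
    table = StrategyTable.from_coop(coop, player=1, memory=1)
    return embed_memory(table, memory)


def ezss(game: Game) -> StrategyTable:
    """Extended (memory-two) zero-sum strategy.

    Fixes the correlation sum
    ``<s1(t+1)s1(t)> + <s1(t+1)s2(t)> + <s2(t+1)s1(t)> + <s2(t+1)s2(t)>``
    at ``(T + S)(<s1> + <s2>)``.  Same feasibility conditions as ZSS.
    """
    R, S, T, P = _pd_params(game)
    _, A = _zss_coop_m1(game)
    # column weights (s1 + s2)(sigma'') / (2R) over profiles
    w = (game.payoffs[0] + game.payoffs[1]) / (2 * R)
    up = (2 * R - (T + S)) / A
    down = ((T + S) - 2 * P) / A
    coop = np.array(
        [
            1 - up * w,
            np.ones(4),
            np.zeros(4),
            down * w,
        ]
    )
    return StrategyTable.from_coop(coop, player=1, memory=2)


_FIXED = {
    "tft": [1, 0, 1, 0],
    "alld": [0, 0, 0, 0],
    "repeat": [1, 1, 0, 0],
}


def fixed_catalog(name: str, memory: int = 2) -> StrategyTable:
    """Payoff-independent catalog: ``tft``, ``tft_atft``, ``alld``, ``repeat``.

    TFT, all-D and Repeat are memory-one rules embedded as memory-two tables;
    TFT-ATFT is genuinely memory-two and deterministic.
    """
    if name == "tft_atft":
        coop = np.array(
            [
                [1, 1, 1, 1],
                [0, 0, 0, 1],
                [0, 1, 0, 1],
                [1, 0, 1, 0],
            ]
        )
        return embed_memory(StrategyTable.from_coop(coop, player=1, memory=2), memory)
    if name not in _FIXED:
        raise KeyError(f"unknown catalog strategy {name!r}")
    table = StrategyTable.from_coop(np.array(_FIXED[name], dtype=float),
                                    player=1, memory=1)
    return embed_memory(table, memory)


def probe(q: float, memory: int = 2) -> StrategyTable:
    """The probe opponent: cooperate with probability ``q`` after mutual
    cooperation and 2/3 otherwise.

    Essentially memory-one; sweeping ``q`` over [0, 1] traces out the linear
    relation a ZD co-player enforces.
    """
    if not 0 <= q <= 1:
        raise ValueError(f"probe probability q = {q} outside [0, 1]")
    coop = np.array([q, 2 / 3, 2 / 3, 2 / 3])
    table = StrategyTable.from_coop(coop, player=2, memory=1)
    return embed_memory(table, memory)


def enforced_relation(name: str, game: Game) -> RelationCoefficients:
    """Coefficient tensor of the linear relation a catalog ZD strategy enforces.

    ``alpha[b, c]`` multiplies ``<s_b(t+1) s_c(t)>`` (with ``s_0 = 1``); the
    enforced relation is ``sum_{b,c} alpha[b,c] <s_b(t+1) s_c(t)> = 0``.
    Coefficients follow the expansion of each strategy's Press-Dyson
    factorization, so they match ``detect_zd`` output up to the canonical
    scaling.
    """
    R, S, T, P = _pd_params(game)
    alpha = np.zeros((3, 3))
    if name == "example1":
        alpha[2, 1] = 1.0
        alpha[2, 0] = -S
        alpha[0, 1] = -P
        alpha[0, 0] = P * S
    elif name in ("etft", "etft2"):
        sign = 1.0 if name == "etft" else -1.0
        alpha[1, 2] = alpha[2, 1] = 1.0
        alpha[1, 1] = alpha[2, 2] = -1.0
        alpha[1, 0] = sign * (T - S)
        alpha[2, 0] = -sign * (T - S)
    elif name == "ftft":
        alpha[1, 2] = 1.0
        alpha[2, 1] = -1.0
        alpha[1, 1] = 1.0
        alpha[2, 2] = -1.0
    elif name == "zss":
        alpha[1, 0] = alpha[2, 0] = 1.0
        alpha[0, 0] = -(T + S)
    elif name == "ezss":
        alpha[1, 1] = alpha[1, 2] = alpha[2, 1] = alpha[2, 2] = 1.0
        alpha[0, 1] = alpha[0, 2] = -(T + S)
    elif name == "tft":
        alpha[1, 0] = 1.0
        alpha[2, 0] = -1.0
    else:
        raise KeyError(f"no enforced relation on record for {name!r}")
    return RelationCoefficients(order=2, n_players=2, alpha=alpha)


#: Built-in strategies with their feasibility preconditions (for the CLI).
CATALOG_NAMES = {
    "example1": "T - P >= P - S",
    "etft": "none",
    "etft2": "none",
    "ftft": "2R > T + S",
    "zss": "2R > T + S and 2P < T + S",
    "ezss": "2R > T + S and 2P < T + S",
    "tft": "none",
    "tft_atft": "none",
    "alld": "none",
    "repeat": "none",
    "probe": "0 <= q <= 1",
}
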