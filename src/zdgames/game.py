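"""Games, action-profile indexing and payoff vectors.

A repeated game has ``N`` players, each choosing an action in ``{1, ..., M}``
every round.  A joint action profile ``sigma = (sigma_1, ..., sigma_N)`` is
stored as a flat index in ``{0, ..., M**N - 1}`` with player 1 most
significant and action 1 before action 2; every other module relies on this
single bijection.  Payoffs are flat vectors over profiles so the machinery is
uniform in ``N`` and ``M``.  The game is undiscounted (discount factor fixed
at 1), which is what makes the stationary-distribution analysis exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Game",
    "make_pd_game",
    "profile_flatten",
    "profile_unflatten",
    "extended_payoff",
]


def profile_flatten(actions: tuple[int, ...], n_actions: int) -> int:
    """Flat index of an action profile.

    ``flat = sum_a (sigma_a - 1) * M**(N - a)``: lexicographic with player 1
    most significant.  Actions are 1-based, the flat index 0-based.
    """
    flat = 0
    for sigma_a in actions:
        if not 1 <= sigma_a <= n_actions:
            raise ValueError(
                f"action {sigma_a} outside {{1..{n_actions}}} in profile {actions}"
            )
        flat = flat * n_actions + (sigma_a - 1)
    return flat


def profile_unflatten(flat: int, n_players: int, n_actions: int) -> tuple[int, ...]:
    """Inverse of :func:`profile_flatten`."""
    if not 0 <= flat < n_actions**n_players:
        raise ValueError(
            f"flat index {flat} outside {{0..{n_actions**n_players - 1}}}"
        )
    actions = []
    for _ in range(n_players):
        actions.append(flat % n_actions + 1)
        flat //= n_actions
    return tuple(reversed(actions))


@dataclass(frozen=True)
class Game:
    """An ``N``-player, ``M``-action one-shot stage game.

    Parameters
    ----------
    n_players : int
        Number of players ``N >= 2``.
    n_actions : int
        Number of actions ``M >= 2`` per player.
    payoffs : tuple of ndarray
        One payoff vector ``s_a`` per player, each of length ``M**N``,
        indexed by flat action profile.
    """

    n_players: int
    n_actions: int
    payoffs: tuple[np.ndarray, ...] = field(repr=False)

    #: The repeated game is undiscounted; this value never changes.
    discount: int = 1

    def __post_init__(self) -> None:
        if self.n_players < 2:
            raise ValueError("need at least 2 players")
        if self.n_actions < 2:
            raise ValueError("need at least 2 actions")
        if self.discount != 1:
            raise ValueError("discount factor is fixed at 1")
        n_profiles = self.n_actions**self.n_players
        if len(self.payoffs) != self.n_players:
            raise ValueError("need one payoff vector per player")
        frozen = []
        for a, s in enumerate(self.payoffs, start=1):
            s = np.asarray(s, dtype=float)
            if s.shape != (n_profiles,):
                raise ValueError(
                    f"payoff vector of player {a} has shape {s.shape}, "
                    f"expected ({n_profiles},)"
                )
            if not np.all(np.isfinite(s)):
                raise ValueError(f"payoff vector of player {a} has non-finite entries")
            s.setflags(write=False)
            frozen.append(s)
        object.__setattr__(self, "payoffs", tuple(frozen))

    @property
    def n_profiles(self) -> int:
        return self.n_actions**self.n_players

    def to_json(self) -> str:
        obj = {
            "n_players": self.n_players,
            "n_actions": self.n_actions,
            "payoffs": {
                str(a + 1): list(s) for a, s in enumerate(self.payoffs)
            },
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Game":
        obj = json.loads(text)
        n = int(obj["n_players"])
        payoffs = tuple(
            np.asarray(obj["payoffs"][str(a)], dtype=float) for a in range(1, n + 1)
        )
        return cls(n_players=n, n_actions=int(obj["n_actions"]), payoffs=payoffs)


def make_pd_game(R: float, S: float, T: float, P: float) -> Game:
    """Two-player Prisoner's Dilemma with payoff ordering ``T > R > P > S``.

    Action 1 is cooperation, action 2 defection.  Profile order is
    ``(1,1), (1,2), (2,1), (2,2)``; player 1 receives ``(R, S, T, P)`` and
    player 2 ``(R, T, S, P)``.
    """
    for name, ok in [("T > R", T > R), ("R > P", R > P), ("P > S", P > S)]:
        if not ok:
            raise ValueError(f"Prisoner's Dilemma ordering violated: {name} fails "
                             f"for (R,S,T,P)=({R},{S},{T},{P})")
    s1 = np.array([R, S, T, P], dtype=float)
    s2 = np.array([R, T, S, P], dtype=float)
    return Game(n_players=2, n_actions=2, payoffs=(s1, s2))


def extended_payoff(game: Game, b: int) -> np.ndarray:
    """Payoff vector ``s_b`` with the constant extension ``s_0 = 1``.

    ``b = 0`` returns the all-ones vector; ``b in {1..N}`` the player's
    payoff vector.
    """
    if not 0 <= b <= game.n_players:
        raise ValueError(f"payoff index {b} outside {{0..{game.n_players}}}")
    if b == 0:
        return np.ones(game.n_profiles)
    return game.payoffs[b - 1]
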