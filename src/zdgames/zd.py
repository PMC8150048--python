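"""Press-Dyson matrices and zero-determinant strategy algebra.

The Press-Dyson (PD) matrix of a strategy is its conditional action
probability table minus the "Repeat" indicator (1 when the candidate action
equals the player's own action of the most recent round).  Akin's lemma in
its memory-``n`` form states that every PD entry-pattern has zero mean under
any stationary distribution of the induced tuple chain.  A strategy is a
memory-``n`` zero-determinant (ZD) strategy when a combination of its PD
matrices lies in the span of the payoff product tensors
``s_{b_1} x ... x s_{b_n}`` (with ``s_0 = 1``); the expansion coefficients
``alpha`` then define a linear relation among stationary payoff correlation
functions that the player enforces unilaterally, whatever the opponents do.

This module computes PD matrices, checks the lemma, detects membership in
the ZD class by least-squares projection, evaluates enforced relations and
constructs strategy tables from target relation coefficients, including an
exact feasibility analysis over the one remaining scale freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .game import Game, extended_payoff, profile_unflatten

if TYPE_CHECKING:  # avoid a circular import; catalog imports this module
    from .catalog import StrategyTable

__all__ = [
    "PDMatrix",
    "RelationCoefficients",
    "DetectionResult",
    "ConstructionResult",
    "pd_matrix",
    "akin_residual",
    "payoff_basis",
    "PayoffBasis",
    "detect_zd",
    "evaluate_relation",
    "construct_from_alpha",
]

DETECTION_TOL = 1e-10


def _repeat_indicator(action: int, player: int, order: int,
                      n_players: int, n_actions: int) -> np.ndarray:
    """1 where the player's own action in the newest profile equals ``action``."""
    P = n_actions**n_players
    n_hist = P**order
    newest = np.arange(n_hist) // P ** (order - 1)
    own = np.array(
        [profile_unflatten(f, n_players, n_actions)[player - 1] for f in range(P)]
    )
    return (own[newest] == action).astype(float)


@dataclass(frozen=True)
class PDMatrix:
    """One action-slice of a strategy's Press-Dyson matrix/tensor."""

    player: int
    action: int
    order: int
    n_players: int
    n_actions: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("Press-Dyson entries must lie in [-1, 1]")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


def pd_matrix(strategy: "StrategyTable", action: int) -> PDMatrix:
    """Press-Dyson matrix slice for one own action.

    Subtracts the Repeat indicator (on the player's most recent own action)
    from the conditional probability table; the result is mean-zero under
    every stationary distribution in which the owner plays this strategy.
    """
    if not 1 <= action <= strategy.n_actions:
        raise ValueError(
            f"action {action} outside {{1..{strategy.n_actions}}}"
        )
    ind = _repeat_indicator(
        action, strategy.player, strategy.memory,
        strategy.n_players, strategy.n_actions,
    )
    return PDMatrix(
        player=strategy.player,
        action=action,
        order=strategy.memory,
        n_players=strategy.n_players,
        n_actions=strategy.n_actions,
        values=strategy.probs[action - 1] - ind,
    )


def akin_residual(pd: PDMatrix, dist) -> float:
    """Contraction ``sum_h pd(h) * P_st(h)``.

    Zero (within 1e-10) whenever ``dist`` is stationary for a chain in
    which the matrix's owner plays the corresponding strategy; generally
    nonzero otherwise, so the check is not vacuous.
    """
    if (pd.order, pd.n_players, pd.n_actions) != (
        dist.order, dist.n_players, dist.n_actions
    ):
        raise ValueError(
            "Press-Dyson matrix and distribution dimensions do not match"
        )
    return float(np.dot(pd.values, dist.probs))


@dataclass(frozen=True)
class RelationCoefficients:
    """Coefficients ``alpha`` of a linear relation among correlation functions.

    ``alpha`` has shape ``(N+1,)*n``; entry ``alpha[b_0, ..., b_{n-1}]``
    multiplies the moment with ``s_{b_0}`` on the most recent round of the
    window.  Defined only up to an overall scale (absorbed in the per-action
    weights); ``canonical()`` fixes it.
    """

    order: int
    n_players: int
    alpha: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (self.n_players + 1,) * self.order:
            raise ValueError(
                f"alpha has shape {a.shape}, expected "
                f"{(self.n_players + 1,) * self.order}"
            )
        a.setflags(write=False)
        object.__setattr__(self, "alpha", a)

    @property
    def degenerate(self) -> bool:
        """True when no payoff actually enters the relation.

        All-zero alpha defines nothing; alpha supported only on the
        all-constant index would assert ``0 = alpha_{0...0}``, a
        contradiction.
        """
        flat = self.alpha.ravel()
        scale = np.max(np.abs(flat))
        if scale == 0:
            return True
        nz = np.abs(flat) > 1e-12 * scale
        return not np.any(nz[1:])

    def canonical(self) -> "RelationCoefficients":
        """Scale so max |entry| = 1 and the first nonzero entry is positive."""
        flat = self.alpha.ravel()
        scale = np.max(np.abs(flat))
        if scale == 0:
            return self
        first = flat[np.abs(flat) > 1e-12 * scale][0]
        return RelationCoefficients(
            order=self.order,
            n_players=self.n_players,
            alpha=self.alpha / (scale * np.sign(first)),
        )


@dataclass(frozen=True)
class PayoffBasis:
    """Outer-product payoff tensors spanning the ZD relation space."""

    order: int
    n_players: int
    index_tuples: tuple[tuple[int, ...], ...]
    vectors: np.ndarray = field(repr=False)  # shape ((N+1)**n, M**(n*N))
    rank: int


def payoff_basis(game: Game, order: int) -> PayoffBasis:
    """The ``(N+1)**n`` payoff product tensors over history tuples.

    Vector ``(b_0, ..., b_{n-1})`` (lexicographic order, index 0 the most
    recent round) has entry ``s_{b_0}(sigma^(-1)) ... s_{b_{n-1}}(sigma^(-n))``
    at each history.  Also reports the rank of the span, which bounds the
    dimension of the ZD strategy space.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    from .markov import _check_size

    P = game.n_profiles
    n_hist = P**order
    _check_size(n_hist)
    hist = np.arange(n_hist)
    profiles = [(hist // P ** (order - 1 - j)) % P for j in range(order)]
    N = game.n_players
    tuples = list(itertools.product(range(N + 1), repeat=order))
    vectors = np.empty((len(tuples), n_hist))
    for i, btuple in enumerate(tuples):
        v = np.ones(n_hist)
        for j, b in enumerate(btuple):
            v = v * extended_payoff(game, b)[profiles[j]]
        vectors[i] = v
    rank = int(np.linalg.matrix_rank(vectors))
    return PayoffBasis(
        order=order,
        n_players=N,
        index_tuples=tuple(tuples),
        vectors=vectors,
        rank=rank,
    )


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of testing a strategy for ZD membership."""

    is_zd: bool
    alpha: RelationCoefficients | None
    c: np.ndarray
    residual: float
    basis_rank: int
    degenerate: bool = False
    non_unique: bool = False


def detect_zd(strategy: "StrategyTable", game: Game,
              tol: float = DETECTION_TOL) -> DetectionResult:
    """Decide whether a strategy is memory-``n`` ZD and recover its relation.

    For binary actions the normalization constraint collapses the per-action
    weights to a single scale, so the test reduces to projecting the
    cooperation PD matrix onto the payoff-tensor span: the strategy is ZD
    iff the relative projection residual is at most ``tol`` and the
    recovered ``alpha`` is non-degenerate.  For more than two actions the
    joint homogeneous system in (per-action weights, alpha) is solved with
    the last weight gauged to zero.
    """
    if strategy.n_players != game.n_players or strategy.n_actions != game.n_actions:
        raise ValueError("strategy dimensions do not match the game")
    basis = payoff_basis(game, strategy.memory)
    B = basis.vectors  # (K, H)
    K = B.shape[0]
    non_unique = basis.rank < K
    shape = (game.n_players + 1,) * strategy.memory

    if game.n_actions == 2:
        t_hat = pd_matrix(strategy, 1).values
        norm = np.linalg.norm(t_hat)
        coeffs, *_ = np.linalg.lstsq(B.T, t_hat, rcond=None)
        resid = np.linalg.norm(B.T @ coeffs - t_hat)
        if norm > 0:
            resid /= norm
        alpha = RelationCoefficients(
            order=strategy.memory, n_players=game.n_players,
            alpha=coeffs.reshape(shape),
        )
        degenerate = norm == 0 or alpha.degenerate
        return DetectionResult(
            is_zd=bool(resid <= tol and not degenerate),
            alpha=None if alpha.degenerate else alpha.canonical(),
            c=np.array([1.0, 0.0]),
            residual=float(resid),
            basis_rank=basis.rank,
            degenerate=degenerate,
            non_unique=non_unique,
        )

    # M > 2: solve sum_a c_a T_hat(a) - B^T alpha = 0 with gauge c_M = 0.
    M = game.n_actions
    t_hats = np.stack([pd_matrix(strategy, a).values for a in range(1, M)])
    A = np.hstack([t_hats.T, -B.T])  # (H, (M-1) + K)
    _, s, vh = np.linalg.svd(A)
    small = s <= max(tol, s[0] * 1e-14) if s.size else np.array([], bool)
    null = vh[len(s) - int(np.sum(small)):] if np.any(small) else vh[:0]
    for vec in null:
        c_part, a_part = vec[: M - 1], vec[M - 1:]
        alpha = RelationCoefficients(
            order=strategy.memory, n_players=game.n_players,
            alpha=a_part.reshape(shape),
        )
        if not alpha.degenerate and np.max(np.abs(c_part)) > tol:
            c = np.append(c_part, 0.0)
            resid = float(np.linalg.norm(A @ vec))
            return DetectionResult(
                is_zd=True, alpha=alpha.canonical(), c=c,
                residual=resid, basis_rank=basis.rank,
                non_unique=non_unique,
            )
    return DetectionResult(
        is_zd=False, alpha=None, c=np.zeros(M), residual=float("inf"),
        basis_rank=basis.rank, non_unique=non_unique,
    )


def evaluate_relation(alpha: RelationCoefficients, dist, game: Game) -> float:
    """Value of ``sum alpha[b] * <product moment>`` under a distribution.

    At most 1e-10 in magnitude when ``alpha`` comes from a ZD strategy that
    is a player of the chain generating ``dist``.
    """
    from .markov import lag_correlations

    if alpha.order != dist.order:
        raise ValueError(
            f"relation order {alpha.order} does not match distribution "
            f"order {dist.order}"
        )
    moments = lag_correlations(dist, game, lags=alpha.order - 1)
    return float(np.sum(alpha.alpha * moments))


@dataclass(frozen=True)
class ConstructionResult:
    """Outcome of building a strategy table from target relation coefficients."""

    feasible: bool
    strategy: "StrategyTable | None"
    w: float
    w_interval: tuple[float, float]
    #: histories whose probability constraint pins the scale to zero
    violations: tuple[int, ...] = ()


def construct_from_alpha(alpha: RelationCoefficients, game: Game,
                         player: int = 1) -> ConstructionResult:
    """Construct a binary-action ZD strategy enforcing a target relation.

    Forms ``D = sum_b alpha[b] * basis tensor`` and the candidate table
    ``T(1|h) = Repeat(h) + w * D(h)``; the admissible scalings ``w`` are the
    exact intersection of the per-entry intervals keeping every probability
    in [0, 1].  Zero is always admissible (it gives Repeat, which enforces
    nothing), so the relation is enforceable iff the interval contains a
    nonzero ``w``; the returned table uses the endpoint of maximal
    magnitude, the convention under which the catalog strategies are exactly
    recovered from their own relations.
    """
    from .catalog import StrategyTable

    if game.n_actions != 2:
        raise ValueError("construction is implemented for binary actions only")
    if alpha.degenerate:
        raise ValueError("degenerate relation coefficients: no payoff enters")
    if alpha.n_players != game.n_players:
        raise ValueError("relation and game player counts differ")
    basis = payoff_basis(game, alpha.order)
    D = basis.vectors.T @ alpha.alpha.ravel()
    r = _repeat_indicator(1, player, alpha.order, game.n_players, game.n_actions)

    scale = np.max(np.abs(D))
    if scale == 0:
        raise ValueError("relation coefficients produce an identically zero "
                         "target matrix")
    w_lo, w_hi = -np.inf, np.inf
    lo_pins, hi_pins = [], []
    for h in range(len(D)):
        d = D[h]
        if abs(d) <= 1e-14 * scale:
            continue
        bounds = sorted(((0 - r[h]) / d, (1 - r[h]) / d))
        if bounds[0] > w_lo:
            w_lo, lo_pins = bounds[0], [h]
        elif bounds[0] == w_lo:
            lo_pins.append(h)
        if bounds[1] < w_hi:
            w_hi, hi_pins = bounds[1], [h]
        elif bounds[1] == w_hi:
            hi_pins.append(h)
    # r is 0/1 so w = 0 is always inside the (possibly degenerate) interval
    w = w_lo if abs(w_lo) > abs(w_hi) else w_hi
    if w == 0:
        return ConstructionResult(
            feasible=False, strategy=None, w=0.0,
            w_interval=(w_lo, w_hi),
            violations=tuple(sorted(set(lo_pins + hi_pins))),
        )
    coop = np.clip(r + w * D, 0.0, 1.0)
    table = StrategyTable.from_coop(
        coop, player=player, memory=alpha.order, n_players=game.n_players
    )
    return ConstructionResult(
        feasible=True, strategy=table, w=float(w), w_interval=(w_lo, w_hi)
    )
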