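"""Strategy file readers/writers and the random-fixture generator.

Two on-disk formats are supported:

* JSON: ``{"name", "player", "memory", "n_players", "n_actions",
  "probs": {"1": [...], "2": [...]}}`` with one probability list per own
  action over flat history indices (most recent profile most significant).
* CSV: header ``history,action_1,...,action_M``, one row per history.  The
  history label concatenates the action digits of each profile, most recent
  profile first, profiles separated by ``;`` (e.g. ``12;21``).  Decimal
  separator is ``.``.

Floats are serialized with shortest round-trip ``repr``, so
``read(write(s))`` reproduces every probability exactly.  On read, rows
whose probabilities sum to within 1e-9 of 1 are renormalized with a logged
warning; larger violations are rejected naming the offending history.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from .catalog import StrategyTable
from .game import profile_unflatten
from .markov import MAX_STATES

__all__ = ["read_strategy", "write_strategy", "random_strategy"]

logger = logging.getLogger(__name__)

_ROW_TOL = 1e-9


def _history_label(h: int, memory: int, n_players: int, n_actions: int) -> str:
    P = n_actions**n_players
    parts = []
    for k in range(memory):
        f = (h // P ** (memory - 1 - k)) % P
        parts.append("".join(str(a) for a in profile_unflatten(f, n_players, n_actions)))
    return ";".join(parts)


def _validate_rows(probs: np.ndarray, memory: int, n_players: int,
                   n_actions: int) -> np.ndarray:
    if np.any(probs < 0) or np.any(probs > 1):
        h = int(np.argmax((probs < 0) | (probs > 1), axis=None)) % probs.shape[1]
        raise ValueError(
            "probability out of [0, 1] at history "
            f"{_history_label(h, memory, n_players, n_actions)}"
        )
    sums = probs.sum(axis=0)
    off = np.abs(sums - 1)
    worst = int(np.argmax(off))
    if off[worst] > _ROW_TOL:
        raise ValueError(
            f"probabilities for history "
            f"{_history_label(worst, memory, n_players, n_actions)} "
            f"sum to {sums[worst]!r}, not 1"
        )
    # representation noise (a few ulp) is left untouched so that writing and
    # re-reading a table is bit-exact; genuine violations are renormalized
    if off[worst] > 1e-13:
        logger.warning(
            "renormalizing %d history rows with probability sums off by up to %.3g",
            int(np.sum(off > 1e-13)), off[worst],
        )
        probs = probs / sums
    return probs


def write_strategy(strategy: StrategyTable, path, fmt: str | None = None,
                   name: str = "") -> None:
    """Write a strategy table as JSON or CSV (inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "json"
    if fmt == "json":
        obj = {
            "name": name,
            "player": strategy.player,
            "memory": strategy.memory,
            "n_players": strategy.n_players,
            "n_actions": strategy.n_actions,
            "probs": {
                str(a + 1): [float(x) for x in row]
                for a, row in enumerate(strategy.probs)
            },
        }
        path.write_text(json.dumps(obj, indent=1))
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["history"] + [f"action_{a}" for a in range(1, strategy.n_actions + 1)]
            )
            for h in range(strategy.n_histories):
                label = _history_label(
                    h, strategy.memory, strategy.n_players, strategy.n_actions
                )
                w.writerow([label] + [repr(float(x)) for x in strategy.probs[:, h]])
    else:
        raise ValueError(f"unknown strategy file format {fmt!r}")


def read_strategy(path) -> StrategyTable:
    """Read and validate a strategy table from a JSON or CSV file."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    return _read_json(path)


def _read_json(path: Path) -> StrategyTable:
    try:
        obj = json.loads(path.read_text())
        memory = int(obj["memory"])
        n_players = int(obj["n_players"])
        n_actions = int(obj["n_actions"])
        player = int(obj.get("player", 1))
        probs = np.array(
            [
                [float(x) for x in obj["probs"][str(a)]]
                for a in range(1, n_actions + 1)
            ],
            dtype=float,
        )
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed strategy file {path}: {exc}") from exc
    n_hist = n_actions ** (memory * n_players)
    if probs.shape != (n_actions, n_hist):
        raise ValueError(
            f"{path}: expected {n_hist} probabilities per action for "
            f"memory={memory}, N={n_players}, M={n_actions}; got shape "
            f"{probs.shape}"
        )
    probs = _validate_rows(probs, memory, n_players, n_actions)
    return StrategyTable(
        player=player, memory=memory, n_players=n_players,
        n_actions=n_actions, probs=probs,
    )


def _read_csv(path: Path) -> StrategyTable:
    with path.open() as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty strategy file") from None
        if not header or header[0] != "history":
            raise ValueError(f"{path}: first CSV column must be 'history'")
        n_actions = len(header) - 1
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: no history rows")
    first = rows[0][0].split(";")
    memory = len(first)
    n_players = len(first[0])
    n_hist = n_actions ** (memory * n_players)
    if len(rows) != n_hist:
        raise ValueError(
            f"{path}: {len(rows)} history rows, expected {n_hist} for "
            f"memory={memory}, N={n_players}, M={n_actions}"
        )
    probs = np.empty((n_actions, n_hist))
    for h, row in enumerate(rows):
        expect = _history_label(h, memory, n_players, n_actions)
        if row[0] != expect:
            raise ValueError(
                f"{path}: row {h + 2} labelled {row[0]!r}, expected {expect!r}"
            )
        try:
            probs[:, h] = [float(x) for x in row[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}: bad probability in row {h + 2}: {exc}") from exc
    probs = _validate_rows(probs, memory, n_players, n_actions)
    return StrategyTable(
        player=1, memory=memory, n_players=n_players,
        n_actions=n_actions, probs=probs,
    )


def random_strategy(n_players: int, n_actions: int, memory: int, seed: int,
                    mode: str = "interior") -> StrategyTable:
    """Seeded random strategy table for tests and sweeps.

    ``interior`` draws each history row from the flat Dirichlet (all action
    probabilities strictly positive, so any pairing gives an irreducible
    chain); ``sparse`` draws a random deterministic strategy (each row a
    simplex vertex).
    """
    n_hist = n_actions ** (memory * n_players)
    if n_hist > MAX_STATES:
        raise ValueError(
            f"history space of size {n_hist} exceeds the supported maximum "
            f"{MAX_STATES}"
        )
    rng = np.random.default_rng(seed)
    if mode == "interior":
        probs = rng.dirichlet(np.ones(n_actions), size=n_hist).T
    elif mode == "sparse":
        probs = np.zeros((n_actions, n_hist))
        probs[rng.integers(n_actions, size=n_hist), np.arange(n_hist)] = 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StrategyTable(
        player=1, memory=memory, n_players=n_players,
        n_actions=n_actions, probs=probs,
    )
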