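"""Independent closed-form oracles used across the test modules.

Each function builds the Press-Dyson cooperation slice of a catalog
strategy directly from its payoff factorization by explicit loops over the
16 history pairs — no shared code with the package's basis machinery.
"""

import numpy as np

import zdgames as z

PROFILES = [(1, 1), (1, 2), (2, 1), (2, 2)]


def _s(game, a, profile):
    return float(game.payoffs[a - 1][z.profile_flatten(profile, 2)])


def closed_form_pd(name, game):
    """16-vector of the cooperation PD entries from the printed factorization."""
    R, S, T, P = (float(game.payoffs[0][i]) for i in range(4))
    A = max(2 * R - (T + S), (T + S) - 2 * P)
    out = np.empty(16)
    for i, sp in enumerate(PROFILES):  # sigma' (last round)
        for j, spp in enumerate(PROFILES):  # sigma'' (round before)
            s1p, s2p = _s(game, 1, sp), _s(game, 2, sp)
            s1pp, s2pp = _s(game, 1, spp), _s(game, 2, spp)
            if name == "example1":
                v = -(s2p - P) * (s1pp - S) / ((T - P) * (T - S))
            elif name == "etft":
                v = ((s1p - s2p) * (s2pp - s1pp)
                     + (T - S) * (s1p - s2p)) / (2 * (T - S) ** 2)
            elif name == "etft2":
                v = -((s1p - s2p) * (s2pp - s1pp)
                      - (T - S) * (s1p - s2p)) / (2 * (T - S) ** 2)
            elif name == "ftft":
                v = (s1p * s2pp - s2p * s1pp
                     + s1p * s1pp - s2p * s2pp) / (2 * R * (T - S))
            elif name == "zss":
                v = -(s1p + s2p - (T + S)) / A
            elif name == "ezss":
                v = -(s1p + s2p - (T + S)) * (s1pp + s2pp) / (2 * R * A)
            else:
                raise KeyError(name)
            out[4 * i + j] = v
    return out


def brute_force_basis(game):
    """The 9 payoff product tensors, assembled by explicit loops."""
    vecs = np.empty((9, 16))
    payoffs = {0: lambda p: 1.0, 1: lambda p: _s(game, 1, p),
               2: lambda p: _s(game, 2, p)}
    k = 0
    for b in range(3):
        for c in range(3):
            for i, sp in enumerate(PROFILES):
                for j, spp in enumerate(PROFILES):
                    vecs[k, 4 * i + j] = payoffs[b](sp) * payoffs[c](spp)
            k += 1
    return vecs


def power_iteration(tm, members, steps=100_000):
    """Stationary distribution by repeated application of the transition
    operator, started uniformly inside one recurrent class."""
    dense = tm.dense()
    p = np.zeros(tm.n_states)
    p[members] = 1.0 / len(members)
    for _ in range(steps):
        p = p @ dense
    return p
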