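import numpy as np
import pytest

import zdgames as z

#: payoff sets satisfying T > R > P > S plus the feasibility conditions
#: used by the payoff-dependent catalog strategies
PAYOFF_GRID = [
    (3.0, 0.0, 5.0, 1.0),
    (4.0, -1.0, 6.0, 0.0),
    (3.0, 0.5, 4.0, 1.0),
    (10.0, 1.0, 12.0, 3.0),
]

ZD_CATALOG = ["example1", "etft", "etft2", "ftft", "zss", "ezss"]


def catalog_strategy(name, game):
    """Instantiate a catalog strategy at the given game's payoffs."""
    if name == "etft":
        return z.etft()
    if name == "etft2":
        return z.etft2()
    if name == "example1":
        return z.example1(game)
    if name == "ftft":
        return z.ftft(game)
    if name == "zss":
        return z.zss(game)
    if name == "ezss":
        return z.ezss(game)
    return z.fixed_catalog(name)


@pytest.fixture(scope="session")
def pd_game():
    """The benchmark Prisoner's Dilemma (R,S,T,P) = (3,0,5,1)."""
    return z.make_pd_game(3, 0, 5, 1)


@pytest.fixture(scope="session")
def uniform_random_table():
    """Both actions with probability 1/2 after every memory-two history."""
    return z.StrategyTable.from_coop(np.full(16, 0.5), player=1, memory=2)


def stationary_per_class(strategy, opponent, game):
    """All (class index, stationary distribution) pairs for a pairing."""
    tm = z.build_transition([strategy, opponent], game)
    classes = z.recurrent_classes(tm)
    return tm, [
        (i, z.stationary(tm, i, classes=classes)) for i in range(len(classes))
    ]
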