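import itertools

import pytest

from paretopaths import FixtureSpec, hand_fixtures, make_landscape


@pytest.fixture()
def hand():
    return hand_fixtures()


@pytest.fixture()
def f1(hand):
    return hand["F1"]


@pytest.fixture()
def f2(hand):
    return hand["F2"]


@pytest.fixture()
def f3(hand):
    return hand["F3"]


def small_grid(seed: int, grid_n: int = 3, n_wetlands: int = 2):
    """A tiny generated landscape (9 nodes at the default size)."""
    return make_landscape(FixtureSpec(seed=seed, grid_n=grid_n, n_wetlands=n_wetlands))


def wetland_od_pairs(net):
    """One (origin, destination) node pair per ordered wetland pair."""
    pairs = []
    for w1, w2 in itertools.permutations(sorted(net.wetlands), 2):
        pairs.append((net.wetland_entrances(w1)[0], net.wetland_entrances(w2)[0]))
    return pairs
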