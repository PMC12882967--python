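"""Shared fixtures: quick constructors for windows and networks."""

from __future__ import annotations

import datetime as dt
import itertools

import numpy as np
import pytest

from swarmnet.netbuild import SwarmNetwork, build_network
from swarmnet.obs_io import ObservationWindow, SwarmKey

DATE = dt.date(2021, 3, 15)


def make_windows(*species_sets, site="S1", swarm="sw1", date=DATE):
    """Observation windows for one swarm-day from bare species sets."""
    return [
        ObservationWindow(site, swarm, date, i + 1, frozenset(s))
        for i, s in enumerate(species_sets)
    ]


def net_from_windows(*species_sets, site="S1", swarm="sw1", date=DATE):
    return build_network(make_windows(*species_sets, site=site, swarm=swarm, date=date))


def net_from_edges(edges, *, isolated=(), site="S1", swarm="sw1", date=DATE):
    """Network with the given unit-weight edges plus optional isolated nodes."""
    weights = {tuple(sorted(e)): 1 for e in edges}
    nodes = {v for e in edges for v in e} | set(isolated)
    return SwarmNetwork(
        key=SwarmKey(site, swarm, date),
        nodes=frozenset(nodes),
        weights=dict(sorted(weights.items())),
        n_windows=1,
    )


def random_network(rng: np.random.Generator, *, max_nodes=10, swarm="sw", date=DATE):
    """Random binary network with at least one edge."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"sp{i}" for i in range(n)]
    pairs = list(itertools.combinations(names, 2))
    p = float(rng.uniform(0.15, 0.9))
    edges = [e for e in pairs if rng.random() < p]
    if not edges:
        edges = [pairs[int(rng.integers(len(pairs)))]]
    return net_from_edges(edges, isolated=names, swarm=f"{swarm}{rng.integers(1e6)}")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
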