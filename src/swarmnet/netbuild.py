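"""Per-swarm-day co-occurrence networks (gambit of the group).

All species seen together within a single five-minute window are taken
to be associating reciprocally, so every window contributes a clique on
its species set.  Edge weights count the number of windows in which a
pair co-occurred; the binary network is the support of the weight map.

Species that never co-occur with another remain in the node set as
isolated nodes: network size is the species richness at the swarm, and
such species carry degree 0 into the degree distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .obs_io import ObservationWindow, SwarmKey

Pair = tuple[str, str]

#: GraphML / DataFrame attribute name for edge weights.
WEIGHT_ATTR = "n_windows_shared"


def _ordered(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SwarmNetwork:
    """One swarm-day network: node set plus binary and weighted edges."""

    key: SwarmKey
    nodes: frozenset[str]
    weights: dict[Pair, int]
    n_windows: int

    @property
    def binary_edges(self) -> set[Pair]:
        return set(self.weights)

    @property
    def size(self) -> int:
        return len(self.nodes)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.weights if node in e)

    def strength(self, node: str) -> int:
        """Weighted degree: summed co-occurrence counts over incident edges."""
        return sum(w for e, w in self.weights.items() if node in e)


def build_network(windows: Sequence[ObservationWindow]) -> SwarmNetwork:
    """Build the co-occurrence network for the windows of one swarm-day.

    Every unordered pair of species within each window gains +1 weight;
    single-species windows simply contribute isolated nodes.
    """
    if not windows:
        raise ValidationError("cannot build a network from zero windows")
    keys = {w.key for w in windows}
    if len(keys) != 1:
        raise ValidationError(f"windows span multiple swarm-days: {sorted(keys)}")
    nodes: set[str] = set()
    weights: dict[Pair, int] = {}
    for w in windows:
        nodes |= w.species
        for pair in combinations(sorted(w.species), 2):
            weights[pair] = weights.get(pair, 0) + 1
    return SwarmNetwork(
        key=windows[0].key,
        nodes=frozenset(nodes),
        weights=dict(sorted(weights.items())),
        n_windows=len(windows),
    )


def edge_list(net: SwarmNetwork, *, weighted: bool = True) -> pd.DataFrame:
    """Edge list as a table (species_1 < species_2, rows sorted).

    Binary output emits weight 1 for every present edge.
    """
    rows = [
        (a, b, w if weighted else 1)
        for (a, b), w in sorted(net.weights.items())
    ]
    return pd.DataFrame(rows, columns=["species_1", "species_2", "weight"])


def to_graph(net: SwarmNetwork, *, weighted: bool = True) -> nx.Graph:
    """networkx view of the network (isolated nodes included)."""
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    for (a, b), w in sorted(net.weights.items()):
        if weighted:
            g.add_edge(a, b, **{WEIGHT_ATTR: w})
        else:
            g.add_edge(a, b)
    return g


def write_graphml(net: SwarmNetwork, path: str | Path) -> None:
    nx.write_graphml(to_graph(net), str(path))


def build_all(
    groups: dict[SwarmKey, list[ObservationWindow]],
) -> list[SwarmNetwork]:
    """Build one network per swarm-day, in deterministic key order."""
    return [build_network(ws) for _, ws in sorted(groups.items())]


def total_weight(net: SwarmNetwork) -> int:
    return sum(net.weights.values())
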