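"""The five per-network summary metrics.

size
    Species richness at the swarm (isolated nodes count).
mean normalized degree
    Each species' interspecific connection count divided by the number
    of available partners (size − 1), averaged over species.
mean weighted degree
    Each species' summed edge weights (co-occurrence window counts),
    averaged over species.  The only metric that uses the weighted
    network.
global clustering (transitivity)
    3 × triangles / connected triples, on the binary graph.
skewness
    Moment skewness g1 of the normalized-degree distribution
    (population moments, no small-sample correction).  Zero-variance
    distributions — complete networks — are assigned skewness 0 rather
    than dropped, since fully connected groups are common at small
    swarms.

Degenerate cases yield NaN ("undefined") rather than an arbitrary
number: size-1 networks have no degree distribution at all; skewness
needs ≥3 species; clustering needs at least one connected triple.
Undefined cells are excluded listwise per-response by the model layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import SwarmNetwork, to_graph

METRIC_COLUMNS = [
    "size",
    "mean_norm_degree",
    "mean_weighted_degree",
    "clustering",
    "skewness",
]


@dataclass(frozen=True)
class NetworkMetrics:
    size: int
    mean_norm_degree: float  # NaN when undefined
    mean_weighted_degree: float
    clustering: float
    skewness: float
    n_windows: int


def network_size(net: SwarmNetwork) -> int:
    """Number of species attending the swarm (isolated nodes included)."""
    return len(net.nodes)


def _normalized_degrees(net: SwarmNetwork) -> np.ndarray:
    n = len(net.nodes)
    degs = np.array([net.degree(v) for v in sorted(net.nodes)], dtype=float)
    return degs / (n - 1)


def mean_normalized_degree(net: SwarmNetwork) -> float:
    """Mean over species of degree/(size−1); NaN for size-1 networks."""
    if len(net.nodes) < 2:
        return math.nan
    return float(_normalized_degrees(net).mean())


def mean_weighted_degree(net: SwarmNetwork) -> float:
    """Mean over species of summed incident edge weights."""
    if not net.nodes:
        return math.nan
    return float(np.mean([net.strength(v) for v in sorted(net.nodes)]))


def global_clustering(net: SwarmNetwork) -> float:
    """Transitivity of the binary graph; NaN when no connected triple exists."""
    g = to_graph(net, weighted=False)
    n_triples = sum(d * (d - 1) // 2 for _, d in g.degree())
    if n_triples == 0:
        return math.nan
    return float(nx.transitivity(g))


def degree_skewness(net: SwarmNetwork) -> float:
    """Moment skewness g1 of normalized degrees; 0 if variance is 0; NaN if size < 3."""
    if len(net.nodes) < 3:
        return math.nan
    x = _normalized_degrees(net)
    if np.ptp(x) == 0.0:
        return 0.0
    return float(stats.skew(x, bias=True))


def compute_metrics(net: SwarmNetwork) -> NetworkMetrics:
    size = network_size(net)
    if size == 1:
        # No degree distribution: all four degree-based metrics undefined.
        return NetworkMetrics(1, math.nan, math.nan, math.nan, math.nan, net.n_windows)
    return NetworkMetrics(
        size=size,
        mean_norm_degree=mean_normalized_degree(net),
        mean_weighted_degree=mean_weighted_degree(net),
        clustering=global_clustering(net),
        skewness=degree_skewness(net),
        n_windows=net.n_windows,
    )


def metrics_table(nets: Sequence[SwarmNetwork]) -> pd.DataFrame:
    """One row per network: swarm key columns, five metrics, n_windows.

    Undefined metrics are emitted as NaN (missing cells in CSV output).
    """
    rows = []
    for net in sorted(nets, key=lambda n: n.key):
        m = compute_metrics(net)
        rows.append(
            {
                "site_id": net.key.site_id,
                "swarm_id": net.key.swarm_id,
                "date": net.key.date.isoformat(),
                "size": m.size,
                "mean_norm_degree": m.mean_norm_degree,
                "mean_weighted_degree": m.mean_weighted_degree,
                "clustering": m.clustering,
                "skewness": m.skewness,
                "n_windows": m.n_windows,
            }
        )
    return pd.DataFrame(rows)
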