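"""Pairwise network dissimilarity and its turnover / rewiring partition.

For two networks with interaction (binary edge) sets E1 and E2, let
a = |E1 ∩ E2|, b = |E1 \\ E2|, c = |E2 \\ E1|.  Whittaker dissimilarity

    βWN = (a + b + c) / ((2a + b + c) / 2) − 1,

algebraically (b + c) / (2a + b + c), measures overall interaction
dissimilarity in [0, 1].  The additive partition attributes it to two
sources: βOS ("rewiring") is the same index computed on the sub-edge
sets induced by the species present in BOTH networks, and
βST = βWN − βOS is the part due to species turnover.  When neither
induced subgraph has any edge, βOS is 0 and all dissimilarity is
turnover.

Interactions are binary: co-occurrence in at least one window; weights
never enter the dissimilarity.  Networks without any edge (isolated
nodes only) cannot be compared and are skipped with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .netbuild import Pair, SwarmNetwork
from .obs_io import SiteEnvironment, SwarmKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BetaPartition:
    """βWN = βST + βOS for one unordered pair of swarm-day networks."""

    key_1: SwarmKey
    key_2: SwarmKey
    beta_wn: float
    beta_st: float
    beta_os: float
    shared_interactions: int  # a
    unique_1: int  # b
    unique_2: int  # c


def whittaker_beta(a: int, b: int, c: int) -> float:
    """Whittaker dissimilarity from shared / unique interaction counts."""
    if min(a, b, c) < 0:
        raise ValidationError("interaction counts must be non-negative")
    total = a + b + c
    if total == 0:
        raise ValidationError(
            "undefined comparison: no interactions in either network"
        )
    return total / ((2 * a + b + c) / 2) - 1


def _induced_edges(edges: set[Pair], shared_nodes: frozenset[str]) -> set[Pair]:
    return {e for e in edges if e[0] in shared_nodes and e[1] in shared_nodes}


def partition_pair(net_1: SwarmNetwork, net_2: SwarmNetwork) -> BetaPartition:
    """Partition the dissimilarity of one network pair into βST + βOS."""
    e1, e2 = net_1.binary_edges, net_2.binary_edges
    if not e1 or not e2:
        raise ValidationError("both networks must have at least one edge")
    a = len(e1 & e2)
    b = len(e1 - e2)
    c = len(e2 - e1)
    beta_wn = whittaker_beta(a, b, c)

    shared_nodes = net_1.nodes & net_2.nodes
    s1 = _induced_edges(e1, shared_nodes)
    s2 = _induced_edges(e2, shared_nodes)
    if not s1 and not s2:
        beta_os = 0.0
    else:
        beta_os = whittaker_beta(len(s1 & s2), len(s1 - s2), len(s2 - s1))
    return BetaPartition(
        key_1=net_1.key,
        key_2=net_2.key,
        beta_wn=beta_wn,
        beta_st=beta_wn - beta_os,
        beta_os=beta_os,
        shared_interactions=a,
        unique_1=b,
        unique_2=c,
    )


def eligible(net: SwarmNetwork) -> bool:
    return bool(net.weights)


def all_pairs(nets: Sequence[SwarmNetwork]) -> list[BetaPartition]:
    """Partition every unordered pair of eligible networks.

    n eligible networks yield n(n−1)/2 records in deterministic
    (key-sorted) order.  Edgeless networks are dropped with a log line.
    """
    usable = sorted((n for n in nets if eligible(n)), key=lambda n: n.key)
    dropped = len(nets) - len(usable)
    if dropped:
        logger.info("dropped %d edgeless network(s) from dissimilarity", dropped)
    if len(usable) < 2:
        raise ValidationError(
            f"need >= 2 networks with edges for pairwise dissimilarity, "
            f"have {len(usable)}"
        )
    out = [partition_pair(x, y) for x, y in combinations(usable, 2)]
    logger.info("%d pairwise comparisons", len(out))
    return out


def proportions(p: BetaPartition) -> tuple[float, float]:
    """(turnover share, rewiring share) of total dissimilarity; sum to 1."""
    if p.beta_wn <= 0:
        raise ValidationError("shares undefined: beta_wn is 0")
    return p.beta_st / p.beta_wn, p.beta_os / p.beta_wn


def pairs_table(
    pairs: Iterable[BetaPartition],
    sites: Mapping[str, SiteEnvironment] | None = None,
) -> pd.DataFrame:
    """Pairwise records as a table, optionally joined to site environments.

    With a site table, |Δrainfall| and |Δsuitability| columns are added
    (0 for same-site pairs).
    """
    rows = []
    for p in pairs:
        row = {
            "site_1": p.key_1.site_id,
            "swarm_1": p.key_1.swarm_id,
            "date_1": p.key_1.date.isoformat(),
            "site_2": p.key_2.site_id,
            "swarm_2": p.key_2.swarm_id,
            "date_2": p.key_2.date.isoformat(),
            "a": p.shared_interactions,
            "b": p.unique_1,
            "c": p.unique_2,
            "beta_wn": p.beta_wn,
            "beta_st": p.beta_st,
            "beta_os": p.beta_os,
        }
        if sites is not None:
            s1, s2 = sites[p.key_1.site_id], sites[p.key_2.site_id]
            row["d_rainfall"] = abs(s1.rainfall - s2.rainfall)
            row["d_suitability"] = abs(s1.suitability - s2.suitability)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SitePairSummary:
    site_1: str
    site_2: str
    mean_beta_wn: float
    mean_beta_st: float
    mean_beta_os: float
    n_pairs: int


def site_pair_summary(pairs: Sequence[BetaPartition]) -> list[SitePairSummary]:
    """Mean dissimilarity components for each unordered site pair.

    Same-site pairs are summarized too (site_1 == site_2); with 7 sites
    holding data this yields 21 between-site rows plus the within-site
    ones.
    """
    acc: dict[tuple[str, str], list[BetaPartition]] = {}
    for p in pairs:
        s1, s2 = sorted((p.key_1.site_id, p.key_2.site_id))
        acc.setdefault((s1, s2), []).append(p)
    out = []
    for (s1, s2), ps in sorted(acc.items()):
        n = len(ps)
        out.append(
            SitePairSummary(
                site_1=s1,
                site_2=s2,
                mean_beta_wn=sum(p.beta_wn for p in ps) / n,
                mean_beta_st=sum(p.beta_st for p in ps) / n,
                mean_beta_os=sum(p.beta_os for p in ps) / n,
                n_pairs=n,
            )
        )
    return out


def site_summary_table(summaries: Sequence[SitePairSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_1": s.site_1,
                "site_2": s.site_2,
                "mean_beta_wn": s.mean_beta_wn,
                "mean_beta_st": s.mean_beta_st,
                "mean_beta_os": s.mean_beta_os,
                "n_pairs": s.n_pairs,
                "same_site": s.site_1 == s.site_2,
            }
            for s in summaries
        ]
    )
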