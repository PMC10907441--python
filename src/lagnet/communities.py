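"""Modularity communities and anchor-word cluster tables.

Communities are detected by Louvain-style greedy modularity maximization on
the *undirected weighted projection* of the LAG (weights of reciprocal
directed edges summed) — the convention of the graph tools commonly used on
fluency data.  Directedness is preserved everywhere else in the package.

Each community's *anchor* is its member with highest (directed) degree —
the word conjectured to organize retrieval within its semantic cluster.
The cluster table lists communities by size with members sorted by degree,
optionally restricted to the most central words of the whole graph so that
large graphs stay readable.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .lag_builder import Lag

__all__ = [
    "CommunityPartition",
    "undirected_projection",
    "detect_communities",
    "modularity_score",
    "cluster_table",
]


@dataclass(frozen=True)
class CommunityPartition:
    """Node -> community assignment with its modularity score.

    Community ids are contiguous integers from 0, numbered by decreasing
    community size (ties by smallest member word) so that runs are
    deterministic given the seed.
    """

    assignment: dict
    modularity_score: float
    resolution: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, community: int) -> set:
        return {w for w, c in self.assignment.items() if c == community}


def undirected_projection(lag: Lag) -> nx.Graph:
    """Undirected weighted projection: reciprocal edge weights are summed."""
    h = nx.Graph()
    h.add_nodes_from(lag.graph.nodes)
    for u, v, w in lag.graph.edges(data="weight"):
        if h.has_edge(u, v):
            h.edges[u, v]["weight"] += w
        else:
            h.add_edge(u, v, weight=w)
    return h


def _canonical_ids(communities: list[set]) -> dict:
    ordered = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    return {node: i for i, com in enumerate(ordered) for node in com}


def detect_communities(lag: Lag, resolution: float = 1.0, seed: int = 0) -> CommunityPartition:
    """Louvain modularity communities on the undirected weighted projection.

    Deterministic given ``seed``.  A singleton graph yields one community.
    The reported score is re-evaluated from the assignment with
    :func:`modularity_score`, never taken from the optimizer.
    """
    if lag.node_count < 1:
        raise ValueError("cannot partition an empty graph")
    h = undirected_projection(lag)
    if h.number_of_edges() == 0:
        communities = [{n} for n in h.nodes]
    else:
        communities = nx.community.louvain_communities(
            h, weight="weight", resolution=resolution, seed=seed
        )
    assignment = _canonical_ids([set(c) for c in communities])
    score = modularity_score(lag, assignment, resolution=resolution)
    return CommunityPartition(assignment, score, resolution, seed)


def modularity_score(lag: Lag, assignment: dict, resolution: float = 1.0) -> float:
    """Weighted Newman modularity of an assignment, evaluated directly.

    Q = sum_c [ W_c / m  -  gamma * (D_c / 2m)^2 ] on the undirected
    projection, where W_c is the total weight inside community c, D_c the
    total weighted degree of its members and m the total edge weight.
    Pure evaluation — no optimization.
    """
    missing = set(lag.graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(map(str, missing))[:5]}")
    h = undirected_projection(lag)
    m = h.size(weight="weight")
    if m == 0:
        return 0.0
    w_in: dict = {}
    deg: dict = {}
    for u, v, w in h.edges(data="weight"):
        if assignment[u] == assignment[v]:
            w_in[assignment[u]] = w_in.get(assignment[u], 0.0) + w
        deg[assignment[u]] = deg.get(assignment[u], 0.0) + w
        deg[assignment[v]] = deg.get(assignment[v], 0.0) + w
    return sum(
        w_in.get(c, 0.0) / m - resolution * (deg.get(c, 0.0) / (2 * m)) ** 2
        for c in set(assignment.values())
    )


def cluster_table(
    lag: Lag,
    partition: CommunityPartition,
    min_size: int = 1,
    top_n_nodes: int | None = None,
) -> pd.DataFrame:
    """Anchor-word cluster table: one row per (community, member).

    Columns ``community, anchor, member, degree, rank``.  When
    ``top_n_nodes`` is given, the graph is first restricted to its
    ``top_n_nodes`` highest-degree words (ties lexicographic) and only
    communities intersecting that set appear.  Communities are ordered by
    size (descending, within the restriction); members by degree descending
    with lexicographic tie-break; the anchor is the rank-1 member.
    """
    g = lag.graph
    degree = {v: g.in_degree(v) + g.out_degree(v) for v in g}
    nodes = set(g.nodes)
    if top_n_nodes is not None:
        ranked = sorted(nodes, key=lambda v: (-degree[v], str(v)))
        nodes = set(ranked[:top_n_nodes])
    groups: dict[int, list] = {}
    for v in nodes:
        groups.setdefault(partition.assignment[v], []).append(v)
    rows = []
    order = sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), min(map(str, kv[1])))
    )
    for cid, members in order:
        if len(members) < min_size:
            continue
        members = sorted(members, key=lambda v: (-degree[v], str(v)))
        anchor = members[0]
        for rank, v in enumerate(members, start=1):
            rows.append(
                {
                    "community": cid,
                    "anchor": anchor,
                    "member": v,
                    "degree": degree[v],
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows, columns=["community", "anchor", "member", "degree", "rank"])
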