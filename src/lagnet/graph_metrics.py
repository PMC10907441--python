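"""Structural and centrality metrics for lexical availability graphs.

All metrics use directed conventions and ignore edge weights for distances,
matching how fluency-graph studies report them:

* density = E / (N(N-1)) — the directed denominator;
* the clustering coefficient of a vertex v is the density of the subgraph
  spanned by v's adjacent vertices (union of in- and out-neighbours):
  r / (k(k-1)), where k is the number of adjacent vertices and r the number
  of directed edges among them.  The graph coefficient is the average over
  the vertex set;
* path length counts edges (hops); averages and the diameter are taken over
  the reachable ordered pairs only, with the reachable fraction reported so
  disconnection is visible rather than silently absorbed.

Five centrality measures are provided — degree, weighted degree,
eccentricity, closeness, harmonic closeness, betweenness — together with
deterministic top-k ranking and ranking-overlap comparison, because a
recurring empirical question is how much the "most central words" lists
agree across measures.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import networkx as nx
import pandas as pd

from .lag_builder import Lag

__all__ = [
    "NodeClustering",
    "MetricsSummary",
    "PathStats",
    "density",
    "node_clustering",
    "mean_clustering",
    "path_stats",
    "summarize",
    "centralities",
    "top_central",
    "ranking_overlap",
]

CENTRALITY_MEASURES = (
    "degree",
    "weighted_degree",
    "eccentricity",
    "closeness",
    "harmonic_closeness",
    "betweenness",
)

#: measures where a *smaller* value means a more central word
ASCENDING_MEASURES = frozenset({"eccentricity"})


@dataclass(frozen=True)
class NodeClustering:
    """Per-vertex clustering: k adjacent vertices, r directed edges among them."""

    word: object
    k: int
    r: int

    @property
    def value(self) -> float:
        if self.k < 2:
            return 0.0
        return self.r / (self.k * (self.k - 1))


@dataclass(frozen=True)
class PathStats:
    avg_shortest_path: float
    diameter: int
    reachable_pair_fraction: float
    eccentricity: dict


@dataclass(frozen=True)
class MetricsSummary:
    node_count: int
    edge_count: int
    density: float
    mean_clustering: float
    avg_shortest_path: float
    diameter: int
    reachable_pair_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def density(lag: Lag) -> float:
    """Directed density E / (N(N-1)); weights ignored."""
    n = lag.node_count
    if n < 2:
        raise ValueError("density undefined for graphs with fewer than 2 nodes")
    return lag.edge_count / (n * (n - 1))


def node_clustering(lag: Lag, word) -> NodeClustering:
    """Clustering of one vertex: density of the subgraph on its neighbours.

    The neighbourhood is the union of in- and out-neighbours (v excluded);
    r counts the directed edges of the graph with both endpoints in that
    neighbourhood.  Vertices with fewer than two neighbours get value 0 by
    convention.
    """
    g = lag.graph
    if word not in g:
        raise KeyError(f"node {word!r} not in graph")
    nbrs = (set(g.successors(word)) | set(g.predecessors(word))) - {word}
    k = len(nbrs)
    r = 0
    for a, b in combinations(nbrs, 2):
        r += g.has_edge(a, b) + g.has_edge(b, a)
    return NodeClustering(word, k, r)


def mean_clustering(lag: Lag, include_low_degree: bool = True) -> float:
    """Average clustering over the vertex set.

    Vertices with k < 2 contribute 0 and are included by default; set
    ``include_low_degree=False`` to average over k >= 2 vertices only.
    """
    if lag.node_count == 0:
        raise ValueError("mean clustering undefined for the empty graph")
    values = [node_clustering(lag, v) for v in lag.graph]
    if not include_low_degree:
        values = [c for c in values if c.k >= 2]
        if not values:
            return 0.0
    return sum(c.value for c in values) / len(values)


def _distances(lag: Lag, mode: str) -> dict:
    if mode == "directed":
        g = lag.graph
    elif mode == "undirected":
        g = lag.graph.to_undirected(as_view=False)
    else:
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    return {src: lengths for src, lengths in nx.all_pairs_shortest_path_length(g)}


def path_stats(lag: Lag, mode: str = "directed") -> PathStats:
    """Hop-count path statistics via all-sources BFS; weights never enter.

    The average and the diameter range over ordered pairs (u, v), u != v,
    where v is reachable from u; ``reachable_pair_fraction`` reports how
    many of the N(N-1) ordered pairs that is.  Eccentricity of v is the
    maximum finite distance from v (0 for a node reaching nothing).
    """
    n = lag.node_count
    if n < 2:
        raise ValueError("path statistics need at least 2 nodes")
    dist = _distances(lag, mode)
    total = 0
    reachable = 0
    diameter = 0
    ecc = {}
    for src in lag.graph:
        lengths = [d for tgt, d in dist.get(src, {}).items() if tgt != src]
        ecc[src] = max(lengths, default=0)
        total += sum(lengths)
        reachable += len(lengths)
        diameter = max(diameter, ecc[src])
    avg = total / reachable if reachable else 0.0
    return PathStats(avg, diameter, reachable / (n * (n - 1)), ecc)


def summarize(lag: Lag, mode: str = "directed") -> MetricsSummary:
    """The headline metric row for one graph: size, density, clustering, paths."""
    ps = path_stats(lag, mode)
    return MetricsSummary(
        node_count=lag.node_count,
        edge_count=lag.edge_count,
        density=density(lag),
        mean_clustering=mean_clustering(lag),
        avg_shortest_path=ps.avg_shortest_path,
        diameter=ps.diameter,
        reachable_pair_fraction=ps.reachable_pair_fraction,
    )


def centralities(lag: Lag) -> pd.DataFrame:
    """Per-word centrality table with the six standard measures.

    degree counts in+out edges; weighted_degree sums in+out edge weights;
    eccentricity, closeness and harmonic closeness use directed hop
    distances *from* the word (harmonic: mean of 1/d with 1/inf = 0;
    closeness: the Wasserman–Faust reach-corrected form, 0 for a node
    reaching nothing); betweenness uses unnormalized directed pair
    dependencies over unweighted shortest paths.
    """
    if lag.node_count < 2:
        raise ValueError("centralities need at least 2 nodes")
    g = lag.graph
    n = g.number_of_nodes()
    dist = _distances(lag, "directed")
    rows = {}
    betw = nx.betweenness_centrality(g, normalized=False)
    for v in g:
        lengths = [d for tgt, d in dist[v].items() if tgt != v]
        reach = len(lengths)
        tot = sum(lengths)
        closeness = (reach / (n - 1)) * (reach / tot) if tot else 0.0
        harmonic = sum(1.0 / d for d in lengths) / (n - 1)
        rows[v] = {
            "degree": g.in_degree(v) + g.out_degree(v),
            "weighted_degree": g.in_degree(v, weight="weight")
            + g.out_degree(v, weight="weight"),
            "eccentricity": max(lengths, default=0),
            "closeness": closeness,
            "harmonic_closeness": harmonic,
            "betweenness": betw[v],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "word"
    return table.sort_index()


def top_central(
    table: pd.DataFrame,
    measure: str,
    count: int = 10,
    min_value: float | None = None,
) -> list:
    """Deterministic top-``count`` ranking of one centrality measure.

    Eccentricity ranks ascending (lower eccentricity = more central); all
    other measures descending.  Ties break lexicographically.  ``min_value``
    drops words below a floor before ranking — useful for filtering out
    degenerate values on disconnected graphs.
    """
    if measure not in CENTRALITY_MEASURES:
        raise KeyError(
            f"unknown measure {measure!r}; choose from {CENTRALITY_MEASURES}"
        )
    col = table[measure]
    if min_value is not None:
        col = col[col >= min_value]
    ascending = measure in ASCENDING_MEASURES
    ranked = sorted(col.items(), key=lambda kv: (kv[1] if ascending else -kv[1], kv[0]))
    return [word for word, _ in ranked[:count]]


def ranking_overlap(list_a: list, list_b: list) -> tuple[int, float]:
    """Overlap between two ranked word lists: (|A ∩ B|, Jaccard |A∩B|/|A∪B|)."""
    if not list_a or not list_b:
        raise ValueError("ranking lists must be non-empty")
    a, b = set(list_a), set(list_b)
    inter = len(a & b)
    return inter, inter / len(a | b)
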