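"""Construction and pruning of the lexical availability graph (LAG).

The LAG is a directed, integer-weighted simple graph.  Nodes are the word
types produced for one prompt; for every pair of *contiguous* words in a
chain there is a directed edge, and each edge is weighted by the number of
informants that produced that ordered pair.  A chain DOG, CAT, LION, TIGER
therefore contributes the three directed edges DOG->CAT, CAT->LION,
LION->TIGER.  Because chains are duplicate-free after editing, a chain can
contribute at most 1 to any single ordered pair and the graph has no
self-loops.  The graph may be disconnected.

Pruning removes every edge whose weight is at or below a threshold — keeping
only associations shared by several informants — and optionally drops the
nodes isolated by that removal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .corpus_io import Corpus

__all__ = ["Lag", "build_lag", "prune", "write_gexf", "write_graphml", "write_edgelist"]


@dataclass(frozen=True)
class Lag:
    """A lexical availability graph: directed ``networkx`` graph + prompt label.

    The wrapped :class:`networkx.DiGraph` stores each edge's informant count
    under the ``"weight"`` attribute.
    """

    graph: nx.DiGraph
    prompt: str = ""

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        """Number of directed edges, weights not counted."""
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def weight(self, source, target) -> int:
        return self.graph.edges[source, target]["weight"]

    def validate(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if not isinstance(w, (int,)) or w < 1:
                raise ValueError(f"edge {u!r}->{v!r} has invalid weight {w!r}")


def build_lag(corpus: Corpus) -> Lag:
    """Aggregate contiguous ordered word pairs over all chains of a corpus.

    Every word type becomes a node (including words produced in isolation);
    each chain of length L increments the weight of its L-1 contiguous
    ordered pairs by 1.  An empty corpus yields an empty graph.
    """
    g = nx.DiGraph()
    for chain in corpus.chains:
        if len(set(chain.words)) != len(chain.words):
            raise ValueError(
                f"chain of informant {chain.informant_id!r} has repetitions; "
                "edit the corpus first"
            )
        g.add_nodes_from(chain.words)
        for a, b in zip(chain.words, chain.words[1:]):
            if g.has_edge(a, b):
                g.edges[a, b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return Lag(g, corpus.prompt)


def prune(lag: Lag, max_removed_weight: int, drop_isolated: bool = True) -> Lag:
    """Remove every edge with weight <= ``max_removed_weight``.

    With ``max_removed_weight=2`` only pairs written by at least three
    informants survive.  When ``drop_isolated`` is set, nodes left with no
    incident edge are removed as well.  Pure function: the input graph is
    untouched.
    """
    if max_removed_weight < 0:
        raise ValueError("max_removed_weight must be >= 0")
    g = lag.graph.copy()
    g.remove_edges_from(
        [(u, v) for u, v, w in g.edges(data="weight") if w <= max_removed_weight]
    )
    if drop_isolated:
        g.remove_nodes_from([n for n, d in g.degree() if d == 0])
    return Lag(g, lag.prompt)


def write_gexf(lag: Lag, path: str | Path) -> None:
    """Gephi-compatible GEXF export; weights in the ``weight`` edge attribute."""
    nx.write_gexf(lag.graph, path)


def write_graphml(lag: Lag, path: str | Path) -> None:
    nx.write_graphml(lag.graph, path)


def write_edgelist(lag: Lag, path: str | Path) -> None:
    """Weighted edge list CSV ``source,target,weight`` (deterministic order)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "weight"])
        for u, v, wt in sorted(lag.graph.edges(data="weight")):
            w.writerow([u, v, wt])
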