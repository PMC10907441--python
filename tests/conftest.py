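from __future__ import annotations

import networkx as nx
import pytest

from lagnet.corpus_io import Corpus, ResponseChain
from lagnet.lag_builder import Lag


def make_lag(edges, nodes=(), prompt="test") -> Lag:
    """Build a Lag from (u, v) or (u, v, weight) tuples."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for e in edges:
        u, v, *w = e
        g.add_edge(u, v, weight=w[0] if w else 1)
    return Lag(g, prompt)


def make_corpus(chains, prompt="animals") -> Corpus:
    """Corpus from a list of word sequences; informants auto-numbered."""
    return Corpus(
        prompt,
        tuple(
            ResponseChain(f"s{i}", prompt, tuple(words))
            for i, words in enumerate(chains)
        ),
    )


@pytest.fixture
def directed_triangle() -> Lag:
    """Directed 3-clique: all 6 ordered pairs."""
    return make_lag([(a, b) for a in "abc" for b in "abc" if a != b])


@pytest.fixture
def two_cliques() -> Lag:
    """Two directed 5-cliques joined by a single edge a0 -> b0."""
    edges = []
    for prefix in ("a", "b"):
        nodes = [f"{prefix}{i}" for i in range(5)]
        edges += [(u, v) for u in nodes for v in nodes if u != v]
    edges.append(("a0", "b0"))
    return make_lag(edges)
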