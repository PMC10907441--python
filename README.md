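# lagnet

Network analysis of verbal-fluency (lexical availability) data.

When informants list words for a cue category — *animals*, *countryside* —
the order of their responses carries structure: words are retrieved in
semantic runs, early positions signal high availability, and the pairs of
contiguous words aggregate into a directed association network of the
(collective) mental lexicon. `lagnet` turns raw fluency chains into such
**lexical availability graphs** (LAGs) and asks the questions this
literature asks of them:

- Is the network **small-world** — clustering far above a size/density-matched
  random digraph, path lengths comparable?
- Which words are **central**, and do degree, closeness, harmonic closeness,
  betweenness and eccentricity agree on them?
- Do modularity **communities** recover semantic clusters, each organized
  around a high-degree **anchor word**?
- Which words have high **lexical availability**
  `D(P_j) = Σ_i e^{-2.3 (i-1)/(n-1)} f_ji / I_1`, i.e. are produced early
  and often?

## The model

The LAG for one prompt is a directed, integer-weighted simple graph: nodes
are the word types produced; for each pair of contiguous words in a chain
there is a directed edge, weighted by the number of informants producing
that ordered pair (a chain DOG, CAT, LION, TIGER contributes DOG→CAT,
CAT→LION, LION→TIGER). Density is `E/(N(N-1))`; the clustering coefficient
of a vertex is the density of the subgraph on its adjacent vertices,
`r/(k(k-1))`; both use directed conventions throughout. Edges with weight
≤ *t* can be pruned (and the resulting isolated nodes dropped) to keep only
associations shared by several informants. Null comparison uses uniform
G(n, m) simple digraphs with exactly the observed node and edge counts.

Because real learner fluency corpora are rarely published, the package
ships a **synthetic generator** with planted structure: a modular lexicon
whose clusters carry availability-graded retrieval weights (geometric decay
from an anchor word), traversed by a within-cluster walk with stochastic
cluster switching and a small erratic-jump rate. Every pipeline claim —
community recovery, anchor detection, availability/weight correspondence,
diameter inflation by erratic edges — is scored against this ground truth.

## Worked example

```sh
lagnet demo --seed 1 --out demo-bundle
```

generates a synthetic corpus (5 clusters × 12 words, 100 informants, mean
chain length 14, switch probability 0.08, erratic rate 0.03) and runs the
full pipeline. From `demo-bundle/metrics.json`:

| metric | full graph | pruned (weight ≤ 2 removed) |
|---|---|---|
| nodes / edges | 60 / 647 | 57 / 164 |
| density | 0.183 | 0.051 |
| mean clustering | 0.421 | 0.296 |
| avg shortest path | 2.101 | 2.168 |
| diameter | 4 | 6 |
| modularity | 0.676 | 0.779 |

The matched-random comparison (`small_world.json`) reports mean random
clustering 0.183 — a clustering ratio of 2.3 with path ratio 1.09: the
planted modular structure raises clustering well above random at unchanged
path lengths, though at this vocabulary size (60 types for 100 informants)
the graph is too dense for an order-of-magnitude excess. Louvain detection
finds exactly 5 communities (modularity 0.676) that coincide with the
planted clusters, and 4 of the 5 planted anchors surface as the top-degree
member of their community. The most available words
(`availability.csv`: `c2w00` at D = 0.354, `c3w00` at 0.302, …) are the
planted anchors — high retrieval weight shows up as early, frequent
production, exactly the availability/centrality correspondence the index
is meant to capture.

The same stages are available as a library (`lagnet.read_chains`,
`edit_corpus`, `build_lag`, `prune`, `summarize`, `centralities`,
`detect_communities`, `availability_index`, `small_world_report`,
`simulate_chains`, …) and as individual CLI verbs: `ingest`, `build`,
`metrics`, `communities`, `availability`, `nullcheck`, `simulate`, and
`run` with a YAML config.

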