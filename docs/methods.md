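# Methods

## Data model and editing

The raw unit is a *response chain*: one informant's ordered word list for
one prompt. Editing applies, in order, a user-supplied spelling table,
multi-word joining (`fresh air` → `fresh-air`), case folding (default on:
availability analyses are case-insensitive), and within-chain
deduplication keeping the first occurrence. Positions recompact to 1..L′
after deduplication so the availability formula sees contiguous ranks.
Spelling correction is strictly table-driven — reference studies corrected
by hand, and automatic correction would be an uncontrolled transformation.
Editing is idempotent, order-preserving, and logged per token. No
lemmatization or singular/plural merging is performed; word identity is
the edited token string.

## Graph construction

Nodes are word types; each chain of length L contributes its L−1
contiguous ordered pairs, each incrementing an integer edge weight.
Within-chain deduplication guarantees no self-loops and that one informant
contributes at most 1 to any ordered pair, so weight = number of
informants producing the pair (asserted in tests). Pruning removes edges
with weight ≤ *t* (i.e. keeps pairs shared by at least *t*+1 informants)
and optionally the nodes thereby isolated; it is a pure function and
monotone in *t*.

## Metrics

All conventions are directed. Density is E/(N(N−1)); back-calculation
against the three published density values this package reproduces
confirms the directed denominator. A vertex's clustering coefficient is
r/(k(k−1)) where the neighbourhood is the *union* of in- and
out-neighbours and r counts directed edges among them; vertices with k < 2
score 0 and are included in the graph mean by default (a flag excludes
them — the exact handling in GUI network tools is not documented).
Distances are hop counts from all-sources BFS; averages and the diameter
are taken over reachable ordered pairs only, with the reachable fraction
reported alongside. An undirected mode is provided because some published
path figures may have been computed on symmetrized graphs; the directed
mode is the default. Edge weights never enter distance computations.

Centralities: degree (in+out), weighted degree (in+out weight sums),
eccentricity (max finite distance from the node; ranked ascending since
low eccentricity means central), closeness (Wasserman–Faust
reach-corrected, on out-distances), harmonic closeness (mean of 1/d,
1/∞ = 0) and unnormalized directed betweenness. Rankings break ties
lexicographically for full determinism, and a generic `min_value` filter
replaces the ad-hoc outlier cut-offs sometimes applied to published
centrality tables. Ranking overlap is reported as intersection count and
Jaccard fraction.

## Communities

Louvain greedy modularity maximization (networkx implementation, seeded,
resolution default 1.0) runs on the undirected weighted projection with
reciprocal weights summed — the convention of the tools this field uses —
while every other computation stays directed. The reported modularity is
always re-evaluated from the assignment by the package's own pure
modularity function (Q = Σ_c [W_c/m − γ(D_c/2m)²]), never taken from the
optimizer, and that evaluator is cross-checked in tests against both an
independent matrix oracle and networkx. Community ids are renumbered by
decreasing size; each community's anchor is its maximum-degree member
(ties lexicographic). The cluster table can be restricted to the top-k
degree words of the whole graph before tabulating, mirroring how large
graphs are presented.

## Availability index

D(P_j) = Σ_i exp(−λ(i−1)/(n−1)) · f_ji / I₁ with λ = 2.3 (configurable,
never silently changed), f_ji the number of informants producing word j at
position i, and I₁ the informant count. n is the sample-wide maximal
position (longest chain for the prompt) — the standard convention; because
the phrase "maximal position reached by the word" is ambiguous, a
`per_word_n` flag implements the per-word reading. For n = 1 the exponent
is taken as 0 (limit convention), collapsing D to relative frequency.
D ∈ (0, 1], is bounded by relative frequency with equality only for
position-1 occurrences, and is monotone under earlier placement (property
tested).

## Null models and the small-world comparison

The null is uniform G(n, m): exactly the observed node and edge counts, m
distinct ordered pairs without self-loops, weights 1. Exact edge matching
was chosen over Bernoulli density matching because it is stricter and
makes every replicate directly comparable; a G(n, p) mode exists for
sensitivity analysis. The report carries ensemble means and standard
deviations of mean clustering, average path length and diameter over R
replicates (default 50), the observed/random ratios, and a verdict flag
small_world = (clustering ratio ≥ 5) ∧ (path ratio ≤ 2). The thresholds
are explicit configuration, not hidden constants, since the underlying
claim ("clustering an order of magnitude above random, paths comparable")
is qualitative. For an Erdős–Rényi digraph the expected mean clustering
equals the density m/(n(n−1)); the ensemble is verified to converge to it
within Monte-Carlo error.

## Synthetic generator

The generator emulates clustered retrieval: a lexicon of 5 clusters × 12
words by default, within-cluster weights decaying geometrically (ratio
0.8) from an anchor whose weight is 3× the next word's — enough for
anchors to dominate production without making runs deterministic. Entry
clusters are equiprobable (keeping planted clusters exchangeable for
recovery scoring). Chains are produced per informant: draw a length from
a shifted negative binomial (mean 14, shape 10 → roughly 5–25 words,
matching typical 2-minute task output; no empirical length distribution is
published, so this is a modelling choice), then walk: sample without
replacement within the current cluster proportionally to weights; after
each word jump to a uniformly random unused word with probability 0.03
(erratic associations), else switch clusters with probability 0.08 — and
always when the cluster is exhausted. Each informant draws from an
independent stream spawned from (seed, informant index), so corpora are
bit-reproducible and chains independently regenerable.

What the generator reproduces: modular association structure recoverable
by Louvain (ARI ≈ 1 at defaults), anchors as community degree-maxima and
top availability scorers, and diameter inflation relative to the matched
null caused by erratic edges. What it does not reproduce: the long-tailed
vocabulary of real samples. Real fluency corpora of ~100 informants yield
200–400+ word types, most produced once; the 60-type lexicon yields a
much denser graph (density ≈ 0.18 vs ≈ 0.016 in comparable empirical
graphs). A direct consequence is that the observed/random clustering
ratio at defaults plateaus near 2.3 — clearly above 1, but far below the
order-of-magnitude excess sparse empirical graphs show, because the
matched null's clustering equals the (here large) density. Passing
recovery tests therefore demonstrate the mechanisms, not the magnitudes,
of the empirical small-world effect.

## Numerical and design notes

- All randomness is explicitly seeded (numpy Generator / seeded networkx);
  candidate sets are iterated in sorted order so results do not depend on
  hash randomization.
- Ties everywhere (rankings, anchors, community ordering) break
  lexicographically.
- Degenerate inputs: empty corpus → empty graph; single-node graphs reject
  density/path/centrality computations with a clear error; disconnected
  graphs are handled by the reachable-pair restriction rather than
  infinities.
- Pipeline bundles are deterministic given their manifest (config + seeds);
  JSON is written with sorted keys at full precision, tables at fixed
  precision.
- Problem sizes in the test suite (200-graph oracle suites on ≤ 8 nodes,
  20-seed synthetic ensembles, 30–50 null replicates) are chosen so the
  whole suite runs in well under a minute while keeping Monte-Carlo error
  far from the asserted margins.

## Known limitations

- Modularity values from single Louvain runs are seed-dependent; treat
  them as descriptive, not as comparable across tools.
- The availability index's per-word-n variant changes rankings for words
  confined to short chains; only the sample-wide default is validated
  against closed-form fixtures.
- No degree-preserving (configuration-model) null is provided; the G(n, m)
  null matches size and density only.
- The generator's clusters are disjoint; polysemous words bridging
  clusters, bilingual interference and timing effects are out of scope.
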