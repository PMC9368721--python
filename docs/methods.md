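# Methods

This note records the models, conventions, and design choices behind
`mediacite`, in the spirit of a statistical package's methods appendix. It
states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## The citation-network model

A media citation network is a simple directed graph. Nodes are media
outlets carrying a two-letter country code and a continent label; an edge
u→v with weight w means outlet u cited outlet v's reporting w times, so
information flows v→u while the citation points u→v. Self-citations are
excluded by construction and duplicate citing→cited records merge by
summing counts. Outlets that neither cite nor are cited are left out of the
network: node counts therefore reflect participants in citation exchange,
not the whole corpus's masthead list.

Citation extraction from raw report snippets is alias-table lookup only:
case-insensitive, longest-alias-first (so a nested name such as "Post"
inside "The Washington Post" is not double-counted), one record per
detected mention, self-mentions dropped, and reports whose publishing
outlet is missing from the thesaurus skipped with a warning count. No fuzzy
matching or disambiguation is attempted.

## Topology conventions

All topological statistics (degree distributions, clustering, path
lengths, shells, betweenness, communities) are computed on the simple
undirected, unweighted view: {u,v} is an edge iff u→v or v→u. Direction
and weights enter only the node scores (strength, ndegree, PageRank) and
the country matrices.

- **Density** is directed: E/(N(N−1)). For N ≤ 1 it is reported as 0 with
  an explicit `density_defined=False` flag.
- **Components** are weakly connected components.
- **Characteristic path length** is the mean BFS distance over unordered
  connected pairs *within the largest component*; cross-component
  distances are undefined and excluded.
- **Clustering** of a node with degree < 2 is defined as 0 and included in
  the average, which runs over all nodes of the graph.
- **Scale-free fit**: ordinary least squares of log₁₀F against log₁₀n on
  the complementary cumulative degree distribution, F(n) = fraction of
  nodes with degree ≥ n. This is a regression-style assessment, not
  maximum-likelihood tail estimation; it requires at least three distinct
  positive degree values and raises a degenerate-fit error otherwise. For
  a pure Barabási–Albert backbone the degree exponent 3 implies a CCDF
  exponent of 2; finite-size cutoffs pull the OLS estimate slightly below
  (measured ≈ 1.8 at 2000 nodes), within the ±0.5 band the tests assert.
- **Rounding** for report output is half-away-from-zero at the printed
  precision; internal computation never rounds.

## Core–periphery

The k-shell index is assigned by iterative pruning: starting at k = 1,
repeatedly remove every node of current degree ≤ k (assigning it shell k);
when none remains, increment k. Shells start at layer 1, and the result is
independent of removal order. Pruning uses plain degree; a weighted
variant (`use_strength=True`) prunes on citation-weighted degree instead,
for corpora where multiplicity is believed to matter.

The core threshold is chosen by the crust-component crossover: among k
whose k-crust second-largest component did not grow relative to k−1, pick
the k maximising the jump in the crust's largest component,
Δ(k) = largest(k) − largest(k−1); if no k qualifies, the unconstrained
argmax of Δ is used; ties break toward the smallest k. This is a
deterministic operationalisation of a visual crossover criterion
("largest component jumps while the second-largest starts shrinking"), and
the constrained-argmax form is the package's own formalisation. The core
is the k\*-core, the periphery the (k\*−1)-crust; the two partition the
node set exactly. Core country matrices exclude domestic citations and
order countries by descending total citations so the heaviest flows occupy
the upper-left corner.

## Communities

Girvan–Newman in its classic form: edge betweenness (Brandes
accumulation; equal fractional credit to tied shortest paths, each
unordered pair counted once) is recomputed after every single edge
removal; the maximal edge is removed, with ties broken by lexicographic
endpoint order so runs are exactly reproducible. After each removal that
increases the component count, the component partition is recorded with
its modularity Q = Σᵢ(eᵢᵢ − aᵢ²), evaluated against the edge set of the
graph handed to the algorithm (a peripheral component is partitioned
against its own edge count). The best partition maximises Q over the
recorded partitions *and* the undivided starting partition, with ties
going to fewer communities — so a graph without community structure (for
instance a single triangle) is returned whole with Q = 0. Q is unweighted;
a weighted variant is out of scope. Note Q lies in [−1, 1): splitting a
clique always gives negative Q, and Q of the one-community partition is
identically 0. In the full pipeline, community detection runs on each
peripheral component with at least 4 nodes; when the crossover yields an
empty periphery (every node in one shell), it falls back to the whole
graph's components.

## Node scores

- **ndegree** = (weighted in-degree + weighted out-degree)/(N−1). The
  weighted reading ("strength") is forced by observed values exceeding the
  unweighted maximum of 2.
- **Damping factor** d = citation connections / reports, clamped to [0,1]
  with a flag if the raw ratio exceeds 1. This treats d as the probability
  that an editor follows a citation chain rather than accessing the
  original report.
- **PageRank**: power iteration from the uniform vector; per step each
  node receives (1−d)/N plus d times the weighted share of its citers'
  mass; nodes with no outgoing citations redistribute their damped mass
  uniformly over all nodes (the convention that conserves total mass under
  rank leak). Convergence is declared when the L1 change falls below 1e-9
  (default), with a hard cap of 1000 iterations and a convergence error
  carrying the last residual beyond it. At d = 1 the citation walk can be
  periodic and plain iteration oscillates; the update is then averaged
  with the previous iterate (lazy walk), which has the identical fixed
  point and restores convergence. For d < 1 the map is a contraction with
  rate d, so plain iteration is kept.
- **Activity share** = strength / (2 × total edge weight), i.e. each
  citation contributes one unit of activity at both its endpoints; shares
  sum to 1. **Influence share** = PageRank × 100 (percent; sums to 100).
  Published per-outlet activity percentages cannot be reconstructed
  exactly from recoverable totals, so the endpoint-mass definition is
  fixed here and documented rather than reverse-engineered.
- **Stage comparison** reports per-outlet and per-country share changes
  (entities absent from a stage appear as missing, not zero) and
  stage2/stage1 node and edge ratios for the full networks and for the
  induced core subnetworks.

## The synthetic media system

The generator emulates the statistical structure of an international news
citation network observed during a health-emergency alert window, with
planted ground truth for validation. One seeded NumPy generator drives
every draw, so identical configurations are bit-identical.

1. **Countries**: outlet counts follow a Zipf-like law, country rank r
   with probability ∝ r^(−skew), skew 1.2 by default over 30 countries —
   a few large media systems and a long tail. Codes come from a shipped
   ISO-3166/continent table ordered with the globally prominent media
   markets first.
2. **Backbone**: preferential attachment (3 edges per newcomer by
   default, matching a mean directed degree near 3), oriented
   newcomer→incumbent since young outlets cite established ones. With
   probability 0.6 a follow-up attachment closes a triangle with a
   neighbour of the previous target, lifting clustering while preserving
   the heavy tail. With probability 0.3 the cited endpoint is rewired to
   a same-country outlet, producing the domestic citation bias visible in
   country matrices.
3. **Core**: the 20 highest-degree nodes are densified with extra mutual
   edges until each has internal degree ≥ ⌈0.6·(size−1)⌉, guaranteeing a
   deep shell that the crossover rule can find, while the degree tail
   stays heavy.
4. **Communities**: blocks of outlets untouched by the backbone are wired
   as planted partitions (default three blocks of 8, internal pair
   probability 0.9, cross-block 0.02) — the country-affine peripheral
   cliques.
5. **Weights**: each edge's multiplicity is 1 plus a geometric variate
   with mean weight_mean − 1 (default mean 3.25, the empirical
   weight-per-edge ratio of an alert-stage citation network).
6. **Corpus**: 20,000 reports by default (the recovery experiments use
   10⁵); each cites an external outlet with probability d = 0.13, following
   one of the publisher's outgoing edges when it has any. The estimator
   d̂ = citations/reports therefore recovers the configured d up to
   binomial error (≤ 0.01 at 10⁴ reports).

**What the generator does not emulate**: report text and timestamps, topic
structure, the retrieval/cleaning process of a commercial news database,
reciprocity patterns of real wire services, and empirical clustering
levels (the synthetic default reaches ≈ 0.17 versus ≈ 0.4–0.5 in real
alert-phase networks). Passing tests therefore demonstrate algorithmic
correctness and parameter recovery under a faithful statistical cartoon,
not fidelity to any particular proprietary corpus. On the default
synthetic system the crossover threshold also lands shallower (k\* ≈ 4)
than in dense empirical networks, because the preferential-attachment
periphery joins the crust in one large step; the planted core is
nevertheless always contained in the selected k\*-core, which is what the
recovery experiments assert.

## Problem sizes in tests and acceptance runs

Oracle suites run at the scale where brute force is exact and fast:
betweenness enumeration on graphs of ≤ 12 nodes (100 seeds), dense
linear-system PageRank on ≤ 50 nodes (100 seeds, d ∈ {0, 0.13, 0.85, 1}),
shell decomposition against minimum-degree deletion on ≤ 37 nodes.
Recovery experiments use 2000-node attachment backbones (10 seeds),
24-node planted partitions and 300-node planted-core systems (20 seeds
each), and a 10⁵-report corpus. The whole acceptance script completes in a
few seconds on one CPU.

## Known limitations

- Alias matching is exact string lookup; outlets sharing a name collide.
- The crossover rule assumes a profile with a discernible jump; on
  profiles with strictly linear growth it falls back to the smallest
  argmax, which is reported with a degenerate flag when only one shell
  exists.
- OLS power-law fitting is descriptive, not a hypothesis test; no
  goodness-of-fit comparison against alternatives is made.
- Girvan–Newman recomputes betweenness after every removal (O(nm) per
  removal); it is intended for peripheral components of at most a few
  hundred nodes, not whole large networks.
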