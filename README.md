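# mediacite

Core–periphery and influence analysis of international media citation
networks.

When a public-health emergency breaks, news of it moves through a citation
network: outlet *A* quotes a report by outlet *B*, so risk information flows
from *B* to *A*. `mediacite` is a toolkit for studying that flow. It builds
directed, weighted citation networks over media outlets (nodes are outlets
labelled by country; an edge's weight counts citations), characterises their
global structure, splits them into a core and periphery, finds collaborative
cliques in the periphery, and ranks outlets by activity and influence. It is
aimed at researchers in infodemiology, risk communication, and international
news-flow analysis.

## What it computes

**Topology.** Directed density E/(N(N−1)), weakly connected components, and
the small-world pair — characteristic path length and mean local clustering —
on the undirected, unweighted view. Scale-freeness is assessed by ordinary
least squares on the complementary cumulative degree distribution in log–log
space, fitting

    F(n) = a · n^(−b)

where F(n) is the fraction of outlets with degree ≥ n.

**Core–periphery.** k-shell decomposition by iterative degree pruning
(shells start at layer 1), then the crust-component crossover rule: the core
threshold k\* is the k at which the k-crust's largest component jumps in size
while its second-largest component starts shrinking — the depth at which the
remaining shells carry the network's connectivity. The core is the k\*-core,
the periphery the (k\*−1)-crust. Core coverage is the fraction of outlets in
or directly connected to the core.

**Communities.** Classic Girvan–Newman on peripheral components: repeatedly
remove the highest-betweenness edge (recomputing betweenness after every
removal) and keep the partition maximising modularity

    Q = Σᵢ (eᵢᵢ − aᵢ²)

with eᵢᵢ the fraction of edges inside community *i* and aᵢ its fraction of
edge endpoints.

**Node scores.** Activity is the citation-weighted total degree normalised
by N−1 (`ndegree = strength/(N−1)`); influence is PageRank on the weighted
citation graph,

    PR(A) = (1−d)/N + d · Σᵢ n(Tᵢ→A)/C(Tᵢ) · PR(Tᵢ)

where the damping factor d is not the web-surfing default 0.85 but an
empirical quantity: the proportion of reports that cite an external source
(0.13 for pandemic-alert news reporting). Outlets citing nobody redistribute
their damped mass uniformly, so scores always sum to 1.

**Synthetic media systems.** Because real news corpora are proprietary, a
seeded generator produces citation networks with the same statistical
signature — a preferential-attachment backbone with triad closure (heavy
degree tail, clustering), a dense planted core, country-affine peripheral
blocks, Zipf-skewed country sizes, geometric citation multiplicities — plus
a report corpus with a known true d, so every stage of the pipeline can be
validated against planted ground truth.

## Worked example

```python
import mediacite as mc

cfg = mc.SyntheticConfig(seed=7)          # ~400 outlets, 30 countries
net, truth = mc.generate_citation_network(cfg)
summary, _ = mc.generate_report_corpus(cfg, net)
report = mc.run_stage(
    net, corpus=mc.CorpusSummary(summary.n_reports,
                                 summary.n_citation_connections, "demo"),
)
print(report.summary_table_row())
```

prints

```
{'Number of Nodes': 400, 'Number of Edges': 1360, 'Total Edge Weights': 4289,
 'Density': 0.009, 'Number of Components': 1, 'Largest Component Size': 400}
```

a single connected 400-outlet system of density 0.009. Drilling in:

- the degree CCDF fits a power law with exponent b ≈ 1.88 (r² ≈ 0.94) — a
  heavy-tailed, approximately scale-free system;
- characteristic path length 3.23 with clustering 0.17: most outlets reach
  each other within three citation hops;
- the shell decomposition reaches k_max = 12 and the crossover selects
  k\* = 4 with core coverage 1.0 — every outlet is in or adjacent to the
  core;
- the damping factor estimated from the synthetic corpus is
  2527/20000 ≈ 0.126, recovering the configured 0.13;
- the top influence scores (PageRank × 100) identify the planted hub
  outlets, e.g. `outlet032` with influence share 0.572%.

The same pipeline is available from the shell:

```bash
mediacite simulate --seed 7 --out sim/
mediacite all --edges sim/edges.csv --nodes sim/nodes.csv \
              --corpus sim/corpus.json --out report.json
mediacite compare --edges1 s1/edges.csv --nodes1 s1/nodes.csv \
                  --edges2 s2/edges.csv --nodes2 s2/nodes.csv --out cmp.json
```

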