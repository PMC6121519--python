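# seedmodule

Network-medicine tooling for building **seed-gene disease networks** from a
consolidated protein–protein/gene interactome, and for asking what those
networks are enriched for. It was written for the kind of analysis used to
chart the molecular neighborhood of pulmonary hypertension (PH) and fibrosis
genes and their overlap with microRNA target programs, but the machinery is
generic: any curated seed list, any collection of interaction databases, any
GMT annotation collection.

## What it computes

1. **Consolidated interactome (CI).** Two-column TSV edge lists and a
   PSI-MITAB 2.5 subset (DIP/BioGRID/IntAct/MINT-style exports) are merged
   into one simple undirected graph over normalized gene symbols. Self-loops
   are dropped, parallel edges collapsed, and every edge keeps the set of
   source databases that reported it.

2. **Seed-network expansion.** Curated seed genes are mapped onto the CI and
   the largest connected component (LCC) of the seed-induced subgraph is
   taken as the anchor. First-degree interactors are then recruited
   iteratively: at each step the candidate adjacent to the network that
   reconnects the most still-disconnected seeds is added (ties broken by
   interactome degree, then lexicographically); when no single interactor
   reconnects a seed outright, the network grows one hop along a shortest
   path toward a disconnected seed. Seeds in unreachable components are
   reported as excluded. The construction is fully deterministic.

3. **Reference-network partition.** A query network (e.g. the expansion of
   heritable-disease factors united with miR-130/301 targets) is classified
   gene-by-gene against two reference networks: common to both, to one only,
   or to neither — the *outer ring* of genes that pre-established disease
   networks do not explain.

4. **Two-round over-representation analysis.** Hypergeometric upper-tail
   tests of (round 1) all query-network genes and (round 2) outer-ring genes
   only, against a GMT collection, with Benjamini–Hochberg FDR control per
   round: `p = P(X ≥ k)`, `X ~ Hypergeom(N, K, n)` for a universe of `N`
   genes, a set of size `K` and a query of size `n` with overlap `k`.

A synthetic-data module generates benchmark instances with known ground
truth — a preferential-attachment background, planted dense modules with
partially observed seeds, edge lists split across source files, and a GMT
collection with one planted enriched set — so every stage is testable
without downloading databases.

## Worked example

Generate a synthetic instance whose planted 20-gene module has within-module
density 0.35 and half of its members observed as seeds, consolidate the three
emitted edge lists, and expand the seed network:

```sh
cat > sim.yaml <<EOF
rng_seed: 3
modules:
  - {size: 20, within_density: 0.35, n_bridges: 3}
EOF
seedmodule simulate --config sim.yaml --outdir fixtures
seedmodule consolidate \
  --edges fixtures/edges_src1.tsv:SRC1 \
  --edges fixtures/edges_src2.tsv:SRC2 \
  --edges fixtures/edges_src3.tsv:SRC3 \
  --out ci.graphml
seedmodule build --interactome ci.graphml --seeds fixtures/seeds_module0.txt \
  --out net.graphml --report report.json
```

which prints

```
wrote 3 edge lists, 1 seed lists, GMT and ground truth to fixtures
consolidated interactome: 320 genes, 663 interactions
network: 11 genes, 13 interactions, 1 connectors, 0 excluded seeds
```

The 10 observed seeds fragment into disconnected pieces inside the CI; the
expansion recruits exactly one connector (`G000311`) to join them — and the
ground truth in `fixtures/ground_truth.json` confirms that this connector is
one of the module's 10 *hidden* members, i.e. the method recovered an
unobserved disease-module gene. Enriching the seed list against the
generated annotations,

```sh
python -c "import networkx as nx; \
  print('\n'.join(sorted(nx.read_graphml('ci.graphml').nodes)))" > universe.txt
seedmodule enrich --query fixtures/seeds_module0.txt \
  --gmt fixtures/annotations.gmt --universe universe.txt --out enrich.tsv
```

reports `21 sets tested; top: GS000 (overlap 8, p_adj 4.45e-08)` — the
planted set ranks first. The full workflow (consolidate → PH and fibrosis
reference networks → query network → partition → two enrichment rounds) runs
from one YAML config via `seedmodule run --config run.yaml`, writing GraphML
networks, TSV enrichment tables and a JSON run report.

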