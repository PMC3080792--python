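# membranome

Systems-analysis toolkit for subcellular proteomes ("membranomes"): ontology
enrichment with a hypergeometric Z-score, recursive category-tree mining,
quantitative membrane/homogenate (P/H) ratio classification, and
protein-interaction network statistics — with seeded synthetic-data
generators so the whole pipeline runs and tests at desk scale with no
downloads.

## What it does

- **`membranome.ontology`** — parses OBO 1.2/1.4 ontologies into a rooted
  DAG, parses GAF-style protein→term TSVs, and applies true-path
  propagation (a protein annotated to a term is annotated to all its
  ancestors).
- **`membranome.enrichment`** — scores each category with
  `z = (a − nA/N) / sqrt(n·(A/N)(1−A/N)·(N−n)/(N−1))` where `a`/`n` count the
  sampled proteins and `A`/`N` the annotated universe; `|z| ≥ 2` marks
  significant enrichment/depletion. Exact hypergeometric tail probabilities
  and BH q-values are emitted alongside.
- **`membranome.mining`** — expands general categories (direct children of a
  namespace root) downward: positive-z nodes expand by default, a force list
  lets you descend into depleted branches, and the report singles out
  "actual enriched" terms — the terminal enriched refinement along each
  path. Custom curated categories can be injected as new general categories.
- **`membranome.quant`** — P/H ratio computation and classification
  (enriched > 1, depleted < 1, `inf` = detected in membrane fraction only),
  declarative filtering, and compartment summaries. Three small reference
  tables ship in `membranome/data/`.
- **`membranome.network`** — simple-graph construction from edge TSVs,
  merging, edge/node ratios, isolated/missing molecule accounting,
  quantitative node overlays, induced subnetwork extraction, and the
  network score `−log10` of a right-tailed Fisher exact probability.
- **`membranome.synth`** — deterministic generators for ontologies,
  annotation universes, membranomes with planted per-term enrichment odds,
  quant tables with planted membrane fractions, and stochastic-block-model
  interactomes, all with recorded ground truth.

## CLI

```bash
membranome demo --seed 1 --out demo_out      # synthetic end-to-end run
membranome synth --seed 1 --out inputs      # generate synthetic input files
membranome parse-check inputs/ontology.obo --annotations inputs/annotations.tsv
membranome enrich OBO ANNOTATIONS PROTEINS   # per-term TSV to stdout
membranome mine OBO ANNOTATIONS PROTEINS --format tree
membranome quant QUANT_TSV                   # ratio-class summary JSON
membranome network EDGES_TSV [EDGES_TSV...]  # merged-graph statistics
membranome run config.yaml --out results     # full pipeline from YAML config
```

`demo` is fully deterministic: the same seed yields byte-identical artifact
sets (enrichment/mining reports, quant summary, network report, and a
manifest with sha256 checksums of every input and output).

A run config looks like:

```yaml
obo: inputs/ontology.obo
annotations: inputs/annotations.tsv
membranome: inputs/membranome.txt
quant: inputs/quant.tsv
edges: [inputs/edges.tsv]
z_threshold: 2.0
max_depth: 10
force_expand: ["SYN:L1N00002"]
```

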