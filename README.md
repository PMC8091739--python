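# pin2target

Drug-target prioritization from a directed protein-interaction network
(PIN), plus overlap-based drug repositioning and gene-set
over-representation analysis.

The pipeline:

1. **Embed** — a symmetric deep autoencoder (ReLU hidden layers, sigmoid
   output, binary cross-entropy, Adam) compresses each gene's binary
   adjacency row into a low-dimensional latent vector. Full-scale
   reference architecture: encoder 6338-3000-1500-500-250-150-100 with a
   mirrored decoder.
2. **Characterize** — eleven per-gene topology values: indegree, outdegree,
   betweenness, closeness, PageRank, clustering coefficient,
   nearest-neighbor degree, one-hot bow-tie layer (input/core/output), and
   a controllability-based indispensability flag (a gene is indispensable
   if deleting it increases the minimum driver-node count
   `ND = max(N - maximum_matching, 1)`). Latent dimensions are compared to
   the metrics by Spearman correlation.
3. **Prioritize** — resampled datasets (all known positive genes + uniform
   negative samples) are class-balanced with a from-scratch SMOTE (k=2),
   then grid-searched gradient-boosted classifiers are fitted with
   stratified 5-fold CV. Fold splits happen **before** oversampling, so no
   synthetic row ever reaches a validation fold (asserted via row
   provenance). Genes are ranked by the ensemble's mean positive-class
   probability; the putative target set is everything strictly above 0.75.
4. **Reposition** — drugs are ranked by the overlap between their known
   targets and the putative set; any drug with a non-empty overlap is a
   candidate.
5. **Enrich** — local hypergeometric over-representation analysis against
   GMT gene-set collections with Benjamini-Hochberg FDR (significant at
   FDR < 0.05).

A seeded synthetic-data module (scale-free directed PIN via preferential
attachment, a planted cohesive positive class, drug->target maps, GMT
collections) makes the whole pipeline testable without external downloads.

## CLI

Everything is driven by one YAML config:

```yaml
seed: 1
outdir: out
synthetic:              # or an `inputs:` block with real file paths
  n_nodes: 500
  n_positives: 30
  positive_cohesion: 0.9
autoencoder:
  profile: desk         # desk = lr 1e-3 / 200 epochs; paper = lr 1e-6 / 10000
  d_latent: 16
  n_layers: 4
prioritizer:
  n_datasets: 10
  n_negatives: 200
```

```bash
pin2target run -c config.yml                 # full pipeline
pin2target simulate -c config.yml            # or any single stage:
pin2target embed|metrics|prioritize|reposition|enrich -c config.yml
pin2target run -c config.yml --seed 7 --outdir elsewhere --profile paper
```

`run` writes: graph summary, latent matrix, metric table, latent-metric
correlations, ranked gene scores, putative target list, repositioning
table, enrichment table, and a manifest (config hash, seed, versions,
stage timings). Stage subcommands recompute deterministically from the
config, so their artifacts byte-match the full run's.

For real inputs, supply:

```yaml
inputs:
  edge_list: pin_edges.tsv      # source<TAB>target, '#' comments ignored
  drug_targets: drugs.tsv       # drug<TAB>target[<TAB>indication]
  positives: known_targets.txt  # one gene per line
enrichment:
  gmt: pathways.gmt
```

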