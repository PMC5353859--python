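# secrepath

A toolkit for curated secretory-pathway network catalogues and the omics
analyses built on top of them:

- **Catalogue & network model** (`secrepath.catalogue`, `secrepath.network`)
  — typed components with subsystem / functional-group / complex membership
  and evidence flags; a heterogeneous network of component, complex,
  functional-group, and isoprotein nodes; export to SIF, node-attribute TSV,
  and GraphML (Cytoscape-compatible).
- **Homology transfer** (`secrepath.homology`) — project a reference-species
  catalogue onto a target species from 12-column tabular alignment output,
  with tiered acceptance rules (high-identity tier, moderate tier requiring
  a bitscore floor and a significant e-value, pseudogene exclusion, partial
  flags).
- **Expression** (`secrepath.expression`) — CPM with plain or TMM-effective
  library sizes, "CPM ≥ c in ≥ k samples" filtering, Benjamini–Hochberg
  adjustment and DE status flagging, and culture growth metrics
  (μ, doubling time, cell-specific productivity).
- **Clustering** (`secrepath.clustering`) — Spearman-distance average-linkage
  trees with deterministic tie-breaking, plain bootstrap probabilities (BP)
  by column resampling, approximately-unbiased (AU) p-values via the
  multiscale bootstrap, and maximal significant-cluster extraction at a
  configurable α.
- **Regulator screen** (`secrepath.regulators`) — rank every gene by the
  summed Spearman correlation (and squared correlation) to a seed cluster to
  nominate correlated and anti-correlated regulator candidates.
- **Phenotype correlation** (`secrepath.phenotype`) — per-gene Spearman and
  Pearson correlation to phenotype vectors (growth rate, productivity) with
  a data-driven mean ± 2 SD significance rule.
- **Network overlay** (`secrepath.overlay`) — colour nodes on a continuous
  log2FC gradient, thick borders for FDR < 0.05, and score complexes /
  functional groups / subsystems for coordinated regulation with a one-sided
  Fisher exact test (no fold-change cut-off: coordinated sub-twofold shifts
  are the point), reported with −log10 p and BH q.
- **Synthetic data** (`secrepath.simulate`) — seeded generators for modular
  expression (latent-factor model), negative-binomial counts, phenotype
  vectors with planted correlations, and toy catalogues / interaction lists /
  alignment hit tables, all with truth tables for scoring.
- **Pipeline** (`secrepath.pipeline`, `secrepath.cli`) — a configured,
  pre-flight-validated, seeded end-to-end run.

## CLI

```bash
secrepath simulate --genes 1000 --samples 24 --modules 4 --module-size 25 --out demo
secrepath network build --catalogue demo/catalogue.tsv \
    --interactions demo/interactions.tsv --drop-isolated --out net
secrepath transfer --catalogue demo/catalogue.tsv --hits demo/hits.tsv --out transfer
secrepath expr normalize --counts demo/counts.tsv --out cpm.tsv
secrepath expr filter --cpm cpm.tsv --out filtered.tsv
secrepath cluster --expr filtered.tsv --nboot 1000 --seed 17 --out clusters
secrepath regulators --expr filtered.tsv --seed-genes seeds.txt --top 10 --out regs
secrepath phenocorr --expr filtered.tsv --phenotypes demo/phenotypes.tsv --out pheno.tsv
secrepath overlay --catalogue demo/catalogue.tsv --dge dge.tsv --kind complex --out overlay
secrepath run --config config.yaml   # all stages, one seeded run
```

`config.yaml` is a flat key-value file mirroring the fields of
`secrepath.pipeline.PipelineConfig` (paths, stage list, thresholds, seed).

## File formats

All I/O is plain text: catalogue TSV (multi-valued cells `";"`-separated),
interaction TSV (`source  class  target  directed  provenance`), 12-column
alignment tabular with optional partial/pseudogene flag columns, genes ×
samples count/expression TSVs, 3-column SIF, GraphML, and Newick trees with
AU support as internal node labels.

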