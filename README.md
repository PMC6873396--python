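# tacitus

A toolkit for managing and integrating transcriptomic expression datasets:

- **io_formats** — readers/writers for GEO-style series matrix files,
  MAGE-TAB (SDRF + data matrix), platform annotation tables, and a fixed
  TSV/CSV export dialect (first line = sample names, one probe per row).
- **store** — a file-backed dataset repository (plain TSV + JSON, one
  directory per accession) with a sample index (sample → matrix column),
  a metadata index (attribute list), a native inverted full-text index
  over sample metadata, and streaming sample selection whose peak memory
  is one matrix row.
- **idmap** — probe → standard identifier mapping (e.g. Entrez) built from
  platform annotation; unmapped probes are dropped, many-to-one collisions
  resolved by `mean` / `first` / `max_mean`.
- **integrate** — merge selections (gene-set intersection, sample
  concatenation with duplicate-id suffixing) and apply one of five
  methods: `none` (passthrough), `sims` (per-dataset gene mean-centering),
  `genestd` (per-dataset gene z-scoring), `combat` (parametric
  empirical-Bayes location/scale batch correction), `xpn` (pairwise block
  normalization via gene/sample clustering). Count data are converted to
  log2-CPM before Gaussian-scale methods.
- **simeval** — synthetic benchmark: simulate microarray-like (Gaussian)
  or NGS-like (negative-binomial) two-condition data with known DEG
  truth, randomly partition, integrate, call DEGs with an empirical-Bayes
  moderated t-test, and score with ROC/AUC.

## CLI

The console script `tacitus` ties the stages together
(import → search → select → map → integrate → simulate/benchmark):

```sh
tacitus import --store ./store --accession GSE1 --format series-matrix --matrix series.txt
tacitus search --store ./store --accession GSE1 --query "h460 lung"
tacitus select --store ./store --accession GSE1 --samples GSM1,GSM3 --name sel1
tacitus map --store ./store --accession GSE1 --selection sel1 \
    --annotation ann.txt --probe-column ID --id-column ENTREZ_GENE_ID=ENTREZ_GENE_ID \
    --namespace ENTREZ_GENE_ID --out mapped/
tacitus integrate --store ./store --selection GSE1:sel1 --selection GSE1:sel2 \
    --method combat --out integrated/
tacitus benchmark --kind ngs --methods baseline,combat --replicates 10 --seed 1 --out bench/
```

A `key=value` config file can supply defaults (`--config run.conf`);
explicit flags win. Exit codes: 0 OK, 1 operation error, 2 usage error.

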