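# dcgnet

Differential-connectivity gene network analysis. Given two-condition
(e.g. normal vs cancer) log2 expression data, `dcgnet`:

1. calls per-dataset differentially expressed genes (Welch t-test,
   Benjamini–Hochberg adjustment, strict fold-change 2.0 / 0.5 and adjusted-p
   0.01 thresholds) and intersects them across datasets into *mutual DEGs*;
2. fits an independent shrinkage Gaussian graphical model per condition
   (analytic shrinkage of the sample correlation matrix toward the identity,
   partial correlations from its inverse) and keeps the top-ranked edges
   (default 1500, ranked by |partial correlation|);
3. computes exact betweenness centrality (Brandes) on each network, takes the
   top 40% of each ranking, removes the cross-condition overlap, and reports
   the remaining cancer-side genes as **differentially connected genes
   (DCGs)** — condition-specific hubs;
4. characterizes a gene set via curated-list overlaps, hypergeometric
   over-/under-representation against GMT collections, and TF-regulon lookup
   from a TRRUST-style TF–target–mode table.

A synthetic-data module generates multi-dataset two-condition studies from
planted sparse precision matrices with known hubs and expression shifts, so
every stage has a recoverable ground truth.

## CLI

One entry point, `dcgnet`, with subcommands
`simulate`, `deg`, `intersect`, `ggm`, `centrality`, `dcg`,
`overlap`, `enrich`, `regulators`, `pipeline`. Exit codes: 0 ok,
1 usage error, 2 data error. A typical synthetic round trip:

```bash
dcgnet simulate --n-genes 60 --n-de-genes 60 --seed 1 --out-prefix sim
dcgnet deg sim.expression.tsv sim.annotation.tsv --out de.tsv
dcgnet intersect de.tsv --out mutual.txt
dcgnet ggm sim.expression.tsv sim.annotation.tsv --condition cancer \
       --genes mutual.txt --out-edges cancer.edges.tsv
dcgnet ggm sim.expression.tsv sim.annotation.tsv --condition normal \
       --genes mutual.txt --out-edges normal.edges.tsv
dcgnet centrality cancer.edges.tsv --universe mutual.txt --out cancer.bc.tsv
dcgnet centrality normal.edges.tsv --universe mutual.txt --out normal.bc.tsv
dcgnet dcg cancer.bc.tsv normal.bc.tsv --fraction 0.40 --out dcgs.txt
```

or everything at once from a YAML config (`dcgnet pipeline run.yaml`):

```yaml
top_edges: 1500
fraction: 0.40
out_dir: out
simulate: {n_genes: 60, n_de_genes: 60, seed: 1}
```

An empty config file means all defaults (fold-change thresholds 2.0/0.5,
alpha 0.01, 1500 edges, top fraction 0.40). Real data enters as an
expression TSV (first column `gene`, one column per sample) plus a sample
annotation TSV (`sample_id`, `condition`, `dataset_id`) via the `datasets:`
config key or the per-stage subcommands.

## Layout

- `src/dcgnet/simulate.py` — planted precision models, study simulation, writers
- `src/dcgnet/diffexpr.py` — fold change, Welch test, BH, DEG calls, intersection
- `src/dcgnet/ggm.py` — shrinkage correlation, partial correlations, edge ranking
- `src/dcgnet/centrality.py` — graph building, Brandes betweenness, ranking
- `src/dcgnet/dcg.py` — top-fraction cut, overlap removal, pipeline orchestration
- `src/dcgnet/annotate.py` — GMT/regulon/gene-list IO, overlaps, hypergeometric tests
- `src/dcgnet/config.py`, `src/dcgnet/io.py`, `src/dcgnet/cli.py` — config, TSV IO, CLI
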