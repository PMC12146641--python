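# creglink

A self-contained toolkit for comparative gene-regulation analysis of
single-cell multiome (joint RNA + ATAC) data:

- **Per-sample processing** — six-criteria cell QC (RNA/ATAC read windows,
  nucleosome signal < 2, TSS enrichment > 1), log-normalization (scale
  10,000), variable-feature selection, scaling, PCA; ATAC feature matrix
  from a fragments file, TF-IDF, LSI; joint SNN clustering (Louvain,
  resolution 1) and reference-based cell-type annotation (Spearman over
  top variable genes).
- **CRE–gene linkage** — for each gene, peaks within 50 kb of the TSS are
  scored by Pearson correlation of log-normalized accessibility and
  expression; significance comes from a z-test against 200 background
  peaks matched on accessibility, width and (optionally) GC content.
- **Cross-sample comparison** — union CRE sets (maximal half-open
  interval merge), linkage remapping, tissue-presence histograms,
  tissue-specific gene-linked CREs (present in more than half of the
  target tissue's samples and fewer than half of every other tissue's),
  cell-type-restricted variants, and a gene-centered region view with
  depth-normalized per-group coverage tracks.
- **TF enrichment** — one-sided Fisher exact over-representation of TF
  ChIP-seq peak sets in a query CRE set against a background universe,
  BH-adjusted and ranked.
- **Synthetic data** — a Poisson-lognormal multiome simulator that plants
  CRE–gene links with a calibrated target correlation, tissue-specific and
  shared links across a multi-tissue corpus, and enriched/decoy TF peak
  sets, with exact ground truth for every planted structure.

## CLI

The pipeline runs over a plain-file run directory with a `manifest.json`:

```sh
creglink simulate --preset tiny --seed 7 --run runs/demo
creglink qc       --run runs/demo
creglink process  --run runs/demo            # + optional --reference ref.tsv
creglink link     --run runs/demo
creglink union    --run runs/demo
creglink presence --run runs/demo
creglink specific --run runs/demo --gene gene0003 --tissue tissue0
creglink tfenrich --run runs/demo --tf-peaks tf_beds/ --cres query.bed
creglink regionview --run runs/demo --sample tissue0_s0 --gene gene0003
```

Parameters (QC thresholds, linkage window/cutoffs, bin sizes, ...) can be
overridden with a flat `key = value` config file passed via `--config`;
unknown keys are rejected. See `creglink.cli.CONFIG_DEFAULTS` for the
schema.

## File formats

BED (3+ columns), 5-column fragments TSV (plain or gzip), MatrixMarket
MTX + feature/barcode lists, GTF or minimal gene TSV
(`gene,chrom,start,end,strand`, 0-based half-open), linkage TSV
(`gene_id chrom start end score zscore pvalue sample_id`), bedGraph
tracks. All internal coordinates are 0-based half-open; GTF is converted
at the boundary.

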