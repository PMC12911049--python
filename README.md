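# sexbias

A tested, reusable pipeline for sex-bias analysis of cancer transcriptomes:

- **Bulk sex-differential expression** (`sexbias.de`): low-expression
  filtering, median-of-ratios size factors, per-feature negative-binomial
  GLM with a Wald test on sex (male vs female; positive log2FC = higher in
  males), optional clinical covariates, Benjamini-Hochberg correction, and
  PCA QC. Significance: adjusted p < 0.05 and |log2FC| > 0.58.
- **Tumor-specific sex-biased (TSSB) sets** (`sexbias.tssb`): partition of
  tumor/normal DE features into tumor-specific, normal-specific,
  shared-concordant and shared-reversed; TSSB = tumor-specific plus
  shared-reversed, with chromosome-distribution summaries.
- **miRNA-mRNA pair filtering** (`sexbias.pairs`): validated-interaction
  parsing (direct evidence only), a log2(normalized + 1)
  variance-stabilizing transform, sex-stratified Pearson correlation in
  tumor samples, retention of significantly negative pairs in at least one
  sex, four-way direction-concordance classification, and SIF/GraphML
  network export.
- **Sex-stratified survival** (`sexbias.surv`): within-sex median
  dichotomization, Kaplan-Meier / log-rank, univariate Cox (Efron ties),
  favored/unfavored labels, and a male-only / female-only / both / neither
  cross-sex partition.
- **Enrichment** (`sexbias.enrich`): hypergeometric over-representation
  against user-supplied GMT collections (reported at padj < 0.05 and
  overlap >= 2).
- **Single-cell expression** (`sexbias.sc`): QC filtering (mito > 10%,
  UMI < 1000, features < 300 or > 6000), log-normalization, and
  per-cell-type Wilcoxon sex-DE on a gene panel.
- **Synthetic cohorts** (`sexbias.synth`): seeded generators for bulk
  mRNA/miRNA counts with planted sex-biased features and planted
  miRNA-mediated repression, sex-specific survival times, and single-cell
  UMI matrices with planted QC violations — every downstream stage is
  testable without any data download.
- **Orchestration** (`sexbias.pipeline` / `sexbias run`): end-to-end runs
  from one YAML config with a checksummed manifest.

## CLI

```bash
# simulate a synthetic cohort with planted ground truth
sexbias simulate --seed 17 --outdir sim/

# sex-DE per tissue
sexbias de --counts sim/mrna_counts.tsv --samples sim/samples.tsv \
    --tissue tumor --covariates age,stage,grade --out de_tumor.tsv
sexbias de --counts sim/mrna_counts.tsv --samples sim/samples.tsv \
    --tissue normal --covariates age --out de_normal.tsv

# TSSB construction
sexbias tssb --tumor de_tumor.tsv --normal de_normal.tsv \
    --annot sim/features.tsv --out tssb.tsv

# pair filtering, survival screen, enrichment, single-cell DE
sexbias pairs --help
sexbias survival --help
sexbias enrich --help
sexbias sc-de --help

# or everything at once from a config
sexbias run --config run.yaml
```

A minimal `run.yaml`:

```yaml
outdir: run
seed: 17
stages: [simulate, de, tssb, pairs, survival, sc]
cohort: {n_male_tumor: 60, n_female_tumor: 60}
```

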