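# factorde

Analysis toolkit for log2 gene-by-sample expression matrices from factorial
designs (exposure × genotype × sex, at one or two exposure durations):

- **Per-gene linear models** (`factorde.linmod`): ordinary least squares on a
  0/1-coded additive design; per-factor Benjamini–Hochberg q values; genes
  called significant at q < 0.05 with |β| > log2(1.3) by default. Positive β
  means higher in smoke / bENaC / male.
- **Interaction testing** (`factorde.linmod.fit_interaction_models`): post-hoc
  exposure × duration model over response genes, flagging duration-dependent
  responses.
- **Gene-set association** (`factorde.gsa`): per-gene signed −log(p)
  statistics, set scores = Σ stats / √m, calibrated by refitting the full
  model under permutations of sample labels with per-tail plug-in FDR
  thresholds.
- **Overlap enrichment** (`factorde.enrich`): exact hypergeometric enrichment
  of a gene list against a GMT collection, and one-sided Fisher tests between
  two lists. The universe size is always an explicit argument.
- **Clustering** (`factorde.cluster`): best-of-restarts k-means over genes,
  elbow curves, and hierarchical gene/sample ordering (Euclidean within
  clusters, Pearson 1 − r across samples) for heatmap export. The pipeline
  centers each gene before clustering; pass `--scale` to also unit-scale.
- **Response-set algebra** (`factorde.sets`): duration partitioning with
  inclusion–exclusion counts, mutually exclusive cross-factor breakdowns, and
  cross-duration β correlation/regression with confidence and prediction
  bands.
- **Synthetic data** (`factorde.simulate`): full-factorial designs with
  additive per-gene effects, optional exposure × duration interactions,
  Gaussian noise, and gene sets with known enrichment labels — ground truth
  for every downstream stage.

## CLI

The `factorde` entry point has subcommands `simulate`, `fit`, `interaction`,
`cluster`, `gsa`, `enrich` and `compare-durations`. Each accepts `--config`
(YAML or flat `key=value`) for defaults plus explicit flag overrides, and
logs the effective configuration, seed and input digests with `-v`.

```sh
factorde simulate --out-dir data --n-per-cell 5 --n-genes 2000 --seed 1
factorde fit --expr data/expression.tsv --design data/design.tsv \
    --duration 1 --out effects_day1.tsv
factorde fit --expr data/expression.tsv --design data/design.tsv \
    --duration 5 --out effects_day5.tsv
factorde interaction --expr data/expression.tsv --design data/design.tsv \
    --effects-day1 effects_day1.tsv --effects-day5 effects_day5.tsv \
    --out interaction.tsv
factorde cluster --expr data/expression.tsv --out-dir clusters --k 5 \
    --restarts 50 --seed 1 --elbow
factorde gsa --expr data/expression.tsv --design data/design.tsv \
    --gmt data/gene_sets.gmt --out-dir gsa --duration 1 --nperm 1000 --seed 1
factorde enrich --query genes.txt --gmt data/gene_sets.gmt \
    --universe-size 2000 --out enrichment.tsv
factorde compare-durations --effects-day1 effects_day1.tsv \
    --effects-day5 effects_day5.tsv --interaction interaction.tsv \
    --out-dir compare
```

File formats: expression matrices are TSV with a `gene_id` first column and
sample columns; designs are TSV/CSV with `sample_id`, `exposure`
(sham/smoke), `genotype` (WT/bENaC), `sex` (female/male), `duration_days`
(1/5); gene sets are standard GMT. Missing values are rejected, not imputed.

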