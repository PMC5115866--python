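# ppilr

Likelihood-ratio evidence integration for protein–protein interaction
networks: a library and CLI for training bin-based likelihood-ratio (LR)
models per evidence channel, combining them naive-Bayes style into a total
LR per protein pair, and evaluating the resulting network.

## What it does

- **Core model** (`ppilr.core`): bin partitions (categorical, interval,
  grid), per-channel binned LR estimation from labelled positive/negative
  reference pairs, naive-Bayes combination across channels
  (`max(SM, PrP) x PR x GO x PP x OR x EP`, absent channels neutral), and a
  strict reliability cutoff (LR > 600 by default).
- **Orthology channel** (`ppilr.orthology`): four-source {0, 1, >1}
  interaction vectors counting the species in which orthologs of a pair
  interact, scored with dimensional backoff to smaller source subsets when
  a bin lacks training support.
- **Partner redundancy** (`ppilr.partner_redundancy`): (n, d)-binned
  first network (structural neighbours of A known to bind B, B's known
  degree) with an m-binned any-species second network as fallback.
- **Expression channel** (`ppilr.expression`): consistency-rewarding
  consolidation of per-dataset Pearson correlations (`s_pos`/`s_neg`,
  majority-sign rule) and the human/cross-species blend `coxs` with
  damping weight w = 0.6.
- **Evaluation** (`ppilr.evaluation`): ROC curves (TPR/FPR over strict
  thresholds, rank-statistic AUC), recovery fractions, compartment-crossed
  negative-set construction, shared-annotation fractions, LR-binned
  positive-probability curves, complex recovery (bottleneck connectivity
  threshold), size-matched random-complex nulls, and seeded complex-member
  prediction.
- **GSEA annotation** (`ppilr.gsea`): weighted running-sum enrichment of
  gene sets at the top of a query's LR-ranked interactor list, with
  label-permutation p-values and Benjamini–Hochberg q-values (q < 0.01
  flags enrichment).
- **Variant–interface enrichment** (`ppilr.snp`): 2x2 residue contingency
  tables (interfacial x mutated), cross-product odds ratio, log-odds
  standard error, and Z-score.
- **Synthetic world** (`ppilr.synthetic`): a seeded generator that emits
  every input the stack consumes (evidence tables, ortholog maps,
  correlation tables, neighbourhoods, reference splits, complexes, gene
  sets, compartments, interface/variant placements with a planted
  enrichment), built on a stochastic block-model interaction graph.
- **Pipeline + I/O + CLI** (`ppilr.pipeline`, `ppilr.io`, `ppilr.cli`):
  feature assembly, training, scoring, TSV/GMT/JSON readers and writers.

## CLI

```sh
ppilr simulate --seed 1 --n-proteins 400 --n-modules 20 --out world/
ppilr train    --world world/ --out models.json
ppilr score    --world world/ --models models.json --out scores.tsv
ppilr evaluate --scores scores.tsv \
               --positives world/eval_positives.tsv \
               --negatives world/eval_negatives.tsv --out-dir eval/
ppilr complexes --scores scores.tsv --complexes world/complexes.tsv \
                --out-dir cplx/ --seed 0
ppilr annotate --scores scores.tsv --query P00001 \
               --gene-sets world/gene_sets.gmt --out annot.tsv
ppilr snp-or   --interfaces world/interfaces.tsv \
               --variants world/variants.tsv --out snp_report.tsv
```

`snp-or` also accepts `--counts-tsv` with a single row of `n11 n10 n01 n00`
columns. All outputs are tab-separated with headers; existing files are
never overwritten without `--force`; every command is deterministic for a
fixed seed.

## File formats

Tabular inputs are TSV with a header row; empty cells mean "absent":
evidence (`protein_a`, `protein_b`, one column per supplied channel), pair
lists, ortholog maps (`source`, `protein_id`, `species`, `ortholog_id`),
per-dataset correlations, complex membership, interface masks and variant
positions. Gene sets use GMT; trained models and world manifests are JSON.
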