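# palgraph

Interactome-based deduction of seed-gene molecular pathways and evaluation of
their activation levels as tumor grade and survival biomarkers, for bulk
RNA-seq cohorts with clinical annotation.

## The problem

Single-gene expression is often a weak biomarker: one read-out, full exposure
to gene-level measurement noise. An alternative is to score the *molecular
pathway* around a gene of interest. Starting from a collection of curated
pathways (named topologies whose nodes are gene products or multi-gene
complexes, connected by typed directed interactions — activation, inhibition,
phosphorylation, binding/association, …), `palgraph`:

1. **merges the collection into one interactome graph**, joining nodes with
   identical member-gene sets and deduplicating typed edges;
2. **deduces a seed-gene pathway** as the induced subgraph of all nodes within
   k interaction steps of the seed (k = 1, 2, 3 give three nested variants),
   and assigns each gene an *activator/repressor role* (ARR) in
   {−1, −0.5, 0, 0.5, 1} by propagating interaction signs along directed
   paths from the seed;
3. **scores per-sample pathway activation levels.** With CNR_n the
   case-to-normal ratio of gene *n* (normalized expression over the averaged
   tumor sample of the dataset, geometric mean by default),

   PAL_p = 100 · Σ_n ARR_np · lg(CNR_n) / Σ_n |ARR_np|

   so PAL > 0 means net pathway up-regulation relative to the cohort average;
4. **evaluates the candidate biomarkers** (seed-gene expression, PAL1-3) the
   way glioma biomarker studies do: Welch t-test and ROC AUC for LGG/GBM
   grade discrimination; median-split Kaplan–Meier with log-rank tests over a
   dataset × grade × endpoint (OS/PFS) × molecular-subgroup grid
   (IDH mutation, 1p/19q codeletion, MGMT methylation; subgroups under 10
   samples excluded), Benjamini–Hochberg FDR across the candidate biomarkers
   within each cell, and univariate/multivariate Cox hazard ratios.

Because curated pathway collections and patient-level cohorts are usually
access-controlled, the package ships a first-class synthetic-data module:
negative-binomial counts with a planted pathway shift between grades,
exponential survival whose hazard follows the latent pathway activity, and
grade-linked IDH/MGMT/1p19q covariates — with the ground truth returned, so
every stage of the pipeline is testable end to end.

## Worked example

```bash
palgraph simulate --seed 7 --out fixture --n-genes 2000 --n-lgg 120 --n-gbm 80 --log2fc 1.5
palgraph deduce --pathways fixture/pathways.json --seed FREM2 --order 2 --out frem2_order2.json
# -> order 2: 8 nodes, 7 edges, 17 genes -> frem2_order2.json

cat > run.yaml <<EOF
pathways: fixture/pathways.json
seed_gene: FREM2
datasets:
  - label: sim
    counts: fixture/counts.tsv
    clinical: fixture/clinical.tsv
outdir: out
seed: 7
EOF
palgraph run-all --config run.yaml
```

`out/discrimination.tsv` then holds the grade-discrimination table (this is
the actual output for the command above):

```
dataset  biomarker   t      p          auc    n_gbm  n_lgg
sim      FREM2_expr  13.81  6.50e-30   0.925  80     120
sim      PAL1        18.03  1.08e-40   0.964  80     120
sim      PAL2        20.15  1.07e-45   0.981  80     120
sim      PAL3        21.28  1.18e-48   0.985  80     120
```

All three pathway variants discriminate the two grades better than the seed
gene's own expression (AUC 0.96–0.99 vs 0.92): the pathway score averages the
planted fold-change over many genes, suppressing gene-level counting noise.
`out/grid_summary.tsv` summarizes the survival grid per biomarker
(comparisons evaluated, cells significant after per-cell FDR, mean
log10 q-value); `out/grid.tsv` has every cell with log-rank p, q, and the
high-vs-low hazard ratio, and `out/km_curves.tsv` exports the Kaplan–Meier
step-curve coordinates for plotting.

The library mirrors the CLI one-to-one (`palgraph.merge_pathways`,
`deduce_variants`, `compute_pal`, `run_comparison_grid`, …); see the module
docstrings.

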