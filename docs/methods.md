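# Methods

This note documents the models, conventions and numerical choices behind
`palgraph`, and what the synthetic-data generator does and does not emulate.

## Pathway collections

A pathway is a directed multigraph whose nodes hold one or more gene products
(a multi-gene node models a complex such as "extracellular matrix"). Exactly
nine interaction types are admitted: activation, compound, inhibition,
phosphorylation, dissociation, repression, dephosphorylation,
binding/association, ubiquitination. Binding/association and compound denote
direction-free relations; they are stored as written with a symmetric flag
that all traversals honor. Gene identity is exact string match after
upper-casing (HGNC-style symbols); alias resolution is out of scope. The
on-disk dialect is JSON (with a three-table TSV alternative) because the
upstream curated formats are proprietary — only the content matters, not the
syntax. Duplicate (source, target, type) triples within one pathway are
collapsed at load time with a warning; duplicates across pathways are
resolved at merge time.

## Interactome construction

Pathways are merged on coinciding gene products: two nodes are the same
interactome node iff their member-gene sets are identical. Merging complexes
by display label across source databases would silently conflate different
assemblies, so it is deliberately not done. Edges are the union of typed
interactions between merged nodes, deduplicated by (source, target, type)
with full pathway provenance retained; conflicting types between the same
node pair (activation in one pathway, inhibition in another) are kept as
parallel typed edges rather than reconciled — any reconciliation rule would
invent evidence.

Graph statistics follow the conventions that make the printed interactome
bookkeeping self-consistent: average vertex degree is edges per node (E/N;
at 7152 nodes and 298,824 typed directed edges this gives 41.8 ≈ 42, whereas
2E/N would give 84), and density uses the undirected-pair denominator
E/(N(N−1)/2) (0.0117 ≈ 0.01 at that scale; the directed-pair convention also
rounds to 0.01, so the choice is cosmetic at realistic sparsity).
Connectivity is assessed on the undirected view of the graph.

## Seed-gene pathway deduction

The order-k variant of a seed gene's pathway is the subgraph induced by all
nodes within BFS distance k of any node containing the seed. Traversal
ignores edge direction by default — an interaction *with* the seed counts
whichever way the arrow points — because curated collections frequently
catalogue only one direction of a physically mutual interaction. A
`downstream_only` mode restricts traversal to outgoing and symmetric edges
for seeds known to have no cataloged upstream regulators. The induced rule
(keep *all* edges between retained nodes, not just the BFS tree) makes the
variant a faithful excerpt of the interactome. Orders nest by construction:
nodes(k) ⊆ nodes(k+1).

### Activator/repressor roles

Each interaction type carries a sign (default: activation and
phosphorylation +1; inhibition, repression, dephosphorylation and
ubiquitination −1; compound, binding/association and dissociation 0), fully
user-overridable — the sign table is configuration, not hard-coded truth. A
directed path's sign is the product of its edge signs; a path through a
0-sign edge is *ambiguous*. For each gene, all node-simple directed paths of
length ≤ k from the seed node to every node containing the gene are
enumerated (symmetric edges traversable both ways; enumeration capped at
10,000 paths per gene, raising an explicit error rather than silently
truncating). The gene's ARR is then

* +1 / −1 when every path is positive / negative (no ambiguity),
* +0.5 / −0.5 when one sign holds a strict majority among all paths
  (ambiguous paths count in the denominator),
* 0 on ties, all-ambiguous evidence, or when no directed path of length ≤ k
  exists (the node entered the neighborhood against edge direction).

The seed gene and genes sharing its node get +1. Path length is capped at
the variant's order so a gene's role reflects the interactions that brought
it into the pathway. One parity caveat: flipping every entry of the sign
table negates each *edge* sign, hence negates path signs only for odd-length
paths; the "global flip negates ARR" identity therefore holds exactly at
order 1 but not in general at higher orders.

## Expression scoring

* **Normalization** is the median-of-ratios size-factor method: per sample,
  the median over genes with all-positive counts of count / per-gene
  geometric mean across samples. It assumes most genes are not
  differentially expressed.
* **CNR** (case-to-normal ratio) divides each (normalized value + 1
  pseudocount) by the control level of that gene. The control is the
  dataset's averaged tumor sample; the geometric mean is the default because
  log-ratios against a geometric mean are exactly mean-zero, matching PAL's
  log formulation (an arithmetic-mean control is available by
  configuration). The pseudocount of 1 handles zero counts. The control is
  computed over all tumor samples of the dataset, LGG and GBM jointly;
  restricting it per grade would shift every PAL by a grade constant and is
  left to the caller.
* **PAL** = 100 · Σ ARR·log10(CNR) / Σ|ARR| over the pathway genes measured
  in the matrix ("lg" read as log10; base configurable). Pathway genes
  absent from a dataset are skipped and counted, not fatal — real cohorts
  sequence different gene panels. Exact identities that the tests enforce:
  PAL = 0 for a sample equal to the control; scaling one sample's CNRs by c
  shifts its PAL by 100·log10(c)·ΣARR/Σ|ARR|; negating all ARRs negates
  PAL; cohort-mean PAL is 0 under the geometric control.

Datasets are always processed independently (no cross-dataset normalization
or pooling) because batch effects between cohorts dominate biological signal
in practice.

## Biomarker evaluation

Scalar machinery is delegated to the standard stack — Welch t-test (scipy),
Mann–Whitney AUC with ties at 0.5 (scikit-learn), Kaplan–Meier/log-rank/Cox
(lifelines, Efron tie handling, Wald 95% CIs), Benjamini–Hochberg
(statsmodels), Kruskal–Wallis and point-biserial correlation (scipy) — while
this module owns the study conventions:

* **median split**: high ⇔ strictly above the median, low ⇔ at or below; a
  split leaving fewer than two samples on a side makes the comparison
  unevaluable (recorded with its reason, never silently dropped);
* **AUC orientation** is fixed (GBM, or the stated positive class); an AUC
  below 0.5 stays visible instead of being auto-flipped;
* **the comparison grid** enumerates dataset × grade × endpoint (OS, PFS) ×
  subgroup, with subgroups {all, IDH mut, IDH wt, IDH mut + 1p/19q codel,
  IDH mut non-codel, MGMT methylated, MGMT unmethylated} and a minimum
  subgroup size of 10; the FDR family is the set of candidate biomarkers
  within each cell (that is what the correction is for — selecting the best
  of four candidates), with a global-across-cells alternative configurable
  since the choice is genuinely open;
* **consistency matrices** (per-biomarker +/− across datasets) use raw
  log-rank p at 0.05, a descriptive presentation of where a single biomarker
  works on primary data;
* **multivariate Cox** models combine the best pathway score with age, IDH
  and MGMT status; constant covariates are dropped, and non-convergence or
  separation is reported rather than masked;
* **patient averaging** (multi-region sampling) takes the arithmetic mean of
  normalized expression across a patient's samples after verifying the
  patient's clinical fields agree;
* **group activation profiles** contrast low-PAL vs high-PAL samples per
  pathway node: log10 of the ratio of geometric-mean CNRs, averaged over the
  node's measured member genes (NaN when none is measured).

## Synthetic cohorts

The generator plants known structure at every level:

* **Pathway collection**: the seed pathway is a tree rooted at a complex
  node containing the seed gene, with configurable layer widths and genes
  per node. A tree gives each gene a unique directed path from the seed, so
  its true ARR is the product of edge signs along that path (0 past a
  neutral edge) — deduction can be checked exactly. Decoy pathways on
  disjoint genes ensure all nine interaction types occur.
* **Counts** are gamma-Poisson (negative binomial, var = μ + φμ², default
  dispersion φ = 0.2, typical of bulk RNA-seq) with lognormal baseline means
  (default meanlog 4.0, sdlog 1.5 on the natural-log scale, i.e. typical
  counts of tens to thousands). Each sample carries a latent activity
  a ~ N(log2FC·1[GBM], 0.5 log2 units); pathway-gene means are scaled by
  2^(a·sign(ARR)).
* **Survival** is exponential with log-hazard β per SD of the standardized
  latent activity (default β = ln 2), identical machinery for OS
  (baseline 1/500 per day) and PFS (1/250 per day) — exactly proportional
  hazards, so Cox recovery is an honest test, not a robustness exercise.
  Censoring is an independent exponential time whose rate is solved by
  bisection to hit the configured expected censoring fraction (default 0.5);
  censoring tied to the event time would be informative and bias Cox.
* **Covariates**: P(IDH mut) = 0.8 in LGG / 0.1 in GBM, P(1p/19q codel |
  IDH mut) = 0.4 / 0.05, P(MGMT methylated) = 0.45, ages N(43, 10) LGG /
  N(60, 10) GBM — the frequencies a glioma cohort typically shows. An IDH
  effect on hazard is available but off by default so that the planted
  activity is the only hazard driver. Default cohort size is 505 LGG + 153
  GBM, the largest public cohort layout this design mirrors; tests and the
  acceptance study run scaled-down cohorts (120–200 samples, 300 genes),
  which preserve every planted property at smaller n.
* **Multi-sample patients**: optionally the first GBM patients receive extra
  profiles re-drawn around their latent activity with small within-patient
  noise, emulating multi-region tumor sampling.

What the generator does **not** emulate: batch effects between cohorts
(handled in the pipeline by never pooling datasets), gene–gene correlation
outside the planted pathway, non-proportional hazards, informative
censoring, and panel differences between datasets. Passing tests therefore
demonstrate correctness of the machinery and calibration under the stated
model, not robustness to those real-data complications.

## Numerical conventions and degenerate inputs

All randomness flows from one explicit integer seed (numpy Generator); no
global RNG state. Report files are written with fixed float formatting and
sorted keys, so a re-run with the same config and seed is bit-identical.
Degenerate cases have defined behavior: a t-test of two equal-constant
groups returns p = 1; Kruskal–Wallis on all-tied data returns H = 0, p = 1;
a log-rank test without events, an AUC with one class, and a Cox fit with a
constant covariate or fewer events than covariates are errors; an all-equal
median split yields an empty high group and the comparison is flagged
unevaluable. Graphs with fewer than two nodes have no defined density.
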