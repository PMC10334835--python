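# chpf — cellular hypoxia predicting framework

`chpf` assigns a binary hypoxia status — *hypoxic* or *normoxic* — to every
cell of a single-cell RNA-seq dataset, and ranks the transcription factors
that sit at the center of the regulatory networks specific to each status.
It is aimed at tumor-microenvironment studies (the design case is
glioblastoma) where oxygen tension shapes cell state but no direct oxygen
measurement exists per cell, so status must be inferred from transcription.

## Method

The framework proceeds in three stages.

**1. High-confidence labeling.** Each cell is scored against a panel of
hypoxia gene signatures by single-sample gene set enrichment (ssGSEA): for
a cell with *G* ranked genes and signature *S*, the score is

    ES = Σ_j [ P_in(j) − P_out(j) ],
    P_in(j)  = Σ_{i≤j, g_i∈S} (G−i+1)^α / Σ_{i, g_i∈S} (G−i+1)^α,
    P_out(j) = #{i≤j : g_i∉S} / (G−|S|),   α = 0.25.

For every signature, a two-component Gaussian mixture splits the per-cell
scores into a high and a low group. A cell that lands in the high group
for **all** signatures is a high-confidence hypoxic cell; in the low group
for all, high-confidence normoxic; anything else is unclassified.

**2. Recall-weighted ensemble classification.** The top 500 genes by
Wilcoxon rank-sum test between the two high-confidence classes form the
feature panel. High-confidence cells are split by stratified 5-fold
cross-validation; each of 100 gradient-boosted tree members (LightGBM)
trains on all hypoxic training cells of its fold plus an equal-size random
draw of normoxic cells, and receives weight `w_t` equal to its recall for
the hypoxic class on the held-out fold. Unclassified cells are then called
by the voting rate

    v_i = Σ_t w_t·I_t(i) / Σ_t w_t,   I_t(i) = 1 iff member t votes hypoxic,

with `v_i ≥ 0.5` ⇒ hypoxic. Genes with positive split importance in more
than 90% of members are *stable features*, and per-cell-type hypoxia
signatures are the stable genes with FDR < 0.05 and log2FC > 1.5
(Wilcoxon, Benjamini–Hochberg within cell type).

**3. Critical regulators.** Given directed TF→target networks inferred
separately for hypoxic and normoxic cells, each node is ranked by five
centralities (total degree, betweenness, closeness, eigenvector,
PageRank); the five normalized rank ratios are integrated into a Q
statistic — the joint order-statistic probability, smaller = more central
across the board — and the top 1% by Q are the critical genes. Critical
TFs of the hypoxic network absent from the normoxic critical set are the
status-specific regulators.

Small self-contained utilities round this out: a per-cell hypoxia score
(mean z-scored signature expression), a CNA score (quadratic sum of
copy-number region values), a prognostic risk score (coefficient-weighted
expression, median split), the connectivity-map weighted connectivity
score (WTCS ∈ [−1, 1]), and a Spearman drug–TF association filter
(|ρ| > 0.3, FDR < 0.05).

A deterministic synthetic-data module generates every input the pipeline
needs — negative-binomial counts with a planted hypoxia program, hypoxia
gene sets, metadata, hub-planted networks, ranked signatures — so the
whole framework runs and is tested without any download.

## Worked example

```sh
chpf simulate --seed 4 --outdir sim/
chpf run --matrix sim/counts.tsv --gmt sim/signatures.gmt \
         --meta sim/meta.tsv --outdir run/ --seed 4
```

The run prints its manifest, e.g. (2,000 cells × 2,000 genes, seed 1):

```json
{
 "n_cells": 2000,
 "n_high_confidence_hypoxic": 596,
 "n_high_confidence_normoxic": 1400,
 "n_unclassified": 4,
 "n_stable_features": 139,
 "member_weights_mean": 1.0
}
```

Read: 1,996 of 2,000 cells received a unanimous mixture-model consensus
across the seven signatures; the ensemble's members all achieved perfect
held-out recall on this cleanly separated synthetic data (`weights_mean`
1.0); 139 of the 500 panel genes were used by more than 90% of members.
`run/predictions.tsv` holds the per-cell voting rate and final status
(consensus labels for high-confidence cells, committee calls for the
rest). Against the generator's planted truth the voting rate reaches
AUROC 1.0 under these default conditions.

The same stages are available as a library of sklearn-style estimators
(`SSGSEAScorer`, `GMMConsensusLabeler`, `HypoxiaEnsembleClassifier`) and
plain functions; see `docs/methods.md` for the modeling details.

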