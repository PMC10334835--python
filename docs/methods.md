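# Methods

This note records the modeling choices behind `chpf`, their defaults, and
what the bundled synthetic data does and does not establish.

## Expression preprocessing

Input is a genes × cells raw-counts matrix (10x MTX triplet or dense
CSV/TSV). Genes expressed — defined as raw count strictly greater than
zero — in fewer than 0.1% of cells are removed; the retention rule is
`expressing fraction ≥ threshold`, so a gene at exactly the threshold
stays. Normalization is library-size scaling to 10,000 counts per cell
followed by natural `log1p` (the standard scRNA-seq log-normalization; the
scale factor is configurable). Cells with zero total counts are rejected
rather than silently dropped. Duplicate gene symbols from input files are
disambiguated deterministically (`ACTB`, `ACTB.1`, …, in file order), and
matrix↔signature gene matching is exact string match after uppercasing,
with unmatched signature genes dropped and counted in the log.

## ssGSEA scoring

Scores are computed per cell, independently of all other cells. Genes are
ranked by expression descending with ties broken by gene identifier, so
results are reproducible and invariant to any strictly monotone transform
of a cell's values. Walking down the ranking, the in-set ECDF accumulates
weights `(G − position)^α` (rank positions, not expression magnitudes —
this keeps scores bounded and fully rank-based) normalized to one, the
out-of-set ECDF accumulates uniform steps, and the score sums the
difference over all positions. `α = 0.25`, the canonical ssGSEA exponent.
No cross-cell normalization is applied by default, because the downstream
mixture labeling is scale-free per signature; a min–max flag exists for
parity with common implementations. A gene set with no gene in the matrix,
or covering every gene, is an error (the out-of-set ECDF would be
undefined).

## Mixture consensus

Per signature, a two-component 1-D Gaussian mixture is fit by EM
(k-means initialization from the seed, tolerance 1e-6 on mean
log-likelihood, at most 500 iterations; non-convergence yields the best
iterate plus a warning). The component with the larger mean is the "high"
group; a cell is "high" iff its posterior for that component is ≥ 0.5,
ties deliberately going high. The number of components is fixed at two —
the framework's dichotomy is high vs low, not a model-selection question.
Consensus is a strict conjunction: hypoxic iff high in every signature,
normoxic iff low in every signature, otherwise unclassified. With seven
signatures, 126 of the 128 patterns are therefore unclassified; this is
what makes the retained labels "high-confidence".

## Ensemble classifier

Feature panel: per-gene two-sided Wilcoxon rank-sum between
high-confidence hypoxic and normoxic cells, implemented as the vectorized
tie-corrected normal approximation (checked against the per-gene scipy
test in the suite); genes are ranked by raw p-value with ties broken by
larger |log2FC| then gene id, and the top 500 kept. Raw rather than
adjusted p-values are used — the panel is a ranking, not an inference.
log2FC is computed on `mean(expm1(lognorm))` with a pseudocount of 1 on
both sides.

Committee: 100 members over stratified 5-fold cross-validation — 20
repeats per fold, each repeat re-drawing the balanced undersample (all
hypoxic training cells plus an equal-size random draw of normoxic cells;
drawn with replacement only if normoxic cells are the minority). Members
are LightGBM gradient-boosted tree classifiers with 100 trees, depth ≤ 6,
31 leaves, learning rate 0.1, `min_child_samples` 10, 63 histogram bins,
deterministic single-threaded training, and per-member seeds derived from
the ensemble seed, making fits bit-reproducible. Each member's weight is
its recall for the hypoxic class on its held-out fold — recall of the
positive class is the quantity the undersampling protects, and a member
that misses hypoxic cells should count less. The voting rate
`v = Σ w_t I_t / Σ w_t` is clipped to [0, 1] against float roundoff;
`v ≥ 0.5` calls hypoxic, with the boundary deliberately on the hypoxic
side. An all-zero-weight committee is an error, not a silent 0/0.

Stable features are genes with positive split importance in strictly more
than 90% of members ("used by" a member = at least one split). Cell-type
signatures retest stable genes within each cell type having at least 3
cells per status (Wilcoxon, Benjamini–Hochberg within cell type) and keep
rows with FDR < 0.05 and log2FC > 1.5, both strict.

## Network critical genes

Centralities on the directed TF→target graph: total (in+out) degree;
betweenness and closeness on the undirected view (normalized harmonic
closeness when disconnected, classical closeness otherwise); eigenvector
centrality on the undirected largest connected component, zero elsewhere
(closed form for components of ≤ 2 nodes); PageRank on the directed graph
with damping 0.85. Self-loops are dropped with a warning. Per metric,
nodes get average-tie ranks (1 = most central), normalized by N.

The integrated Q statistic is the joint order-statistic probability: for
a node's sorted rank ratios r₍₁₎ ≤ … ≤ r₍ₙ₎,
`Q = P(U₍₁₎ ≤ r₍₁₎, …, U₍ₙ₎ ≤ r₍ₙ₎)` for uniform order statistics,
evaluated by the classical recursion `Q = n!·Vₙ`,
`V_k = Σᵢ (−1)^(i−1) V_{k−i} r₍ₙ₋ₖ₊₁₎^i / i!`. Smaller Q means jointly
more extreme ranks; the recursion is validated in the suite against a
Monte-Carlo estimate of the same dominance probability. Q is a dominance
measure, not a p-value: its null distribution over independent uniform
rank ratios is concentrated toward small values (mean 1/(n+1)), not
uniform on (0, 1]. Critical genes are the `ceil(0.01·N)` nodes with
smallest Q, boundary ties all included; "top 1%" applies to all nodes,
with the TF flag applied afterward. Status-specific TFs are critical TFs
of the hypoxic network absent from the normoxic critical gene set.

## Downstream scores

- **Hypoxia score**: per cell, the mean over signature genes of per-gene
  z-scored lognorm expression; genes constant across cells contribute 0.
  A mean z-score was chosen because it is monotone in every signature
  gene, centered at zero by construction, and needs no reference
  population.
- **CNA score**: per cell, Σ region² over copy-number region values.
- **Risk score**: Σ coefficientᵢ·expressionᵢ with externally fitted
  survival-regression coefficients; patients split at the median, scores
  exactly equal to the median going to the low-risk group (documented,
  boundary-tested; with an even number of distinct scores the split is
  exactly half/half).
- **WTCS**: enrichment of an up and a down query set against a ranked
  signature by the weighted-KS running sum (weights = |statistic|, signed
  value at the maximum absolute deviation); WTCS = (ES_up − ES_down)/2
  when the two enrichments have opposite signs, else 0, following the
  connectivity-map convention. Always within [−1, 1] and antisymmetric
  under set swap.
- **Drug–TF associations**: Spearman ρ per (TF, drug) over ≥ 3 shared
  cell lines, constant vectors skipped, Benjamini–Hochberg over all
  tested pairs, retained iff |ρ| > 0.3 (strict) and FDR < 0.05. ρ < 0 is
  reported as "sensitivity" because lower drug AUC means a more sensitive
  line.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not any real tissue: gamma-distributed per-gene baseline abundances,
log-normal library sizes (σ = 0.3), gamma-Poisson (negative binomial)
counts with dispersion 0.3 (variance = μ + 0.3μ²), a planted hypoxia
program (default 200 of 2,000 genes at log2FC 2 in 30% of 2,000 cells),
four cell types with small 2× marker blocks, and seven 50-gene signatures
drawing 80% of their genes from the program. Hypoxic cells are confined
to the "core" region of the metadata, mirroring the core/periphery
structure of tumor resections. Defaults were fixed once as a clean but
non-trivial recovery problem; sample-size-like parameters (counts, sizes,
rates) are all surfaced in `GeneratorConfig`.

What passing tests on this data show: the pipeline recovers a planted
transcriptional dichotomy through the full scoring → consensus →
classification chain, with exact formula-level behavior at every
decision boundary. What they do not show: robustness to batch effects,
doublets, ambient RNA, continuous hypoxia gradients, cell-type-confounded
programs, or real signature redundancy — none of which the generator
models. Network generators plant hub TFs by 20× selection weight in a
parent-sampling scheme; recovering them demonstrates that the Q ranking
finds planted centrality, not that inferred biological networks are
correct.

## Problem sizes and numerics

The reference study conditions (2,000 × 2,000, 100 members) run in about
a minute on one core; tests exercising cross-module behavior use smaller
but structurally identical configurations (250–600 cells). Tolerances:
ssGSEA vs brute-force oracle 1e-9; voting formula to machine precision
(1e-15 plus the [0,1] clip); centralities vs enumeration 1e-12. Ties are
broken deterministically everywhere (gene id in rankings, average ranks
in centralities); all randomness flows from explicit integer seeds via
`numpy.random.default_rng`, never from wall clock.

## Known limitations

- The consensus stage assumes each signature's score distribution is a
  two-Gaussian mixture; heavily skewed or unimodal score distributions
  will still be split, and only the multi-signature conjunction protects
  against over-calling.
- Recall-weighting is per member on its own held-out fold; weights are
  not comparable across datasets and are not calibrated probabilities.
- The Q statistic orders nodes; it does not test significance (see
  above), so "top 1%" is a selection rule, not an error-rate guarantee.
- GRN construction, CNV inference and survival-model fitting are consumed
  as inputs (edge lists, region values, coefficients), never performed.
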