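# Methods

## Data model and aggregation

Inputs are two genes × samples matrices of normalized log2 intensities —
one per system level (transcriptome = total mRNA, translatome =
polysome-associated mRNA) — and a sample map assigning each sample a
level, promoter, cell type and replicate number.  No re-normalization or
transformation is applied; values are assumed already on the log2 scale.

Two analysis scenarios restrict the promoter set, mirroring studies where
only some promoters are used verbatim on both levels while others target
the same cell type with different constructs:

* **identical** — only promoter labels present on both levels;
* **common** — all promoters.

The gene universe is the intersection of the two matrices' gene lists
(coupling statistics need paired vectors).  A cell-type profile entry is
the unweighted grand mean over all replicate samples of all scenario
promoters mapped to that cell type.  Pooling at the replicate level (not
mean-of-promoter-means) is the default because it weights every
hybridization equally and avoids arbitrary promoter weights when replicate
counts differ; `pooling="promoter"` switches to promoter-level pairing for
sensitivity analyses.  A cell type covered on only one level is a hard
error rather than a silent drop.

## Per-gene coupling

For each gene the Pearson correlation (PCC) of its two cell-type profiles
measures transcription–translation coupling; the coefficient of variation
(sample sd over mean, n−1 denominator) measures profile variability per
level.  Genes whose profile mean is non-positive, or whose profile is
exactly constant, carry a NaN "degenerate" marker and are excluded from
summaries, never silently dropped.  Constancy is detected by an exact
range check: centering a constant vector can leave a 1-ulp residue that
would otherwise masquerade as variance and produce a spurious ±1
correlation.

### Bootstrap null and Z-scores

The null model asks how large a PCC arises when cell-type identity is
destroyed but the per-level expression structure is kept.  Each of
`n_boot` (default 1000) iterations draws k units without replacement,
independently per level, averages replicates per unit, and pairs the two
draws in sampled order; the per-gene PCC of these randomly mixed profiles
forms the null sample.  Draw plans:

* identical scenario: k = 4 promoters from each level's full promoter pool;
* common scenario (default): k = 5 cell-type aggregates, i.e. an
  order-randomized pairing of the observed cell-type profiles;
* common alternative (`common_bootstrap="promoters"`): k = 8 raw promoters.
  Note the null vectors are then longer than the 5-entry observed profile,
  which shrinks the null spread (Fisher sd ≈ 1/√(k−3)) and inflates |Z| —
  retained for comparability, not recommended for calibrated calls.

**Z-scores are computed on the Fisher scale** (atanh of the PCC, clipped
at |r| = 1 − 1e−15): with only 4–5 cell types the raw-PCC null is a
bounded, strongly non-normal distribution — exactly uniform on [−1, 1] at
n = 4, a semicircle at n = 5 — whose standard deviation (≈ 0.58 / 0.5)
makes a raw-scale |Z| ≥ 1.96 literally unattainable at n = 4.  atanh(r)
is close to normal at these sizes, so the ±1.96 two-sided 5 % critical
value is meaningful.  On all-null synthetic data the two-sided call rate
measures ≈ 0.05 (the packaged calibration test asserts [0.03, 0.07] at
2000 genes and 200 bootstrap iterations; the slight excess over 5 % is
the usual t-type inflation from estimating the null moments from a finite
bootstrap).  `z_scale="raw"` is available for comparison.

Per-gene classification: coupled (Z ≥ 1.96), uncoupled (Z ≤ −1.96),
neutral otherwise, degenerate when the PCC or null sd is undefined.
Bootstrap iterations with an undefined PCC are dropped from that gene's
null and the retained count is reported.

A known, intrinsic limitation: genes whose profile is a single-cell-type
spike (marker-like genes) are under-called as coupled.  A random mixture
draw aligns the spiking cell type across the two levels with probability
≈ 1/n, so their null distribution is bimodal with a heavy high-correlation
component, which inflates the null mean and sd.  This is a property of the
mixture-bootstrap null itself, not of the implementation; the recovery
guarantees below therefore apply to genes whose coupling is carried by a
full cell-type effect vector.

## Network conservation

Each level's cell-type profiles define a fully connected weighted network:
nodes are genes, edge weight = pairwise profile PCC.  Edges incident to a
constant-profile gene are NaN and excluded pairwise everywhere.  Per gene,
the expression conservation (EC) score is the PCC between its two
adjacency rows with the diagonal excluded — the diagonal is identically 1
in both networks and would only inflate the correlation.  The full matrix
correlation is the PCC over the two strict upper triangles.

The EC bootstrap rebuilds both adjacency matrices per iteration from k
random *promoters* (adjacency construction is invariant to the order of
profile columns, so permuting the observed cell-type aggregates would
reproduce the observed networks exactly and collapse the null); k matches
the observed number of cell-type columns (4 identical / 5 common) so the
null networks' edge-weight sampling noise is exchangeable with the
observed ones.  Per-gene EC nulls give Z-scores and classes — conserved
(Z ≥ 1.96 and EC > 0), rewired (Z ≤ −1.96), neutral, degenerate — and the
full-matrix-correlation null gives a one-sided lower-tail empirical p with
+1 smoothing, P = (1 + #{null ≤ observed}) / (n_boot + 1), since the
scientific question is whether network similarity is *lower* than chance.
On all-null data the rewired call rate measures ≈ 2.5 % one-sided nominal
(asserted band [1 %, 4.5 %] at 1000 genes, 200 iterations).

Relevance networks threshold the adjacency at `t_edge` (default 0.9; edge
iff weight ≥ t).  Node properties: degree; betweenness (plus a per-edge
betweenness table); harmonic closeness normalized by n−1 (well-defined on
disconnected graphs); eigenvector centrality as the max-normalized
principal eigenvector of the adjacency; alpha centrality as the solution
of (I − αA)x = 1 with α = 0.5/λ_max (half the convergence bound, so the
resolvent always exists; the fraction is configurable); local clustering
and graph transitivity.  Isolated nodes get 0 for closeness and
centralities by convention.

For large gene sets the 1000-network bootstrap is quadratic in genes per
iteration; `ec_gene_subsample` restricts the network to a random gene
subset, which changes the problem size but not the statistic's definition.

## Cell-type differential expression and motifs

Per gene and level, a classic fixed-effects one-way ANOVA across cell
types uses replicate samples as observations (grouping by cell type;
promoter-level grouping is available through the promoter pooling config).
Genes with both variance components zero are degenerate and excluded.
Benjamini–Hochberg FDR (step-up, monotone adjusted p-values; reject iff
adjusted p < q = 0.05) is applied per level across all testable genes.
Genes DE on *both* levels proceed to Tukey HSD.

Tukey HSD uses the Tukey–Kramer form: q = |mean_i − mean_j| /
sqrt(MSW/2 · (1/n_i + 1/n_j)) with the pooled within-group mean square,
p from the studentized range distribution with (k, N−k) parameters —
exact for balanced groups, mildly conservative for the 2–3-replicate
unbalance this design produces.  The bulk pipeline path compares q against
the single critical value per (k, df) instead of evaluating one
studentized-range tail per gene and pair; the two paths are
threshold-equivalent and cross-checked in the tests.  Zero pooled variance
marks all pairs degenerate and non-significant.

Pairwise outcomes are encoded as a binary difference vector over the
canonical lexicographic pair order ((0,1), (0,2), …); 1 = significant
difference.  The complementary similarity bits define a labelled graph on
the cell types (edge = similar), one of 2^(n(n−1)/2) motifs; the motif id
is the integer with bit p equal to the similarity bit of the p-th pair.
Motifs are labelled — cell-type identity matters, isomorphic graphs with
different isolated cell types are distinct — because the scientific
reading ("which cell type deviates") depends on the labels.  Significance
of occurrence counts is assessed by within-gene permutation: each of
`n_perm` (default 1000) rounds shuffles every gene's bits uniformly at
random (preserving its number of significant pairs), re-encodes and
re-counts; the upper-tail empirical p uses +1 smoothing.  Within-gene
shuffling keeps each gene's overall discriminability fixed and tests only
the arrangement of differences across pairs.

## Enrichment

Terms are tested by the hypergeometric upper tail P(X ≥ k) for k study
genes with the term, K population genes with the term, study size n,
population N (scipy's log-gamma-based survival function; verified against
exact combinatorial sums for all N ≤ 30).  The default population is the
full shared gene universe of the two matrices.  One test per term with at
least one study gene; raw p-values are reported with BH adjustment across
tested terms.  Annotation is consumed as a flat pre-propagated gene→term
table; ontology-graph propagation is upstream.

## Synthetic data generator

The generator emulates the sampling design of paired cell-sorted /
ribosome-immunopurified root array studies and plants ground truth for
every stage.  Defaults (all configurable):

| parameter | default | rationale |
| --- | --- | --- |
| cell types | 5, one ("cortex") without a shared promoter | identical scenario → 4 cell types, common → 5 |
| promoters per cell type per level | 1 (shared where possible) + 1 extra | pools of 10 promoters per level |
| replicates per promoter | 2–3, drawn per promoter | typical replication of cell-sorting experiments |
| baseline | Uniform(4, 12) log2 | spans the usual array intensity range |
| effect_sd | 1.0 log2 units | cell-type effects of about one fold-change unit |
| noise_sd (tr / tl) | 0.3 / 0.2 log2 units | replicate noise; translatome set lower, reproducing the empirically smaller translatome variability |
| class fractions (coupled / uncoupled / null) | 0.15 / 0.10 / 0.75 | enough planted genes for stable sensitivity estimates; most genes null |
| motif genes | 5 % of genes, shift 2.0 | one strongly deviant cell type |

Coupled genes share one N(0, effect_sd²) cell-type effect vector on both
levels; uncoupled genes get the sign-flipped vector on the translatome
(an anti-correlated mode; an "independent" sub-class is available for
null-power studies); null genes have zero effects.  Replicate value =
baseline + effect + N(0, noise_sd²).  Class counts follow the configured
fractions exactly via largest-remainder rounding.  Motif genes are carved
from the coupled class and carry a pure one-cell-type indicator effect,
identical on both levels: a same-sign single-cell-type shift makes a gene
positively coupled by construction, so labelling such genes null would
corrupt false-positive-rate estimates, and stacking the shift on a random
effect vector would destroy the planted one-deviant-cell-type pattern the
DE/motif stages are scored against.

The annotation generator gives each gene each background term with a
background probability and plants one term on coupled genes with a higher
probability.

What the generator does **not** emulate: probe-level effects and
normalization artifacts, correlated (batch) noise between levels or
between promoters, heavy-tailed intensity noise, gene–gene correlation
beyond the planted classes, and annotation structure (term hierarchies,
strongly varying term sizes).  Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the stated
generative model, not performance on real arrays, where interlaboratory
and protocol differences add variance the null model cannot see.

## Problem sizes and numerical choices

Packaged statistical tests run at sizes chosen for stable estimates:
calibration at 2000 genes × 200 bootstrap iterations, recovery at 1000
genes (effect/noise = 3; measured sensitivity ≈ 0.93–0.95 per class,
null false-positive rate ≈ 0.05), EC calibration at 1000 genes, motif
oracles against exhaustive enumeration at 3 genes × 3 cell types and
brute-force tallies at 500 vectors.  Correlations are clipped to
[−1, 1] against rounding; sample statistics use the n−1 denominator
throughout (small-sample bootstrap moments); permutation/empirical
p-values use +1 smoothing so p = 0 never occurs; all randomness flows
through seeded numpy Generators, with per-stage substream seeds derived
from the master seed by hashing, so stage-level reruns reproduce full
pipeline runs.

## Known limitations

* The mixture-bootstrap null under-calls marker-like (single-cell-type
  spike) genes as coupled; see above.
* With only 4–5 cell types, per-gene PCCs are noisy regardless of the
  classification scale; Z-scores inherit bootstrap-moment noise of order
  1/√n_boot.
* The permutation motif test conditions on each gene's number of
  significant pairs; alternatives (cross-gene or cross-pair shuffles)
  answer different questions and are not implemented.
* EC bootstrap cost grows quadratically with gene count; use
  `ec_gene_subsample` beyond a few thousand genes.
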