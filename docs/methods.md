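# Methods

## The SPKMG statistic

SPKMG treats exome read depth as a quantitative measure of DNA content.
For gene *g* in sample *s*,

    SPKMG(g, s) = 1e9 · R / (E · G)

with `R` the cleaned reads overlapping any exonic base of the locus, `E` the
exonic length of the collapsed gene model, and `G` the sample's cleaned
aligned read total. The constant 1e9 makes the units "reads per kilobase of
exon per million aligned reads", the RPKM convention; the ratio `R/G`
removes sequencing depth, and `1/E` removes gene length, so the remaining
per-gene variation reflects local copy number plus capture efficiency.
Division by `G` makes SPKMG invariant under uniform read duplication and
under depth changes; `R = 0` maps to exactly 0, which is the signature of a
homozygous deletion.

Assumptions: capture is approximately uniform within targets (random
fragmentation libraries), reads are independent observations (paired-end
mates are counted separately), and CNV affects depth multiplicatively. No
GC-content or mappability correction is applied.

### Collapsed gene model

All splice isoforms of a symbol on one chromosome/strand are merged into a
single locus whose exons are the interval union (adjacent intervals merge;
the union's length is `E`). Same-symbol transcripts further apart than a
`locus_gap` (default 1 Mb) form separate loci with distinct `locus_id`s
(`SYMBOL|chrom|index`). Coordinates are 0-based half-open throughout;
refFlat exon starts are already in that convention, BED12 blocks are
converted from relative offsets. Strand is carried but ignored for
counting, since exome depth is strand-agnostic.

### Read cleaning and counting

Unmapped, secondary and supplementary alignments are always dropped;
duplicate-flagged reads are dropped unless duplicate retention is requested;
reads with Phred quality strictly below 20 are dropped. The quality used is
the mapping quality by default, with mean base quality available as a
switch — alignment records carry both and either reading of a "Phred < 20"
filter is defensible. A read is assigned to a gene when any aligned block
overlaps at least one exonic base (whole-read counting; a read touching two
genes increments both). `G` counts all cleaned mapped reads genome-wide,
not only exonic ones.

## Case/control comparison

SPKMG values are real numbers, so they are rounded to pseudocounts
(`round(scale · value)`, scale default 1) before count modelling. Library
composition is normalized by trimmed-mean-of-M-values factors (reference =
highest-depth sample; trim 30 % of M and 5 % of A tails; inverse-variance
weights; factors rescaled to geometric mean 1). A common negative-binomial
dispersion φ (variance μ + φμ²) is estimated by maximizing the profile
log-likelihood summed over genes — group means profiled out at their sample
means — on a log grid over [1e-6, 10] refined by bounded scalar
minimization. Per-gene p-values come from a conditional exact test: counts
are rescaled to a common effective library size, the gene's total across
both groups is fixed, and the two-sided p-value sums the probabilities of
all splits no more likely than the observed one (probability-mass ordering).
Group sums of NB counts with common dispersion are NB with shape n/φ, so the
conditional split law is the ratio of two NB masses; the φ → 0 limit is the
binomial split of a Poisson total. Benjamini–Hochberg step-up controls FDR.

Tagwise (per-gene) dispersion is deliberately omitted: a single common φ
keeps the estimator and the exact test directly testable against
enumeration, at the price of some power when dispersions vary.

MDS coordinates use leading-log-fold-change distances: for each sample pair,
the root mean square of the 500 largest moderated log2 ratios (prior count
2), embedded by classical metric MDS. Hierarchical clustering is average
linkage on Euclidean distances between log2(SPKMG + 1) sample profiles.

## Control-free networks

### Mutual information

MI is reported in nats. The plug-in estimator computes
S(X) + S(Y) − S(X, Y) from a contingency table (with quantile binning when
discretizing continuous profiles). The continuous estimator is Kraskov
algorithm 1 with k = 3 neighbours in the max-norm: ψ(k) + ψ(N) −
⟨ψ(n_x + 1) + ψ(n_y + 1)⟩, with marginal neighbour counts strictly inside
the k-th joint distance, tie-broken by seeded jitter of 1e-10 of the value
range, and floored at 0.

ARACNe-style pruning applies the data-processing inequality once against
the original matrix: edge (i, j) is removed when MI(i, j) <
min(MI(i, k), MI(j, k)) − eps for any third gene k. Removals do not cascade
within the pass, matching published ARACNe behaviour; eps is the additive
tolerance (0.05 is a typical setting for this data type, 0.01 a stricter
one). The pruned matrix is thresholded (keep MI ≥ min_mi by default; the
boundary comparison is configurable) and isolated genes are dropped.
Clusters are connected components with at least `min_size` members (default
10), which is the simplest reading of cluster analysis on a sparse network;
a community-detection alternative would change cluster boundaries but not
the component structure tests rely on.

### Pearson correlation

Gene–gene Pearson matrices are quantized hard: r strictly above 0.95 → +1,
strictly below −0.95 → −1, else 0 (diagonal forced to 0), yielding
positive, negative and complete (union) networks. Degree ("link") vectors
over a fixed gene universe — absent genes scoring 0 — are compared between
two networks (e.g. germline vs tumour) by overall Pearson r; the same
correlation inside consecutive non-overlapping 50-gene windows per
chromosome localizes rewired regions (windows with |r| < 0.3 are flagged
deviant, r > 0.95 conserved; a trailing remainder is kept as its own
window when it has at least half a window's genes, otherwise folded into
the previous window). Undefined correlations (constant degree vectors) are
reported as missing, never as 0.

## Graph metrics

Clustering coefficient is global transitivity (3 · triangles / connected
triples) by default, with average local clustering as a switch. Diameter
and average path length are computed on the largest connected component,
with a flag recording disconnectedness — MI networks are disconnected by
construction. Degree centralization is Freeman's index
Σ(d_max − d_i)/((n−1)(n−2)); assortativity is the Pearson correlation of
endpoint degrees and is reported as undefined (None) for regular graphs
rather than NaN. The power-law exponent is the exact discrete MLE: α
maximizes −α Σ ln k − n ln ζ(α, kmin) with the Hurwitz-zeta normalization,
kmin = 1 fixed. The familiar closed form 1 + n/Σ ln(k_i/(kmin − ½)) is only
an approximation and underestimates α badly at kmin = 1 (≈ 2.0 for a true
2.5), so it is not used.

## Enrichment

Over-representation of a query gene list in each GMT set uses the
upper-tail hypergeometric probability P(X ≥ k | N, K, n) with BH adjustment
across sets. The universe N defaults to 19358, the collapsed human gene
count, rather than the union of annotated genes; it is configurable.
Significant sets form a pathway–gene bipartite network; genes sharing a
significant pathway and pathways sharing an overlapping gene are linked in
the two projections, and the most central node (degree centrality by
default, betweenness optionally) is reported per projection with
lexicographic tie-breaking.

## Synthetic data

The generators emulate the structure of the real inputs at desk scale, with
every draw controlled by an explicit seed:

- **Gene models**: non-overlapping genes on up to a few chromosomes,
  exonic lengths log-uniform in roughly 0.5–10 kb, 3 exons per gene.
- **Reads**: per gene, clean read count ~ Poisson(base_coverage ·
  multiplier · efficiency · E/median E); 100-bp reads placed uniformly
  within exons; a configurable fraction of clean reads gains a
  duplicate-flagged copy, and an extra fraction of reads carries mapping
  quality 10 (< 20). Copy multipliers per locus model deletion (0, 0.5),
  neutrality (1) and amplification (≥ 1.5). An optional shared lognormal
  per-gene capture-efficiency profile (σ = 1) reproduces the strong
  between-sample SPKMG correlation of real exomes; without it per-gene
  expectations are flat and only Poisson noise remains. Ground-truth
  tables record the expected post-filter R and G, so counting can be
  checked exactly.
- **Counts**: NB draws via gamma–Poisson mixing, base mean ~100, dispersion
  default 0.1 (a typical biological-replicate value), 10 % of genes at
  2-fold change by default — the regime where the exact test should have
  high power at n = 10 per group.
- **Modular expression**: single latent factor per module with loading
  √ρ_within, giving within-module correlation ρ and ≈ 0 between; optional
  sign flips create planted negative edges.
- **Power-law degrees**: inverse-CDF sampling of the zeta-normalized mass,
  truncated at k = 1e6 (omitted tail mass ≪ 1/n for α > 1.5).

What these simulations do not model: GC and mappability bias, indels and
split reads, base-calling error profiles, correlated duplicate structure,
capture edge effects, and the heavy-tailed per-gene dispersion of real
cohorts. Passing tests therefore demonstrate correctness of the
algorithms under their stated model, not robustness to those artefacts.

## Problem sizes and numerical choices

Simulation-based checks use 2 000 genes × 20 samples for the count model,
2 000 observations for MI closed-form accuracy, 5 000 draws for exponent
recovery, and 30–150-gene models for read-level tests — sizes chosen so
estimator error is well below the tolerances being asserted while the whole
suite stays fast. Degenerate inputs are defined rather than left to
chance: constant vectors give MI 0 with a warning and undefined
correlations are masked or flagged; BH uses a stable mergesort so ties are
deterministic; ranking ties break lexicographically by locus id; the exact
test clips p to [0, 1] and treats split masses equal within 1e-12 as tied;
dispersion estimation reports the grid optimum with a warning if
refinement fails.

## Known limitations

- Common dispersion only; strongly gene-specific variance inflates or
  deflates individual p-values.
- Pseudocount rounding discards sub-integer SPKMG differences at scale 1;
  raise `scale` when matrices are small-valued.
- The all-pairs MI matrix is O(p² · n log n) and intended for shortlisted
  gene sets (hundreds to a few thousand genes), not the full genome in one
  pass.
- DPI pruning with eps = 0 on near-tied triples is sensitive to estimator
  noise; the tolerance exists to absorb exactly that.
- Window boundaries are fixed gene-count cuts, so a rewired region
  straddling two windows dilutes its signal across both.
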