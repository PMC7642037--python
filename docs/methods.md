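# Methods

This note documents the statistical procedures gelnet implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
deterministic.

## Co-expression networks and cutoff selection

Pairwise Pearson correlations are computed on the FPKM matrix after a
light expression filter: a gene must reach `min_fpkm` (default 1 FPKM) in
at least `min_expressed_samples` (default 2) samples and have non-zero
variance. The filter defaults are deliberately conservative — their role
is only to remove genes for which correlation is undefined or dominated by
detection noise — and both are configurable. Excluded genes are reported
with a reason (`low_expression` or `zero_variance`) rather than silently
dropped. The sample count is taken from the input matrix; it is data, not
a contract.

A grid of hard cutoffs (default 0.6–0.95 in steps of 0.05) is scanned.
At each cutoff the scan records the edge count, the number of connected
(degree ≥ 1) nodes, and two density conventions:

* `density` — 2E/(N′(N′−1)) over the N′ connected nodes, i.e. the graph
  actually built at that cutoff;
* `density_all` — the same quantity over the full correlated gene set.

Both are reported because they answer different questions. The
connected-node density describes the network a user will browse and is the
quantity bounded during cutoff selection; however it is *not* guaranteed
monotone in the cutoff, because the node set shrinks together with the
edge set (at high cutoffs the surviving subgraph can concentrate on a
dense core). The fixed-universe density is monotone by construction and
is the right quantity for monotonicity checks.

The scale-free topology fitting index R² bins the positive degrees into
`n_bins` (default 10) equal-width bins, computes each non-empty bin's mean
degree and relative frequency, and returns the squared correlation of
log₁₀ frequency against log₁₀ mean degree. Real-valued degrees (weighted
connectivities) are accepted so the same routine serves soft-threshold
scans. With fewer than two non-empty bins, or zero spread on either axis,
the fit is undefined and reported as such rather than raising.

`select_cutoff` returns, among cutoffs with defined R² and density within
the bound (default 0.05), the one with maximal R²; ties break toward the
smaller |cutoff|, i.e. the denser and therefore more informative network.
Final networks use strict inequalities (PCC > c₊, PCC < c₋, defaults 0.8
and −0.75), so a pair sitting exactly at a cutoff is excluded.

## Module detection

The pipeline is the classical weighted-network recipe: unsigned adjacency
a_ij = |PCC_ij|^β with β = 7 by default, topological overlap

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    L_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

average-linkage hierarchical clustering of 1 − TOM, a static cut of the
dendrogram, a minimum module size of 30, and eigengene-based merging.
The unsigned adjacency was chosen because negative correlations are
handled separately by the signed co-expression networks; squaring-style
signed variants are out of scope.

The tree cut is the static-height variant: the dendrogram is cut at
`cut_height` × (tallest merge height) and clusters below `min_module_size`
are labelled grey. The default cut height is 0.9, the conventional
default for static tree cutting. A cut very close to the top of the tree
(e.g. 0.99 — the convention for *dynamic* cut variants, where it only
bounds the search region) behaves badly here: unclustered noise genes
join real modules just below the tallest merges, inflating modules with
false members. At 0.9 the planted-module benchmark recovers the true
partition essentially perfectly; the parameter remains configurable.

A module eigengene is the first right singular vector of the member ×
sample matrix after per-gene standardization (mean 0, sd 1 with ddof = 1
across samples), scaled to unit norm, with its sign fixed so that it
correlates non-negatively with the module's mean standardized profile —
without the sign rule the eigengene is defined only up to ±1 and results
would depend on the SVD implementation. Merging is iterative: while the
closest pair of module eigengenes has dissimilarity 1 − PCC below
`merge_cut_height` (default 0.25, the common-practice value; published analyses
rarely report theirs), the pair is merged and all
eigengenes recomputed. Grey genes never participate. Module labels M1,
M2, … are assigned by decreasing size, ties broken by first gene position,
so the labelling is deterministic and order-independent up to names.

Clustering is single-block: at desk scale (≤ ~20k genes) the full TOM fits
comfortably in memory, so no blockwise pre-partition is needed.

## Gene-set enrichment

Enrichment is over-representation analysis. For a query of n genes in a
universe of N, against a set with K members overlapping the query in k
genes, the default score is the hypergeometric upper tail

    p = P(X ≥ k) = Σ_{i=k}^{min(n,K)} C(n,i) C(N−n, K−i) / C(N,K),

evaluated by summing point masses computed in log space (log-gamma), so
genome-scale N does not overflow. The point mass alone is kept as a
separate operation; it is not an enrichment p-value. One-sided Fisher on
the induced 2×2 table is mathematically the same tail and is implemented
as such; the χ² test uses the Pearson statistic on 1 df without continuity
correction by default and refuses tables with a zero expected count.

The background N defaults to the annotated universe (union of all set
members) and can be overridden, e.g. with a genome-wide gene count.
Query genes outside the universe are dropped with a warning. By default
only sets with k ≥ 1 are tested (and corrected for); `include_empty`
changes the correction denominator by testing all sets.

All six corrections — Bonferroni, Holm, Hochberg, Hommel, BH, BY — are
implemented directly as their published step-up/step-down recursions,
preserve input order, and clip at 1. The test suite checks them against
statsmodels and hand-stepped references.

Note on calibration: the hypergeometric test is exact but discrete, so for
small sets or queries P(p < 0.05) under the null can sit well below 0.05
(the test is conservative, not anti-conservative). The calibration check
therefore uses query size 100 against sets of 60–200 genes in a ~600-gene
annotated universe, where the null p-value distribution is close enough to
uniform for the rejection rate to be informative.

## Promoter motif enrichment

Promoters are extracted strand-aware from the genome FASTA + GFF3: for a
`+` gene the window [start−L, start−1] (1-based, truncated at the contig
start), for a `−` gene the reverse complement of [end+1, end+L] (truncated
at the contig end), L ∈ {1000, 2000, 3000}. The promoter abuts the
annotated gene start and excludes the gene body; windows are not clipped
against neighboring genes. Truncated (even empty) promoters are kept,
with a warning, so that the query and the random null share one gene
universe — dropping them would bias the null. Soft-masked bases are
upper-cased before scanning; an N in the sequence matches only the motif
letter N.

Scanning counts every overlapping position at which the IUPAC consensus
matches the forward strand, plus every match against the reverse
complement of the sequence; a palindromic site therefore counts twice.
This both-strand, overlap-permitting convention is symmetric under
reverse-complementing the input, which the test suite asserts as a
property.

The null is empirical: B (default 1000) gene lists of the query's size n
are drawn uniformly without replacement (within a list) from the promoter
universe, and μ and σ are the mean and standard deviation (ddof = 1) of
the per-gene match counts pooled across all B·n sampled promoters. The
per-gene (rather than per-list-mean) reading of σ is what makes dividing
by √n in Z = (X̄ − μ)/(σ/√n) correct; the alternative reading would
shrink the spread twice and is available behind `sigma_mode="set_mean"`
for comparison. The null is built at the same promoter length as the
query. Per-promoter match counts are computed once and cached, so null
construction reduces to index sampling and stays fast at B = 1000.
P = 1 − Φ(Z); σ = 0 (a motif absent from, or constant across, the
universe) yields a flagged degenerate result with P = 1 when X̄ ≤ μ and 0
otherwise, never a crash. The query's own genes are not excluded from the
null universe.

Because the query is itself a subset of the finite promoter universe, X̄
under the null has variance (σ²/n)·(N−n)/(N−1); ignoring the finite-
population factor makes the test very slightly conservative (rejection
rate ≈ 0.045 at nominal 0.05 for n = 30 of N = 500), which the
calibration band accommodates.

## Network operations

Neighbor queries rank a gene's partners by |PCC| descending with ties
broken by gene id. A gene that survived correlation but is isolated at
the network's cutoff returns an empty neighbor list; a gene absent from
the network is an error. Interolog projection filters ortholog pairs at
bootstrap strictly greater than the cutoff (default 60%), expands each
source edge through the full cross-product of its endpoints' targets,
drops self-loops, deduplicates, and records the provenance (source
network) of every projected edge; unions over several source species
deduplicate edges while concatenating provenances.

## Synthetic data

The generator exists to give every pipeline stage inputs with known
truth. Expression is a Gaussian latent-factor block model: genes in a
block share a latent per-sample profile with standard deviation s plus
independent noise with standard deviation ε, so the expected within-block
correlation is s²/(s² + ε²) in closed form; defaults s = 2, ε = 1 give
0.8, and the default layout (five blocks of 60–200 genes among 2,000
genes over 39–40 samples) mirrors the shape of a multi-experiment plant
expression atlas. Values are shifted to a non-negative FPKM-like scale;
correlation is shift-invariant so the truth is unaffected. Left-over
genes are pure noise and carry the grey truth label.

Promoter fixtures emit a consistent genome FASTA + GFF3 (genes laid out
promoter-adjacent on both strands) so that extraction can be validated
against the generating truth exactly; motif instances are planted at
non-overlapping random positions in the enriched genes' promoters. The
planted-graph generator for cutoff selection is a Chung–Lu graph with
power-law expected degrees whose edges receive correlation values above
the scan grid's lower end and whose non-edges stay below it.

What the generator does *not* emulate: RNA-seq count noise
(negative-binomial mean–variance structure), batch effects, correlated
noise between modules, genome-realistic base composition or repeat
structure, and annotation bias. Passing the recovery and calibration
checks therefore demonstrates correctness of the algorithms under their
own statistical assumptions, not robustness to every artifact of real
transcriptome data.

## Determinism and problem sizes

Every stochastic component takes an explicit seed and uses an
independently constructed generator, so identical configuration + seed
reproduces every output byte for byte (run manifests, which record
absolute paths, are the only files that differ between runs in different
directories). The bundled property checks run at: 80 genes for the PCC
oracle, universes up to N = 12 (enumeration) and N = 30
(Fisher/hypergeometric equivalence), 50 genes for the TOM oracle, 800
nodes for cutoff selection, 2,000 genes × 40 samples for module recovery,
400 replicate queries for both calibration checks, B = 1000 null draws
over 500 one-kb promoters, and 50 seeds for planted-motif power — sizes
chosen so the whole battery completes in about a minute on one CPU while
keeping Monte-Carlo error small against the tolerance bands.

## Known limitations

* The static tree cut is a simplification of adaptive dendrogram cutting;
  modules with strongly nested correlation structure may need the cut
  height tuned.
* Hard-threshold networks discard edge-weight information below the
  cutoff; mutual-rank or Spearman alternatives are out of scope.
* Motif scanning is consensus-based; position-weight-matrix scoring with
  log-odds thresholds is out of scope.
* The χ² option is asymptotic and refuses degenerate tables; for small
  counts the exact tests are the right choice.
* Interolog projection transfers edges, not confidence; no interaction
  scoring is attempted.
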