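# gelnet

Species-agnostic gene co-expression network analysis for bulk RNA-seq
expression atlases, built for plant genomics groups that want the
computational core of a gene-function-analysis platform as a scriptable
library and CLI: signed Pearson co-expression networks with
scale-free-topology cutoff selection, WGCNA-style functional-module
detection, over-representation gene-set enrichment, empirical promoter
cis-element (motif) enrichment, and ortholog-based (interolog) projection
of protein–protein interaction networks.

## The statistics at the core

**Co-expression.** For genes *x*, *y* with FPKM profiles over *n* samples,

PCC<sub>xy</sub> = Σᵢ(xᵢ−x̄)(yᵢ−ȳ) / √(Σᵢ(xᵢ−x̄)² · Σᵢ(yᵢ−ȳ)²).

A grid of hard cutoffs (default 0.6, 0.65, …, 0.95) is scanned; at each
cutoff the thresholded graph's edge count, density 2E/(N(N−1)) and
scale-free topology fitting index *R*² (squared correlation of
log₁₀ frequency vs log₁₀ mean degree over equal-width degree bins) are
recorded, and the cutoff maximizing *R*² under a density bound is selected.
Positive (PCC > c₊) and negative (PCC < c₋) networks are built with strict
inequalities.

**Modules.** Unsigned soft-threshold adjacency a<sub>ij</sub> =
|PCC<sub>ij</sub>|<sup>β</sup> (default β = 7) is converted to the
topological overlap matrix TOM<sub>ij</sub> = (L<sub>ij</sub> +
a<sub>ij</sub>)/(min(kᵢ,kⱼ) + 1 − a<sub>ij</sub>), clustered with average
linkage on 1 − TOM, cut at a static height, and modules whose eigengenes
(first principal component of the standardized member profiles) correlate
above 1 − merge height are merged.

**Gene-set enrichment** is over-representation analysis: the overlap *k*
between a query of *n* genes and a set of *K* annotated genes in a
universe of *N* is scored by the hypergeometric upper tail P(X ≥ k) (or
one-sided Fisher, or χ²), with Bonferroni, Holm, Hochberg, Hommel,
Benjamini–Hochberg and Benjamini–Yekutieli corrections.

**Motif enrichment** is empirical: promoters (1/2/3 kb upstream, strand
aware) are scanned for IUPAC consensus matches on both strands; B = 1000
random same-size gene lists give a null mean μ and standard deviation σ of
per-gene match counts, and the query mean X̄ is scored as
Z = (X̄ − μ)/(σ/√n), P = 1 − Φ(Z), significant at P < 0.05.

## Worked example

Everything below runs on synthetic data with known ground truth — no
downloads. Generate a 300-gene × 39-sample fixture (five planted
co-expression blocks, one motif planted 3× in the promoters of the first
30 genes), then run the pipeline:

```bash
gelnet simulate --seed 17 --n-genes 300 --n-samples 39 --out-dir demo
gelnet scan     --expr demo/expression.tsv --max-density 1.0 --out demo/scan.tsv
# selected_cutoff  0.85
gelnet modules  --expr demo/expression.tsv --min-size 15 --out demo/modules.tsv
# n_modules         5
# n_assigned_genes  156
```

The scan table reports, per cutoff, edge counts and both density
conventions (over connected nodes, and over all correlated genes) plus the
scale-free fit used for selection. Module detection recovers the five
planted blocks (156 = 48+36+30+24+18 genes; the rest are simulated noise
genes and stay grey).

Motif enrichment on the 30 genes whose promoters carry the planted
element:

```bash
gelnet motif --genes demo/enriched_genes.txt --genome demo/genome.fa \
             --gff demo/genes.gff3 --motifs demo/motifs.tsv \
             --draws 1000 --seed 17 --out demo/motif.tsv
```

```text
motif_id  consensus  x_bar     mu       sigma    n   z        p            significant
PLANTED   TGACGTCA   6.06667   0.6272   1.82853  30  16.2935  5.48871e-60  True
BG3       CACGTCCT   0.033333  0.01697  0.12915  30  0.69412  0.243805     False
...
```

The planted motif averages 6.07 matches per query promoter (3 planted
copies, counted on both strands, plus chance matches) against a null mean
of 0.63, giving Z = 16.3 — overwhelmingly significant — while background
motifs sit at their null level. Gene-set enrichment of the same query
against the module-derived annotation ranks the true set first with
hypergeometric p = 6.2 × 10⁻²⁰ (N=156, K=48, n=30, k=30).

The same operations are importable, sklearn-style:

```python
from gelnet import ModuleDetector, ThresholdSelector, read_expression_tsv

em = read_expression_tsv("demo/expression.tsv")
det = ModuleDetector(power=7, min_module_size=15).fit(em)
det.labels_        # gene -> module label ("grey" = unassigned)
det.eigengenes_    # module x sample eigengene matrix
```

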