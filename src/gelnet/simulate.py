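"""Synthetic fixtures with known ground truth for every toolkit input.

Expression matrices are generated from a Gaussian latent-factor block
model: genes in a block share a latent per-sample signal (sd s) plus
independent noise (sd eps), so the expected within-block correlation is
s^2 / (s^2 + eps^2) in closed form — the property the correlation- and
module-level tests rely on.  Values are shifted to a non-negative
FPKM-like scale (correlation is shift-invariant, so the truth survives).

Promoter fixtures emit a consistent genome FASTA + GFF3 pair (genes on
both strands) together with the true promoter sequences and any planted
motif copies, so the full promoter-extraction path can be exercised
end-to-end and compared with the truth.

Everything is bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    ExpressionMatrix,
    GeneCoordinate,
    GeneSet,
    GeneSetCollection,
    MotifLibrary,
    PromoterRecord,
    PromoterSet,
    write_expression_tsv,
    write_fasta,
    write_gff_genes,
    write_gmt,
    write_motif_tsv,
)
from .modules import GREY

__all__ = [
    "SimulationSpec",
    "SimulatedExpression",
    "SimulatedPromoters",
    "simulate_expression",
    "simulate_promoters",
    "simulate_annotation",
    "simulate_scale_free_correlation",
    "power_law_degrees",
    "write_full_fixture",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults mirror the statistical shape of a desk-scale plant
    co-expression study: blocks of co-regulated genes observed over ~39
    RNA-seq samples, with within-block expected correlation
    s^2/(s^2+eps^2).
    """

    n_genes: int = 500
    n_samples: int = 39
    module_sizes: tuple[int, ...] = (80, 60, 50, 40, 30)
    signal_sd: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    # promoter / motif layout
    promoter_length: int = 1000
    gene_body_length: int = 500
    genes_per_contig: int = 10
    motif: str = "TGACGTCA"
    n_background_motifs: int = 5
    planted_copies: int = 3
    enriched_fraction: float = 0.1

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError("module sizes exceed n_genes")
        if self.signal_sd < 0 or self.noise_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n_samples < 3:
            raise ValidationError("need >= 3 samples")
        if self.promoter_length not in (1000, 2000, 3000):
            raise ValidationError("promoter_length must be 1000, 2000 or 3000")

    @property
    def expected_within_module_pcc(self) -> float:
        s2, e2 = self.signal_sd**2, self.noise_sd**2
        return s2 / (s2 + e2) if (s2 + e2) > 0 else 0.0


@dataclass(frozen=True)
class SimulatedExpression:
    expression: ExpressionMatrix
    truth: pd.Series  # gene -> true module label ("grey" for noise genes)


def simulate_expression(spec: SimulationSpec) -> SimulatedExpression:
    """Draw a block-structured FPKM-like matrix with known module truth.

    Each block's genes equal a shared latent sample profile (sd
    ``signal_sd``) plus independent Gaussian noise (sd ``noise_sd``);
    left-over genes are pure noise and carry the grey truth label.  The
    whole matrix is shifted so its minimum is zero.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    X = np.empty((spec.n_genes, spec.n_samples))
    truth = pd.Series(GREY, index=genes, dtype=object)
    pos = 0
    for m, size in enumerate(spec.module_sizes, start=1):
        latent = rng.normal(0.0, spec.signal_sd, size=spec.n_samples)
        X[pos : pos + size] = latent + rng.normal(
            0.0, spec.noise_sd, size=(size, spec.n_samples)
        )
        truth.iloc[pos : pos + size] = f"M{m}"
        pos += size
    n_noise = spec.n_genes - pos
    if n_noise:
        sd = spec.noise_sd if spec.noise_sd > 0 else 1.0
        X[pos:] = rng.normal(0.0, sd, size=(n_noise, spec.n_samples))
    X = X - X.min()  # FPKM-like non-negative scale; correlations unchanged
    df = pd.DataFrame(X, index=genes, columns=[f"s{j + 1:02d}" for j in range(spec.n_samples)])
    return SimulatedExpression(ExpressionMatrix(df), truth)


@dataclass(frozen=True)
class SimulatedPromoters:
    genome: dict[str, str]
    coordinates: list[GeneCoordinate]
    promoters: PromoterSet  # the truth sequences
    enriched_genes: tuple[str, ...]
    planted_motif: str
    motifs: MotifLibrary


_BASES = np.array(list("ACGT"))
_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _instantiate(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(list(_IUPAC_CHOICES[c])) for c in consensus)


def _plant(rng: np.random.Generator, seq: str, consensus: str, copies: int) -> str:
    """Overwrite ``copies`` random non-overlapping windows with concrete
    instances of the consensus."""
    m = len(consensus)
    L = len(seq)
    if copies * m > L:
        raise ValidationError("planted copies exceed promoter capacity")
    out = list(seq)
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(taken) < copies:
        attempts += 1
        if attempts > 10000:
            raise ValidationError("cannot place planted copies without overlap")
        start = int(rng.integers(0, L - m + 1))
        if any(start < e and start + m > s for s, e in taken):
            continue
        out[start : start + m] = _instantiate(rng, consensus)
        taken.append((start, start + m))
    return "".join(out)


def simulate_promoters(spec: SimulationSpec, gene_ids: list[str] | None = None) -> SimulatedPromoters:
    """Generate a genome FASTA + GFF3 pair with known promoter truth.

    Genes are laid out on contigs (``genes_per_contig`` each), alternating
    strands; each gene's upstream window of ``promoter_length`` bases is
    uniform random sequence, with ``planted_copies`` concrete instances of
    the planted motif overwritten into the promoters of the first
    ``enriched_fraction`` of genes.  A library of background motifs is
    emitted alongside the planted one.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    n_enriched = max(1, int(round(spec.enriched_fraction * len(gene_ids))))
    enriched = tuple(gene_ids[:n_enriched])

    L, G = spec.promoter_length, spec.gene_body_length
    genome: dict[str, str] = {}
    coords: list[GeneCoordinate] = []
    records: dict[str, PromoterRecord] = {}
    for c_start in range(0, len(gene_ids), spec.genes_per_contig):
        contig_genes = gene_ids[c_start : c_start + spec.genes_per_contig]
        contig_id = f"chr{c_start // spec.genes_per_contig + 1}"
        parts: list[str] = []
        offset = 0  # 0-based length so far
        for j, g in enumerate(contig_genes):
            promoter = _random_seq(rng, L)
            if g in enriched:
                promoter = _plant(rng, promoter, spec.motif, spec.planted_copies)
            body = _random_seq(rng, G)
            strand = "+" if j % 2 == 0 else "-"
            if strand == "+":
                # layout: [promoter][body]; gene starts right after promoter
                parts.append(promoter + body)
                start = offset + L + 1
                end = offset + L + G
            else:
                # layout: [body][revcomp(promoter)]; promoter reads away from
                # the gene end on the minus strand
                parts.append(body + _revcomp(promoter))
                start = offset + 1
                end = offset + G
            coords.append(GeneCoordinate(g, contig_id, start, end, strand))
            records[g] = PromoterRecord(g, promoter, L)
            offset += L + G
        genome[contig_id] = "".join(parts)
    motifs = {"PLANTED": spec.motif}
    for i in range(spec.n_background_motifs):
        motifs[f"BG{i + 1}"] = _random_seq(rng, len(spec.motif))
    return SimulatedPromoters(
        genome=genome,
        coordinates=coords,
        promoters=PromoterSet(L, records),
        enriched_genes=enriched,
        planted_motif=spec.motif,
        motifs=MotifLibrary(motifs),
    )


def simulate_annotation(
    truth: pd.Series,
    contamination: float = 0.0,
    seed: int = 0,
    min_set_size: int = 1,
) -> GeneSetCollection:
    """One gene set per true module, optionally contaminated.

    With contamination c, a fraction c of each set's members is replaced by
    random genes drawn from outside the module, degrading the enrichment
    signal in a controlled way.  Empty modules emit no set.
    """
    if not (0.0 <= contamination < 1.0):
        raise ValidationError("contamination must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    all_genes = np.array(truth.index)
    sets: dict[str, GeneSet] = {}
    for module in sorted(set(truth) - {GREY}):
        members = list(truth.index[truth == module])
        if len(members) < min_set_size:
            continue
        if contamination > 0:
            n_swap = int(round(contamination * len(members)))
            if n_swap:
                outside = all_genes[~np.isin(all_genes, members)]
                n_swap = min(n_swap, outside.size)
                drop_idx = rng.choice(len(members), size=n_swap, replace=False)
                new = rng.choice(outside, size=n_swap, replace=False)
                for i, g in zip(sorted(drop_idx), new):
                    members[i] = str(g)
                members = list(dict.fromkeys(members))
        sets[f"SET_{module}"] = GeneSet(f"SET_{module}", f"true module {module}", tuple(members))
    return GeneSetCollection(sets)


def power_law_degrees(
    exponent: float = 2.0, k_max: int = 100, scale: int = 10_000
) -> np.ndarray:
    """A deterministic degree sequence following p(k) ~ k^-exponent exactly
    (frequencies rounded to large counts) over k = 1..k_max."""
    ks = np.arange(1, k_max + 1)
    counts = np.round(scale * ks.astype(float) ** (-exponent)).astype(int)
    return np.repeat(ks, counts)


def simulate_scale_free_correlation(
    n_nodes: int = 800,
    exponent: float = 2.3,
    mean_degree: float = 6.0,
    edge_pcc_range: tuple[float, float] = (0.62, 0.99),
    background_pcc_range: tuple[float, float] = (0.0, 0.55),
    seed: int = 0,
) -> "CorrelationMatrix":
    """A synthetic correlation matrix whose thresholded graph is scale-free.

    A Chung-Lu random graph with power-law expected degrees is planted:
    nodes i, j are connected with probability proportional to w_i w_j,
    where w follows k^-exponent.  Planted edges receive PCC values drawn
    uniformly from ``edge_pcc_range`` and non-edges from
    ``background_pcc_range``, so scanning cutoffs inside the gap between
    the two ranges progressively prunes the planted graph.
    """
    from .coexpression import CorrelationMatrix

    rng = np.random.default_rng(seed)
    # power-law weights via inverse-CDF sampling, truncated at k=1
    u = rng.uniform(size=n_nodes)
    w = (1.0 - u) ** (-1.0 / (exponent - 1.0))
    w *= mean_degree * n_nodes / w.sum()
    total = w.sum()
    p = np.clip(np.outer(w, w) / total, 0.0, 1.0)
    np.fill_diagonal(p, 0.0)
    upper = np.triu(rng.uniform(size=(n_nodes, n_nodes)) < p, k=1)
    edge = upper | upper.T
    lo_e, hi_e = edge_pcc_range
    lo_b, hi_b = background_pcc_range
    vals_edge = rng.uniform(lo_e, hi_e, size=(n_nodes, n_nodes))
    vals_bg = rng.uniform(lo_b, hi_b, size=(n_nodes, n_nodes))
    m = np.where(edge, vals_edge, vals_bg)
    m = np.triu(m, k=1)
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    genes = tuple(f"n{i + 1:04d}" for i in range(n_nodes))
    return CorrelationMatrix(genes, m)


def write_full_fixture(out_dir: str | Path, spec: SimulationSpec = SimulationSpec()) -> dict[str, Path]:
    """Write every toolkit input format to ``out_dir`` from one spec.

    Emits expression TSV, genome FASTA, GFF3, motif TSV and GMT annotation,
    plus the ground-truth module labels; returns the path of each file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_expression(spec)
    prom = simulate_promoters(spec, gene_ids=sim.expression.gene_ids)
    annot = simulate_annotation(sim.truth, seed=spec.seed)
    paths = {
        "expression": out_dir / "expression.tsv",
        "genome": out_dir / "genome.fa",
        "gff": out_dir / "genes.gff3",
        "motifs": out_dir / "motifs.tsv",
        "gmt": out_dir / "annotation.gmt",
        "truth": out_dir / "module_truth.tsv",
        "enriched": out_dir / "enriched_genes.txt",
    }
    write_expression_tsv(sim.expression, paths["expression"])
    write_fasta(prom.genome, paths["genome"])
    write_gff_genes(prom.coordinates, paths["gff"])
    write_motif_tsv(prom.motifs, paths["motifs"])
    write_gmt(annot, paths["gmt"])
    sim.truth.rename("module").to_csv(paths["truth"], sep="\t", index_label="gene_id")
    paths["enriched"].write_text("\n".join(prom.enriched_genes) + "\n")
    return paths
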