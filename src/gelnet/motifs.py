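"""Empirical promoter cis-element (motif) enrichment.

A query gene list's promoters are scanned for each IUPAC consensus motif
(both strands, overlapping matches counted).  The expected match level is
estimated empirically: B random gene lists of the same size are drawn from
the promoter universe, every sampled promoter is scanned, and the pooled
per-gene counts give a null mean mu and standard deviation sigma.  The
query is then summarized as

    Z = (xbar - mu) / (sigma / sqrt(n))
    P = 1 - Phi(Z)                       (upper-tail normal probability)

and a motif is called significantly enriched when P < 0.05.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .io import IUPAC_LETTERS, MotifLibrary, PromoterSet

__all__ = [
    "MotifEnrichmentResult",
    "NullModel",
    "scan_motif",
    "mean_matches",
    "count_matrix",
    "build_null",
    "motif_z",
    "motif_p",
    "motif_enrich",
]

# IUPAC degeneracy -> regex character class.  A plain N in the scanned
# sequence matches only the motif letter N, so no other class contains N.
_IUPAC_CLASS = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "[AG]",
    "Y": "[CT]",
    "S": "[CG]",
    "W": "[AT]",
    "K": "[GT]",
    "M": "[AC]",
    "B": "[CGT]",
    "D": "[AGT]",
    "H": "[ACT]",
    "V": "[ACG]",
    "N": "[ACGTN]",
}

_RC = str.maketrans("ACGTN", "TGCAN")


def _compile(consensus: str) -> re.Pattern:
    consensus = consensus.upper()
    bad = set(consensus) - IUPAC_LETTERS
    if bad:
        raise ValidationError(f"invalid IUPAC letter(s) {sorted(bad)} in {consensus!r}")
    if not consensus:
        raise ValidationError("empty consensus")
    # lookahead makes overlapping occurrences count
    return re.compile("(?=" + "".join(_IUPAC_CLASS[c] for c in consensus) + ")")


def scan_motif(sequence: str, consensus: str) -> int:
    """Number of matches of an IUPAC consensus in a DNA sequence.

    Counts every (possibly overlapping) forward-strand position plus every
    match of the consensus against the reverse complement of the sequence;
    a palindromic site therefore counts twice.  A motif longer than the
    sequence yields 0.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"sequence has invalid base(s) {sorted(bad)}")
    pat = _compile(consensus)
    rc = seq.translate(_RC)[::-1]
    return len(pat.findall(seq)) + len(pat.findall(rc))


def count_matrix(promoters: PromoterSet, motifs: MotifLibrary) -> pd.DataFrame:
    """Gene x motif table of match counts over the whole promoter universe.

    Scanning is the expensive step of the empirical null; computing this
    table once lets ``build_null`` reduce to index sampling.
    """
    genes = promoters.gene_ids
    data = {}
    for motif_id, consensus in motifs:
        pat = _compile(consensus)
        col = np.empty(len(genes), dtype=np.int64)
        for i, g in enumerate(genes):
            seq = promoters.sequence(g)
            rc = seq.translate(_RC)[::-1]
            col[i] = len(pat.findall(seq)) + len(pat.findall(rc))
        data[motif_id] = col
    return pd.DataFrame(data, index=genes)


def mean_matches(
    promoters: PromoterSet,
    genes: Sequence[str],
    consensus: str,
) -> float:
    """Mean motif match count over the listed genes' promoters.

    Genes without a promoter entry are dropped with a warning; an all-
    missing list is an error.
    """
    import warnings

    present = [g for g in genes if g in promoters]
    missing = [g for g in genes if g not in promoters]
    if not present:
        raise ValidationError("no listed gene has a promoter entry")
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) without promoters dropped from mean", stacklevel=2
        )
    return float(np.mean([scan_motif(promoters.sequence(g), consensus) for g in present]))


@dataclass(frozen=True)
class NullModel:
    """Empirical null for motif counts: per-motif (mu, sigma) from B random
    same-size gene lists drawn from the promoter universe."""

    stats: pd.DataFrame  # index motif_id, columns mu, sigma
    n_draws: int
    set_size: int
    promoter_length: int
    seed: int | None
    sigma_mode: str = "per_gene"

    def mu(self, motif_id: str) -> float:
        return float(self.stats.loc[motif_id, "mu"])

    def sigma(self, motif_id: str) -> float:
        return float(self.stats.loc[motif_id, "sigma"])


def build_null(
    promoters: PromoterSet,
    motifs: MotifLibrary,
    set_size: int,
    n_draws: int = 1000,
    seed: int | None = None,
    counts: pd.DataFrame | None = None,
    sigma_mode: str = "per_gene",
) -> NullModel:
    """Estimate the null motif-count distribution by random gene-list draws.

    ``n_draws`` gene lists of ``set_size`` genes are sampled uniformly
    without replacement (within a list) from the promoter universe.  With
    ``sigma_mode="per_gene"`` (default), mu and sigma are the mean and
    standard deviation of the per-gene counts pooled over all sampled
    promoters — the reading consistent with dividing sigma by sqrt(n) in
    the Z score.  ``sigma_mode="set_mean"`` instead uses the spread of the
    B list means.  Deterministic given ``seed``.
    """
    if sigma_mode not in ("per_gene", "set_mean"):
        raise ValidationError("sigma_mode must be 'per_gene' or 'set_mean'")
    universe = promoters.gene_ids
    if set_size < 1 or n_draws < 1:
        raise ValidationError("set_size and n_draws must be >= 1")
    if set_size > len(universe):
        raise ValidationError(
            f"set_size {set_size} exceeds promoter universe of {len(universe)}"
        )
    if counts is None:
        counts = count_matrix(promoters, motifs)
    else:
        missing = set(universe) - set(counts.index)
        if missing:
            raise ValidationError(f"counts table lacks {len(missing)} universe gene(s)")
        counts = counts.loc[universe]
    rng = np.random.default_rng(seed)
    C = counts.to_numpy(dtype=float)
    m = len(universe)
    idx = np.empty((n_draws, set_size), dtype=np.int64)
    for b in range(n_draws):
        idx[b] = rng.choice(m, size=set_size, replace=False)
    sampled = C[idx]  # (B, n, n_motifs)
    if sigma_mode == "per_gene":
        pooled = sampled.reshape(-1, C.shape[1])
        mu = pooled.mean(axis=0)
        sigma = pooled.std(axis=0, ddof=1) if pooled.shape[0] > 1 else np.zeros(C.shape[1])
    else:
        means = sampled.mean(axis=1)  # (B, n_motifs)
        mu = means.mean(axis=0)
        sigma = means.std(axis=0, ddof=1) if n_draws > 1 else np.zeros(C.shape[1])
    stats = pd.DataFrame({"mu": mu, "sigma": sigma}, index=counts.columns)
    return NullModel(
        stats,
        n_draws=n_draws,
        set_size=set_size,
        promoter_length=promoters.requested_length,
        seed=seed,
        sigma_mode=sigma_mode,
    )


def motif_z(x_bar: float, mu: float, sigma: float, n: int) -> float:
    """Standardized enrichment score Z = (xbar - mu) / (sigma / sqrt(n))."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sigma <= 0:
        raise ValidationError("sigma must be positive; degenerate nulls are flagged upstream")
    return float((x_bar - mu) / (sigma / np.sqrt(n)))


def motif_p(z: float) -> float:
    """Upper-tail normal probability P = 1 - Phi(Z)."""
    return float(norm.sf(z))


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif_id: str
    consensus: str
    x_bar: float
    mu: float
    sigma: float
    n: int
    z: float | None
    p: float
    degenerate: bool

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def motif_enrich(
    query_genes: Iterable[str],
    promoters: PromoterSet,
    motifs: MotifLibrary,
    n_draws: int = 1000,
    seed: int | None = None,
    counts: pd.DataFrame | None = None,
    sigma_mode: str = "per_gene",
    null_model: NullModel | None = None,
) -> pd.DataFrame:
    """Empirical enrichment of every motif in a query gene list's promoters.

    Combines the per-motif query mean, the random-draw null (mu, sigma) and
    the Z / P statistics; motifs are flagged significant at P < 0.05 and
    rows are sorted by P ascending (ties by motif id).  When the null sigma
    is zero the Z score is undefined and P is set to 1 if xbar <= mu, else
    0, with ``degenerate=True``.
    """
    query = [g for g in dict.fromkeys(query_genes)]
    present = [g for g in query if g in promoters]
    if not present:
        raise ValidationError("no query gene has a promoter entry")
    if counts is None:
        counts = count_matrix(promoters, motifs)
    n = len(present)
    if null_model is None:
        null_model = build_null(
            promoters,
            motifs,
            set_size=n,
            n_draws=n_draws,
            seed=seed,
            counts=counts,
            sigma_mode=sigma_mode,
        )
    rows = []
    for motif_id, consensus in motifs:
        x_bar = float(counts.loc[present, motif_id].mean())
        mu = null_model.mu(motif_id)
        sigma = null_model.sigma(motif_id)
        if sigma <= 0:
            z, p, degenerate = np.nan, (1.0 if x_bar <= mu else 0.0), True
        else:
            z = motif_z(x_bar, mu, sigma, n)
            p = motif_p(z)
            degenerate = False
        rows.append(
            {
                "motif_id": motif_id,
                "consensus": consensus,
                "x_bar": x_bar,
                "mu": mu,
                "sigma": sigma,
                "n": n,
                "z": z,
                "p": p,
                "significant": p < 0.05,
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["p", "motif_id"], kind="mergesort").reset_index(drop=True)
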