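"""Pearson co-expression networks with scale-free-topology cutoff selection.

The workflow mirrors how plant co-expression platforms pick a hard
correlation threshold: compute all pairwise Pearson correlation
coefficients (PCC), scan a grid of candidate cutoffs, and keep the cutoff
whose thresholded graph maximizes the scale-free topology fitting index
R^2 while keeping network density low.  Positive (PCC > c+) and negative
(PCC < c-) networks are built separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import UndefinedStatisticError, ValidationError
from .io import ExpressionMatrix, canonical_edges

__all__ = [
    "CorrelationMatrix",
    "ThresholdScan",
    "CoexpressionNetwork",
    "ThresholdSelector",
    "pearson",
    "correlation_matrix",
    "network_density",
    "scale_free_fit",
    "scan_thresholds",
    "select_cutoff",
    "build_network",
    "DEFAULT_CUTOFF_GRID",
]

#: Candidate |PCC| cutoffs scanned by default.
DEFAULT_CUTOFF_GRID = (0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient between two expression profiles.

    PCC_xy = sum((x_i - xbar)(y_i - ybar)) /
             sqrt(sum((x_i - xbar)^2) * sum((y_i - ybar)^2))

    Requires n >= 3 samples and non-constant vectors; a constant vector
    makes the denominator zero and raises
    :class:`~gelnet.errors.UndefinedStatisticError` so the caller can decide
    whether to exclude the gene.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 samples, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    r = float((xc * yc).sum() / denom)
    return min(1.0, max(-1.0, r))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric pairwise PCC matrix over the genes that survived filtering."""

    gene_ids: tuple[str, ...]
    matrix: np.ndarray
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValidationError("matrix shape does not match gene_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(m)) > 1 + 1e-12:
            raise ValidationError("correlation entries must lie in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.gene_ids)


def correlation_matrix(
    em: ExpressionMatrix,
    min_expressed_samples: int = 2,
    min_fpkm: float = 1.0,
) -> CorrelationMatrix:
    """All-pairs PCC after a minimal expression filter.

    Genes expressed (value >= ``min_fpkm``) in fewer than
    ``min_expressed_samples`` samples, or with zero variance, are excluded
    and reported in ``CorrelationMatrix.excluded`` with a reason.
    """
    X = em.data.to_numpy(dtype=float)
    genes = np.array(em.gene_ids)
    expressed = (X >= min_fpkm).sum(axis=1) >= min_expressed_samples
    nonconst = X.std(axis=1) > 0.0
    keep = expressed & nonconst
    excluded: dict[str, str] = {}
    for g, e, c in zip(genes, expressed, nonconst):
        if not e:
            excluded[g] = "low_expression"
        elif not c:
            excluded[g] = "zero_variance"
    if keep.sum() < 2:
        raise ValidationError(
            f"only {int(keep.sum())} gene(s) pass the expression filter; need >= 2"
        )
    Xk = X[keep]
    with np.errstate(invalid="ignore"):
        m = np.corrcoef(Xk)
    m = np.clip(m, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return CorrelationMatrix(tuple(genes[keep]), m, excluded)


def network_density(n_nodes: int, n_edges: int) -> float:
    """Realized fraction of possible edges: 2E / (N (N - 1))."""
    if n_nodes < 2:
        raise ValidationError(f"need >= 2 nodes, got {n_nodes}")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges < 0 or n_edges > max_edges:
        raise ValidationError(f"{n_edges} edges impossible for {n_nodes} nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def scale_free_fit(degrees: Sequence[float], n_bins: int = 10) -> float | None:
    """Scale-free topology fitting index R^2 of a degree sequence.

    Positive degrees are binned into ``n_bins`` equal-width bins; for each
    non-empty bin the mean degree and the relative frequency are computed,
    and R^2 is the squared Pearson correlation between log10(frequency) and
    log10(mean degree) over the non-empty bins.  Real-valued degrees
    (weighted connectivities) are accepted.  Returns ``None`` when fewer
    than two non-empty bins exist (the fit is undefined, not an error).
    """
    k = np.asarray(degrees, dtype=float)
    k = k[k > 0]
    if k.size == 0:
        return None
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    lo, hi = k.min(), k.max()
    if lo == hi:
        return None
    edges = np.linspace(lo, hi, n_bins + 1)
    # right-inclusive last bin so the max degree is counted
    idx = np.clip(np.digitize(k, edges[1:-1], right=False), 0, n_bins - 1)
    mean_k = np.full(n_bins, np.nan)
    freq = np.zeros(n_bins)
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            mean_k[b] = k[mask].mean()
            freq[b] = mask.sum() / k.size
    ok = freq > 0
    if ok.sum() < 2:
        return None
    log_k = np.log10(mean_k[ok])
    log_f = np.log10(freq[ok])
    if np.ptp(log_k) == 0 or np.ptp(log_f) == 0:
        return None
    r = np.corrcoef(log_k, log_f)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ThresholdScan:
    """Per-cutoff edge counts, densities and scale-free fits."""

    sign: str
    table: pd.DataFrame  # columns: cutoff, n_nodes, n_edges, density, r_squared

    def __post_init__(self) -> None:
        need = {"cutoff", "n_nodes", "n_edges", "density", "r_squared"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"scan table missing columns {sorted(need - set(self.table.columns))}")
        if self.sign not in ("positive", "negative"):
            raise ValidationError("sign must be 'positive' or 'negative'")


def _thresholded_degrees(m: np.ndarray, cutoff: float, sign: str) -> np.ndarray:
    if sign == "positive":
        adj = m >= cutoff
    else:
        adj = m <= -abs(cutoff)
    np.fill_diagonal(adj, False)
    return adj.sum(axis=1)


def scan_thresholds(
    cm: CorrelationMatrix,
    cutoffs: Sequence[float] = DEFAULT_CUTOFF_GRID,
    sign: str = "positive",
    n_bins: int = 10,
) -> ThresholdScan:
    """Build the thresholded graph at each candidate cutoff and record edge
    count, density over non-isolated nodes, and scale-free fit R^2.

    For the positive network an edge survives when PCC >= cutoff; for the
    negative network when PCC <= -|cutoff|.  Two density conventions are
    reported: ``density`` over nodes with degree >= 1 at that cutoff (the
    graph actually built, used by :func:`select_cutoff`) and
    ``density_all`` over the full correlated gene set, which is guaranteed
    monotone non-increasing along the grid.  An empty graph is recorded
    with zero edges and an undefined R^2.
    """
    if sign not in ("positive", "negative"):
        raise ValidationError("sign must be 'positive' or 'negative'")
    abs_cut = [abs(c) for c in cutoffs]
    if abs_cut != sorted(abs_cut):
        raise ValidationError("cutoffs must be sorted ascending in absolute value")
    rows = []
    for cutoff in cutoffs:
        deg = _thresholded_degrees(cm.matrix, abs(cutoff), sign)
        n_edges = int(deg.sum()) // 2
        connected = deg[deg > 0]
        n_nodes = int(connected.size)
        density = network_density(n_nodes, n_edges) if n_nodes >= 2 else 0.0
        r2 = scale_free_fit(connected, n_bins=n_bins) if n_nodes else None
        rows.append(
            {
                "cutoff": abs(cutoff) if sign == "positive" else -abs(cutoff),
                "n_nodes": n_nodes,
                "n_nodes_total": cm.n_genes,
                "n_edges": n_edges,
                "density": density,
                "density_all": network_density(cm.n_genes, n_edges),
                "r_squared": np.nan if r2 is None else r2,
            }
        )
    return ThresholdScan(sign, pd.DataFrame(rows))


def select_cutoff(scan: ThresholdScan, max_density: float = 0.05) -> float:
    """Pick the scanned cutoff maximizing R^2 subject to density <= bound.

    Ties in R^2 break toward the smaller |cutoff| (the denser, more
    informative network).
    """
    t = scan.table
    defined = t[np.isfinite(t["r_squared"])]
    if defined.empty:
        raise ValidationError("no scanned cutoff has a defined scale-free fit")
    ok = defined[defined["density"] <= max_density]
    if ok.empty:
        raise ValidationError(
            f"no cutoff satisfies density <= {max_density}; try a larger bound "
            f"(minimum scanned density is {defined['density'].min():.4g})"
        )
    ok = ok.assign(abs_cutoff=ok["cutoff"].abs()).sort_values(
        ["r_squared", "abs_cutoff"], ascending=[False, True], kind="mergesort"
    )
    return float(ok["cutoff"].iloc[0])


@dataclass(frozen=True)
class CoexpressionNetwork:
    """A signed, hard-thresholded co-expression network.

    ``edges`` holds the canonical (gene_a < gene_b) edge list with PCC
    weights; node counts are reported both for all correlated genes and for
    the non-isolated subset actually present in the edge list.
    """

    sign: str
    cutoff: float
    edges: pd.DataFrame  # columns gene_a, gene_b, pcc
    genes: tuple[str, ...] = ()  # full correlated gene universe (may exceed edges)

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise ValidationError("sign must be 'positive' or 'negative'")
        e = self.edges
        if (e["gene_a"] == e["gene_b"]).any():
            raise ValidationError("self-loop in edge list")
        if self.sign == "positive":
            if not (e["pcc"] > self.cutoff).all():
                raise ValidationError("positive edge violates cutoff")
        else:
            if not (e["pcc"] < self.cutoff).all():
                raise ValidationError("negative edge violates cutoff")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_ids(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    @property
    def n_nodes_connected(self) -> int:
        return len(self.node_ids)

    @property
    def n_genes_total(self) -> int:
        return len(self.genes) if self.genes else len(self.node_ids)


def _edges_from_matrix(cm: CorrelationMatrix, mask: np.ndarray) -> pd.DataFrame:
    iu = np.triu_indices(cm.n_genes, k=1)
    keep = mask[iu]
    genes = np.asarray(cm.gene_ids)
    df = pd.DataFrame(
        {
            "gene_a": genes[iu[0][keep]],
            "gene_b": genes[iu[1][keep]],
            "pcc": cm.matrix[iu][keep],
        }
    )
    return canonical_edges(df)


def build_network(
    cm: CorrelationMatrix,
    pos_cutoff: float = 0.8,
    neg_cutoff: float = -0.75,
) -> tuple[CoexpressionNetwork, CoexpressionNetwork]:
    """Build the positive (PCC > pos_cutoff) and negative (PCC < neg_cutoff)
    networks with strict inequalities at the cutoffs."""
    if not (0.0 < pos_cutoff <= 1.0):
        raise ValidationError(f"pos_cutoff must be in (0, 1], got {pos_cutoff}")
    if not (-1.0 <= neg_cutoff < 0.0):
        raise ValidationError(f"neg_cutoff must be in [-1, 0), got {neg_cutoff}")
    pos = CoexpressionNetwork(
        "positive",
        pos_cutoff,
        _edges_from_matrix(cm, cm.matrix > pos_cutoff),
        cm.gene_ids,
    )
    neg = CoexpressionNetwork(
        "negative",
        neg_cutoff,
        _edges_from_matrix(cm, cm.matrix < neg_cutoff),
        cm.gene_ids,
    )
    return pos, neg


class ThresholdSelector(BaseEstimator):
    """Scale-free-topology hard-threshold selection as an estimator.

    Scans a grid of candidate |PCC| cutoffs on the pairwise correlation
    structure of a genes x samples expression matrix and selects the cutoff
    maximizing the scale-free fitting index R^2 under a density bound.

    Parameters
    ----------
    cutoffs : sequence of float
        Candidate cutoffs, ascending in absolute value.
    sign : {"positive", "negative"}
        Which tail of the correlation distribution forms edges.
    max_density : float
        Upper bound on the density of the selected network.
    n_bins : int
        Equal-width degree bins for the log-log R^2 fit.
    min_expressed_samples, min_fpkm
        Expression filter applied before correlation.

    Attributes
    ----------
    scan_ : ThresholdScan
        Per-cutoff edge counts, densities and R^2 values.
    cutoff_ : float
        The selected cutoff (signed).
    correlation_ : CorrelationMatrix
        The filtered pairwise PCC matrix the scan was run on.
    """

    def __init__(
        self,
        cutoffs: Sequence[float] = DEFAULT_CUTOFF_GRID,
        sign: str = "positive",
        max_density: float = 0.05,
        n_bins: int = 10,
        min_expressed_samples: int = 2,
        min_fpkm: float = 1.0,
    ):
        self.cutoffs = cutoffs
        self.sign = sign
        self.max_density = max_density
        self.n_bins = n_bins
        self.min_expressed_samples = min_expressed_samples
        self.min_fpkm = min_fpkm

    def fit(self, X, y=None) -> "ThresholdSelector":
        """Fit on a genes x samples DataFrame, ExpressionMatrix or an
        already-computed CorrelationMatrix."""
        if isinstance(X, CorrelationMatrix):
            cm = X
        else:
            if isinstance(X, pd.DataFrame):
                X = ExpressionMatrix(X.astype(float))
            if not isinstance(X, ExpressionMatrix):
                raise ValidationError(
                    "X must be a DataFrame, ExpressionMatrix or CorrelationMatrix"
                )
            cm = correlation_matrix(
                X,
                min_expressed_samples=self.min_expressed_samples,
                min_fpkm=self.min_fpkm,
            )
        self.correlation_ = cm
        self.scan_ = scan_thresholds(cm, self.cutoffs, self.sign, n_bins=self.n_bins)
        self.cutoff_ = select_cutoff(self.scan_, self.max_density)
        return self
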