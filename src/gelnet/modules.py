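"""WGCNA-style functional-module detection.

Pipeline: unsigned soft-threshold adjacency a_ij = |PCC_ij|^beta ->
topological overlap matrix (TOM) -> average-linkage clustering of 1 - TOM
-> static-height dendrogram cut with a minimum module size -> module
eigengenes (first principal component of the standardized member profiles)
-> iterative merging of modules whose eigengenes are highly correlated.

Genes that end up in no module carry the conventional label ``"grey"``;
real modules are labelled M1, M2, ... in decreasing size order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .coexpression import CorrelationMatrix, correlation_matrix, scale_free_fit
from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "DetectionConfig",
    "ModulePartition",
    "ModuleDetector",
    "soft_threshold_scan",
    "adjacency",
    "tom_similarity",
    "cluster_modules",
    "module_eigengene",
    "merge_modules",
    "GREY",
]

GREY = "grey"


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the module-detection pipeline.

    soft_power : exponent beta applied to |PCC| (default 7).
    min_module_size : smallest cluster kept as a module (default 30).
    cut_height : static cut as a fraction of the maximal merge height
        (default 0.9, the conventional static-cut height).
    merge_cut_height : eigengene dissimilarity (1 - PCC) below which two
        modules merge (default 0.25).
    """

    soft_power: int = 7
    min_module_size: int = 30
    cut_height: float = 0.9
    merge_cut_height: float = 0.25

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValidationError("soft_power must be a positive integer")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if not (0.0 < self.cut_height <= 1.0):
            raise ValidationError("cut_height must lie in (0, 1]")
        if not (0.0 <= self.merge_cut_height <= 1.0):
            raise ValidationError("merge_cut_height must lie in [0, 1]")


@dataclass(frozen=True)
class ModulePartition:
    """Gene -> module assignment plus per-module eigengenes.

    ``labels`` maps every clustered gene to a module name ("grey" =
    unassigned); ``eigengenes`` is a module x sample DataFrame of
    unit-length first principal components.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    config: DetectionConfig

    def __post_init__(self) -> None:
        sizes = self.labels[self.labels != GREY].value_counts()
        too_small = sizes[sizes < self.config.min_module_size]
        if len(too_small):
            raise ValidationError(
                f"module(s) smaller than min_module_size: {dict(too_small)}"
            )
        missing = set(sizes.index) - set(self.eigengenes.index)
        if missing:
            raise ValidationError(f"module(s) without eigengene: {sorted(missing)}")

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.eigengenes.index]

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def soft_threshold_scan(
    cm: CorrelationMatrix,
    powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free fit and mean connectivity per candidate soft power.

    For each power beta the weighted connectivity k_i = sum_j |PCC_ij|^beta
    (j != i) is computed; R^2 is the scale-free fit of the connectivity
    distribution and mean connectivity the average k_i.
    """
    rows = []
    for beta in powers:
        if beta < 1:
            raise ValidationError("powers must be >= 1")
        a = adjacency(cm, beta)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2 = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": beta,
                "r_squared": np.nan if r2 is None else r2,
                "mean_connectivity": float(k.mean()),
            }
        )
    return pd.DataFrame(rows)


def adjacency(cm: CorrelationMatrix, beta: int = 7) -> np.ndarray:
    """Unsigned soft-threshold adjacency |PCC|^beta with unit diagonal."""
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    a = np.abs(cm.matrix) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    the diagonal is 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    # (a0 @ a0)_ij sums a_iu a_uj over all u; the u = i and u = j terms
    # vanish because the diagonal of a0 is zero, giving L_ij exactly.
    L = a0 @ a0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a0) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _rank_labels(labels: pd.Series, min_module_size: int) -> pd.Series:
    """Relabel raw cluster ids as M1, M2, ... by decreasing size; clusters
    below the minimum size become grey.  Ties in size break by first member
    position for determinism."""
    out = pd.Series(GREY, index=labels.index, dtype=object)
    counts: dict[int, int] = labels.value_counts().to_dict()
    first_pos = {}
    for pos, lab in enumerate(labels):
        first_pos.setdefault(lab, pos)
    eligible = [lab for lab, n in counts.items() if n >= min_module_size]
    eligible.sort(key=lambda lab: (-counts[lab], first_pos[lab]))
    for rank, lab in enumerate(eligible, start=1):
        out[labels == lab] = f"M{rank}"
    return out


def cluster_modules(
    tom: np.ndarray,
    gene_ids: Sequence[str],
    config: DetectionConfig = DetectionConfig(),
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static-height cut.

    The dendrogram is cut at ``config.cut_height`` times the maximal merge
    height; clusters smaller than ``min_module_size`` are labelled grey.
    Returns a gene -> label Series (pre-merge partition).
    """
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValidationError("TOM shape does not match gene_ids")
    if n < config.min_module_size:
        import warnings

        warnings.warn(
            f"only {n} genes (< min_module_size={config.min_module_size}); all grey",
            stacklevel=2,
        )
        return pd.Series(GREY, index=list(gene_ids), dtype=object)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    max_h = Z[:, 2].max() if len(Z) else 0.0
    if max_h <= 0:
        raw = pd.Series(1, index=list(gene_ids))
    else:
        raw = pd.Series(
            fcluster(Z, t=config.cut_height * max_h, criterion="distance"),
            index=list(gene_ids),
        )
    return _rank_labels(raw, config.min_module_size)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengene(em: ExpressionMatrix, members: Iterable[str]) -> np.ndarray:
    """First principal component across samples of a module's standardized
    expression, sign-fixed to correlate non-negatively with the mean
    standardized profile, scaled to unit length."""
    members = list(members)
    if not members:
        raise ValidationError("module must have >= 1 member")
    missing = [g for g in members if g not in em.data.index]
    if missing:
        raise ValidationError(f"gene(s) not in expression matrix: {missing[:5]}")
    X = _standardize(em.data.loc[members].to_numpy(dtype=float))
    # right singular vector of the member x sample matrix = PC over samples
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    e = vt[0]
    mean_profile = X.mean(axis=0)
    if float(e @ mean_profile) < 0:
        e = -e
    norm = np.linalg.norm(e)
    return e / norm if norm > 0 else e


def _eigengene_frame(em: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    modules = sorted(set(labels) - {GREY}, key=lambda m: (len(m), m))
    rows = {m: module_eigengene(em, labels.index[labels == m]) for m in modules}
    return pd.DataFrame.from_dict(rows, orient="index", columns=em.sample_ids)


def merge_modules(
    labels: pd.Series,
    em: ExpressionMatrix,
    merge_cut_height: float = 0.25,
) -> pd.Series:
    """Iteratively merge the closest module pair while their eigengene
    dissimilarity 1 - PCC(E_i, E_j) is below ``merge_cut_height``,
    recomputing eigengenes after every merge.  Grey genes never merge."""
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {GREY})
        if len(modules) < 2:
            break
        eig = _eigengene_frame(em, labels)
        E = eig.loc[modules].to_numpy()
        C = np.corrcoef(E)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] >= merge_cut_height:
            break
        keep, drop = sorted((modules[i], modules[j]))
        labels[labels == drop] = keep
    # re-rank after merging so names reflect final sizes
    out = pd.Series(GREY, index=labels.index, dtype=object)
    non_grey = labels != GREY
    if non_grey.any():
        raw = labels[non_grey].map(
            {m: idx for idx, m in enumerate(sorted(set(labels[non_grey])))}
        )
        out[non_grey] = _rank_labels(raw, min_module_size=1)
    return out


class ModuleDetector(BaseEstimator, ClusterMixin):
    """WGCNA-style module detection as a clustering estimator.

    Given a genes x samples expression matrix, computes pairwise Pearson
    correlations, raises them to ``power`` to form an unsigned adjacency,
    converts that to topological overlap, clusters 1 - TOM with average
    linkage, cuts the tree at a static height, discards clusters below
    ``min_module_size`` into the grey bin, and merges modules whose
    eigengenes correlate above ``1 - merge_cut_height``.

    Parameters
    ----------
    power : int
        Soft-threshold exponent beta (default 7).
    min_module_size : int
        Minimum genes per module (default 30).
    cut_height : float
        Static cut as a fraction of the tallest dendrogram merge.
    merge_cut_height : float
        Eigengene dissimilarity below which modules merge (default 0.25).
    min_expressed_samples, min_fpkm
        Expression filter forwarded to the correlation step.

    Attributes
    ----------
    labels_ : pandas.Series
        Gene -> module label ("grey" for unassigned); excluded genes are
        absent.
    eigengenes_ : pandas.DataFrame
        Module x sample matrix of unit-norm eigengenes.
    partition_ : ModulePartition
        Labels, eigengenes and the configuration bundled together.
    premerge_labels_ : pandas.Series
        The partition before eigengene merging.
    """

    def __init__(
        self,
        power: int = 7,
        min_module_size: int = 30,
        cut_height: float = 0.9,
        merge_cut_height: float = 0.25,
        min_expressed_samples: int = 2,
        min_fpkm: float = 1.0,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_cut_height = merge_cut_height
        self.min_expressed_samples = min_expressed_samples
        self.min_fpkm = min_fpkm

    def _config(self) -> DetectionConfig:
        return DetectionConfig(
            soft_power=self.power,
            min_module_size=self.min_module_size,
            cut_height=self.cut_height,
            merge_cut_height=self.merge_cut_height,
        )

    def fit(self, X, y=None) -> "ModuleDetector":
        """Fit on a genes x samples DataFrame or ExpressionMatrix."""
        if isinstance(X, pd.DataFrame):
            X = ExpressionMatrix(X.astype(float))
        if not isinstance(X, ExpressionMatrix):
            raise ValidationError("X must be a genes x samples DataFrame or ExpressionMatrix")
        config = self._config()
        cm = correlation_matrix(
            X,
            min_expressed_samples=self.min_expressed_samples,
            min_fpkm=self.min_fpkm,
        )
        tom = tom_similarity(adjacency(cm, config.soft_power))
        pre = cluster_modules(tom, cm.gene_ids, config)
        self.premerge_labels_ = pre
        merged = merge_modules(pre, X, config.merge_cut_height)
        eig = _eigengene_frame(X, merged)
        self.labels_ = merged
        self.eigengenes_ = eig
        self.partition_ = ModulePartition(merged, eig, config)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()
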