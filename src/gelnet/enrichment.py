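"""Over-representation gene-set enrichment with exact and asymptotic tests.

A query gene list is tested against every annotated gene set by asking how
surprising the observed overlap k is given the background universe of N
genes, a set of K annotated genes and a query of n genes.  The default test
is the upper-tail hypergeometric probability P(X >= k); Fisher's exact test
(one-sided, equivalent) and the 1-df chi-square test are alternatives.  Six
multiple-testing corrections are provided: Bonferroni, Holm, Hochberg,
Hommel, Benjamini-Hochberg and Benjamini-Yekutieli.

The hypergeometric mass is evaluated in log space (log-gamma) for
numerical stability at genome-scale N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import ValidationError
from .io import GeneSetCollection

__all__ = [
    "EnrichmentQuery",
    "hypergeom_pmf",
    "hypergeom_tail",
    "fisher_exact_2x2",
    "chisq_2x2",
    "adjust_pvalues",
    "gsea",
    "TESTS",
    "CORRECTIONS",
]

TESTS = ("hypergeometric", "fisher", "chisq")
CORRECTIONS = ("bonferroni", "holm", "hochberg", "hommel", "BH", "BY")


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _check_hypergeom_args(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(X = k) for the overlap of a size-n draw with a size-K set in a
    universe of N genes: C(n,k) C(N-n, K-k) / C(N,K)."""
    _check_hypergeom_args(N, K, n, k)
    if K - k > N - n:  # impossible configuration, zero mass
        return 0.0
    logp = _log_comb(n, k) + _log_comb(N - n, K - k) - _log_comb(N, K)
    return float(np.exp(logp))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail enrichment p-value P(X >= k)."""
    _check_hypergeom_args(N, K, n, k)
    hi = min(n, K)
    total = sum(hypergeom_pmf(N, K, n, i) for i in range(k, hi + 1))
    return float(min(1.0, max(0.0, total)))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table
    [[a, b], [c, d]] = [[k, n-k], [K-k, N-n-K+k]].

    With margins fixed this equals the hypergeometric upper tail at k = a.
    """
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValidationError("2x2 table cells must be non-negative")
    N = a + b + c + d
    K = a + c
    n = a + b
    return hypergeom_tail(N, K, n, a)


def chisq_2x2(table: Sequence[Sequence[float]], continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 table (1 df).

    Returns ``(statistic, p_value)``.  No continuity correction by default;
    a zero expected count is an error (the exact test should be used).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any():
        raise ValidationError("table cells must be non-negative")
    total = t.sum()
    if total == 0:
        raise ValidationError("empty table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValidationError("zero expected count; use the exact test instead")
    diff = np.abs(t - expected)
    if continuity:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(chi2.sf(stat, df=1))
    return stat, p


# ---------------------------------------------------------------------------
# multiple-testing corrections
#
# All six methods are implemented directly (step-up/step-down recursions as
# published); statsmodels provides the same methods and is used as an
# independent cross-check in the test suite.

def _adjust_bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(p * p.size, 1.0)


def _adjust_holm(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


def _adjust_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj
    return out


def _adjust_hommel(p: np.ndarray) -> np.ndarray:
    # Hommel (1988) adjustment via the standard O(m^2) recursion.
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q = np.full(m, min(float(np.min(m * ps / np.arange(1, m + 1))), 1.0))
    pa = q.copy()
    for j in range(m - 1, 1, -1):
        i1 = np.arange(m - j + 1)
        i2 = np.arange(m - j + 1, m)
        q1 = np.min(j * ps[i2] / np.arange(2, j + 1))
        q[i1] = np.minimum(j * ps[i1], q1)
        q[i2] = q[m - j]
        pa = np.maximum(pa, q)
    adj = np.minimum(np.maximum(pa, ps), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _adjust_bh(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _adjust_by(p: np.ndarray) -> np.ndarray:
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


_ADJUST = {
    "bonferroni": _adjust_bonferroni,
    "holm": _adjust_holm,
    "hochberg": _adjust_hochberg,
    "hommel": _adjust_hommel,
    "BH": _adjust_bh,
    "BY": _adjust_by,
}


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Adjust raw p-values for multiple testing.

    ``method`` is one of bonferroni, holm, hochberg, hommel, BH
    (Benjamini-Hochberg FDR) or BY (Benjamini-Yekutieli FDR).  Input order
    is preserved; adjusted values are clipped to <= 1.
    """
    if method not in _ADJUST:
        raise ValidationError(f"unknown correction {method!r}; choose from {CORRECTIONS}")
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if (arr <= 0).any() or (arr > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return _ADJUST[method](arr)


@dataclass(frozen=True)
class EnrichmentQuery:
    """A query gene list with its background and testing configuration."""

    genes: tuple[str, ...]
    collection: GeneSetCollection
    background: int | None = None  # None => size of the annotated universe
    test: str = "hypergeometric"
    correction: str = "BH"
    include_empty: bool = False

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValidationError(f"unknown test {self.test!r}; choose from {TESTS}")
        if self.correction not in CORRECTIONS:
            raise ValidationError(
                f"unknown correction {self.correction!r}; choose from {CORRECTIONS}"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in query")


def _p_raw(test: str, N: int, K: int, n: int, k: int) -> float:
    if test == "hypergeometric" or test == "fisher":
        # one-sided Fisher on the induced 2x2 table is the same tail
        return hypergeom_tail(N, K, n, k)
    table = [[k, n - k], [K - k, N - n - K + k]]
    try:
        _, p = chisq_2x2(table)
    except ValidationError:
        # degenerate margins: fall back to the exact tail
        p = hypergeom_tail(N, K, n, k)
    return p


def gsea(
    query: Iterable[str] | EnrichmentQuery,
    collection: GeneSetCollection | None = None,
    background: int | None = None,
    test: str = "hypergeometric",
    correction: str = "BH",
    include_empty: bool = False,
) -> pd.DataFrame:
    """Over-representation analysis of a query gene list.

    Each annotated set with overlap k >= 1 (or every set when
    ``include_empty``) is tested; p-values are corrected across the tested
    sets.  Query genes outside the annotated universe are dropped with a
    warning.  Results are sorted by raw p ascending, ties by set id.

    Returns a DataFrame with columns set_id, description, N, K, n, k,
    p_raw, p_adjusted, overlap_genes.
    """
    if isinstance(query, EnrichmentQuery):
        q = query
    else:
        if collection is None:
            raise ValidationError("a GeneSetCollection is required")
        q = EnrichmentQuery(
            tuple(dict.fromkeys(query)), collection, background, test, correction, include_empty
        )
    universe = q.collection.universe()
    N = q.background if q.background is not None else len(universe)
    in_universe = [g for g in q.genes if g in universe]
    dropped = set(q.genes) - set(in_universe)
    if dropped:
        if not in_universe:
            raise ValidationError("no query gene is in the annotated universe")
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the annotated universe were dropped",
            stacklevel=2,
        )
    n = len(in_universe)
    if N < n:
        raise ValidationError(f"background N={N} smaller than query size n={n}")
    qset = set(in_universe)
    rows = []
    for gs in q.collection:
        members = set(gs.members)
        K = len(members)
        overlap = sorted(qset & members)
        k = len(overlap)
        if k == 0 and not q.include_empty:
            continue
        rows.append(
            {
                "set_id": gs.set_id,
                "description": gs.description,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_raw": _p_raw(q.test, N, K, n, k),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "description", "N", "K", "n", "k", "p_raw", "p_adjusted", "overlap_genes"]
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = adjust_pvalues(df["p_raw"].clip(lower=np.nextafter(0, 1)), q.correction)
    df = df.sort_values(["p_raw", "set_id"], kind="mergesort").reset_index(drop=True)
    return df[
        ["set_id", "description", "N", "K", "n", "k", "p_raw", "p_adjusted", "overlap_genes"]
    ]
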