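"""Network queries and ortholog-based (interolog) PPI projection.

Covers the lookup operations a co-expression platform serves: ranked
co-expression neighborhoods, module membership, counting orthologous pairs
between two species' neighbor lists, and projecting a source-species
protein-protein interaction network onto a target species through a
bootstrap-filtered ortholog map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import CoexpressionNetwork
from .errors import FormatError, ValidationError
from .modules import ModulePartition

__all__ = [
    "OrthologMap",
    "PPINetwork",
    "read_ortholog_tsv",
    "read_ppi_tsv",
    "neighbors",
    "neighborhood_overlap",
    "project_ppi",
    "module_of",
]


@dataclass(frozen=True)
class OrthologMap:
    """Source -> target ortholog pairs with InParanoid-style bootstrap
    percentages (0-100)."""

    pairs: pd.DataFrame  # columns source_gene, target_gene, bootstrap

    def __post_init__(self) -> None:
        need = {"source_gene", "target_gene", "bootstrap"}
        if not need <= set(self.pairs.columns):
            raise ValidationError(f"ortholog table missing {sorted(need - set(self.pairs.columns))}")
        b = self.pairs["bootstrap"]
        if ((b < 0) | (b > 100)).any():
            raise ValidationError("bootstrap values must lie in [0, 100]")
        if self.pairs.duplicated(["source_gene", "target_gene"]).any():
            raise ValidationError("duplicate ortholog pair")

    def filtered(self, bootstrap_min: float = 60.0) -> "OrthologMap":
        """Pairs with bootstrap strictly greater than the cutoff."""
        return OrthologMap(
            self.pairs[self.pairs["bootstrap"] > bootstrap_min].reset_index(drop=True)
        )

    def targets_of(self, source_gene: str) -> list[str]:
        sel = self.pairs["source_gene"] == source_gene
        return list(self.pairs.loc[sel, "target_gene"])

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PPINetwork:
    """Undirected protein-protein interaction edges with a provenance tag."""

    edges: pd.DataFrame  # columns gene_a, gene_b [, provenance]
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        e = self.edges
        if not {"gene_a", "gene_b"} <= set(e.columns):
            raise ValidationError("PPI edges need gene_a and gene_b columns")
        if (e["gene_a"] == e["gene_b"]).any():
            raise ValidationError("self-loop in PPI network")
        swapped = e["gene_a"] > e["gene_b"]
        if swapped.any():
            raise ValidationError("PPI edges must be canonically ordered (gene_a < gene_b)")
        if e.duplicated(["gene_a", "gene_b"]).any():
            raise ValidationError("duplicate PPI edge")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_ids(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


def _canonicalize_ppi(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    swap = df["gene_a"] > df["gene_b"]
    df.loc[swap, ["gene_a", "gene_b"]] = df.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    df = df[df["gene_a"] != df["gene_b"]]
    df = df.drop_duplicates(["gene_a", "gene_b"])
    return df.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)


def read_ortholog_tsv(path: str | Path) -> OrthologMap:
    """Read a TSV with columns source_gene, target_gene, bootstrap."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"source_gene": str, "target_gene": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    try:
        return OrthologMap(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def read_ppi_tsv(path: str | Path, provenance: str = "unknown") -> PPINetwork:
    """Read a TSV with columns gene_a, gene_b (extra columns ignored)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise FormatError(f"{path}: need gene_a and gene_b columns")
    return PPINetwork(_canonicalize_ppi(df[["gene_a", "gene_b"]]), provenance)


def neighbors(
    net: CoexpressionNetwork, gene: str, top_k: int | None = None
) -> pd.DataFrame:
    """Co-expression neighbors of a gene, ranked by |PCC| descending (ties
    by neighbor id), optionally truncated to the strongest ``top_k``.

    A gene present in the correlated set but isolated at the network's
    cutoff returns an empty list; a gene unknown to the network is an
    error.
    """
    e = net.edges
    known = set(net.genes) | net.node_ids
    if gene not in known:
        raise ValidationError(f"gene {gene!r} is not a node of this network")
    hit_a = e[e["gene_a"] == gene][["gene_b", "pcc"]].rename(columns={"gene_b": "neighbor"})
    hit_b = e[e["gene_b"] == gene][["gene_a", "pcc"]].rename(columns={"gene_a": "neighbor"})
    out = pd.concat([hit_a, hit_b], ignore_index=True)
    out["abs_pcc"] = out["pcc"].abs()
    out = out.sort_values(["abs_pcc", "neighbor"], ascending=[False, True], kind="mergesort")
    out = out.drop(columns="abs_pcc").reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out


def neighborhood_overlap(
    list_a: list[str], list_b: list[str], orthologs: OrthologMap
) -> int:
    """Number of orthologous (a, b) pairs with a in ``list_a`` (source
    species), b in ``list_b`` (target species) and a -> b in the map."""
    if not list_a or not list_b:
        raise ValidationError("gene lists must be non-empty")
    sa, sb = set(list_a), set(list_b)
    p = orthologs.pairs
    hit = p["source_gene"].isin(sa) & p["target_gene"].isin(sb)
    return int(hit.sum())


def project_ppi(
    source: PPINetwork | list[PPINetwork],
    orthologs: OrthologMap,
    bootstrap_min: float = 60.0,
) -> PPINetwork:
    """Interolog projection of source-species PPI edges onto the target
    species.

    Ortholog pairs with bootstrap > ``bootstrap_min`` are kept; every
    source edge (s1, s2) yields each (t1, t2) with s1 -> t1 and s2 -> t2.
    Self-loops are dropped and edges deduplicated; a list of source
    networks is projected and unioned, recording each edge's provenance.
    """
    nets = source if isinstance(source, list) else [source]
    kept = orthologs.filtered(bootstrap_min)
    targets: dict[str, list[str]] = {}
    for s, t in zip(kept.pairs["source_gene"], kept.pairs["target_gene"]):
        targets.setdefault(s, []).append(t)
    rows = []
    for net in nets:
        for s1, s2 in zip(net.edges["gene_a"], net.edges["gene_b"]):
            for t1 in targets.get(s1, ()):
                for t2 in targets.get(s2, ()):
                    if t1 != t2:
                        a, b = (t1, t2) if t1 < t2 else (t2, t1)
                        rows.append((a, b, net.provenance))
    if not rows:
        return PPINetwork(pd.DataFrame(columns=["gene_a", "gene_b", "provenance"]), "projected")
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "provenance"])
    df = (
        df.groupby(["gene_a", "gene_b"], sort=True)["provenance"]
        .apply(lambda s: ",".join(sorted(set(s))))
        .reset_index()
    )
    return PPINetwork(df, "projected")


def module_of(partition: ModulePartition, gene: str) -> tuple[str, list[str]]:
    """Module label of a gene plus the full member list of that module
    (grey genes return the grey set)."""
    if gene not in partition.labels.index:
        raise ValidationError(f"gene {gene!r} is not in the partition")
    label = partition.labels[gene]
    return label, partition.members(label)
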