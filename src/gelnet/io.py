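"""Readers, writers and domain containers for every file format the toolkit touches.

Formats handled here: expression TSV (genes x samples, FPKM), GFF3 gene
models, genome FASTA, GMT gene-set collections, IUPAC motif TSVs and
co-expression edge-list TSVs.  Every reader validates its invariants and
raises :class:`~gelnet.errors.FormatError` with enough context (gene id,
row/column) to locate the offending record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneCoordinate",
    "PromoterSet",
    "GeneSet",
    "GeneSetCollection",
    "MotifLibrary",
    "IUPAC_LETTERS",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gff_genes",
    "read_fasta",
    "extract_promoters",
    "read_gmt",
    "write_gmt",
    "read_motif_tsv",
    "write_motif_tsv",
    "read_edge_list",
    "write_edge_list",
]

#: Valid IUPAC nucleotide codes for motif consensus strings.
IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")

PROMOTER_LENGTHS = (1000, 2000, 3000)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated genes x samples FPKM matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, finite values >= 0.

    Attributes
    ----------
    zero_variance_genes : tuple of str
        Genes whose expression is constant across samples.  They are
        retained in the matrix but flagged, because Pearson correlation is
        undefined for them.
    """

    data: pd.DataFrame
    zero_variance_genes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("expression matrix must have >= 1 gene and >= 1 sample")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value for gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative FPKM for gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        flat = tuple(df.index[values.std(axis=1) == 0.0])
        object.__setattr__(self, "zero_variance_genes", flat)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values_for(self, gene_id: str) -> np.ndarray:
        try:
            return self.data.loc[gene_id].to_numpy(dtype=float)
        except KeyError:
            raise ValidationError(f"gene {gene_id!r} not in expression matrix") from None


class GeneCoordinate(NamedTuple):
    """1-based inclusive genomic span of a gene model."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def validate(self) -> "GeneCoordinate":
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: need 1 <= start <= end, got [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        return self


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    sequence: str
    requested_length: int

    @property
    def actual_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PromoterSet:
    """Upstream promoter sequences for a set of genes, all extracted with the
    same requested length (1, 2 or 3 kb).  Sequences at contig edges may be
    shorter than requested (``actual_length <= requested_length``)."""

    requested_length: int
    records: dict[str, PromoterRecord]

    def __post_init__(self) -> None:
        if self.requested_length not in PROMOTER_LENGTHS:
            raise ValidationError(
                f"promoter length must be one of {PROMOTER_LENGTHS}, got {self.requested_length}"
            )
        for rec in self.records.values():
            if rec.actual_length > self.requested_length:
                raise ValidationError(
                    f"promoter for {rec.gene_id!r} longer than requested "
                    f"({rec.actual_length} > {self.requested_length})"
                )
            bad = set(rec.sequence) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"promoter for {rec.gene_id!r} has invalid base(s) {sorted(bad)}"
                )

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, gene_id: str) -> str:
        return self.records[gene_id].sequence

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValidationError(f"gene set {self.set_id!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.set_id!r} has duplicate members")


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of named gene sets (GO/KEGG/Pfam-style)."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for set_id, gs in self.sets.items():
            if set_id != gs.set_id:
                raise ValidationError(f"key {set_id!r} does not match set id {gs.set_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def universe(self) -> set[str]:
        """Union of all member genes across sets (the annotated universe)."""
        out: set[str] = set()
        for gs in self.sets.values():
            out.update(gs.members)
        return out


@dataclass(frozen=True)
class MotifLibrary:
    """Named IUPAC consensus motifs."""

    motifs: dict[str, str]

    def __post_init__(self) -> None:
        for motif_id, consensus in self.motifs.items():
            if not consensus:
                raise ValidationError(f"motif {motif_id!r} has empty consensus")
            bad = set(consensus.upper()) - IUPAC_LETTERS
            if bad:
                raise ValidationError(
                    f"motif {motif_id!r}: invalid IUPAC letter(s) {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs.items())

    def __getitem__(self, motif_id: str) -> str:
        return self.motifs[motif_id]


# ---------------------------------------------------------------------------
# expression TSV

def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples FPKM table.

    The file must be tab-separated with a header row of sample ids and gene
    ids in the first column.  Duplicate ids, non-numeric cells and empty
    files raise :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: no genes or no samples")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = "gene_id"
    try:
        return ExpressionMatrix(numeric.astype(float))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    df = em.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# GFF3 / FASTA / promoters

def read_gff_genes(path: str | Path, feature_type: str = "gene") -> list[GeneCoordinate]:
    """Parse gene coordinates from a GFF3 file.

    One :class:`GeneCoordinate` is returned per record of ``feature_type``;
    the gene id is taken from the ``ID`` attribute.  Strand is required
    because promoter extraction is strand-aware.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several concrete types
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from None
    coords: list[GeneCoordinate] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        ids = feat.attributes.get("ID")
        if not ids:
            raise FormatError(
                f"{path}: {feature_type} record at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks an ID attribute"
            )
        gene_id = ids[0]
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {gene_id!r} has strand {feat.strand!r}; '+' or '-' required "
                "for promoter extraction"
            )
        if feat.start > feat.end:
            raise FormatError(f"{path}: gene {gene_id!r} has start > end")
        coords.append(
            GeneCoordinate(gene_id, feat.seqid, int(feat.start), int(feat.end), feat.strand).validate()
        )
    seen: set[str] = set()
    for c in coords:
        if c.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene id {c.gene_id!r}")
        seen.add(c.gene_id)
    return coords


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a contig id -> upper-case sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def extract_promoters(
    genome: Mapping[str, str],
    coords: Iterable[GeneCoordinate],
    length: int,
) -> PromoterSet:
    """Extract fixed-length upstream promoter sequences.

    The promoter abuts the annotated gene start and excludes the gene body:
    for a ``+`` strand gene it is the genomic window ``[start-length,
    start-1]`` (1-based inclusive) truncated at position 1; for a ``-``
    strand gene, the reverse complement of ``[end+1, end+length]`` truncated
    at the contig end.  Genes with zero available upstream bases are kept
    with an empty sequence and a warning so that query and null gene
    universes stay aligned.
    """
    if length not in PROMOTER_LENGTHS:
        raise ValidationError(f"promoter length must be one of {PROMOTER_LENGTHS}, got {length}")
    records: dict[str, PromoterRecord] = {}
    for coord in coords:
        coord.validate()
        if coord.gene_id in records:
            raise ValidationError(f"duplicate gene id {coord.gene_id!r}")
        if coord.contig_id not in genome:
            raise ValidationError(
                f"gene {coord.gene_id!r}: contig {coord.contig_id!r} not in genome FASTA"
            )
        contig = genome[coord.contig_id]
        if coord.end > len(contig):
            raise ValidationError(
                f"gene {coord.gene_id!r} extends past contig {coord.contig_id!r} "
                f"({coord.end} > {len(contig)})"
            )
        if coord.strand == "+":
            lo = max(1, coord.start - length)  # 1-based
            seq = contig[lo - 1 : coord.start - 1]
        else:
            hi = min(len(contig), coord.end + length)
            seq = str(Seq(contig[coord.end : hi]).reverse_complement())
        seq = seq.upper()
        if not seq:
            warnings.warn(
                f"gene {coord.gene_id!r} has zero upstream bases on {coord.contig_id!r}; "
                "promoter recorded with length 0",
                stacklevel=2,
            )
        records[coord.gene_id] = PromoterRecord(coord.gene_id, seq, length)
    return PromoterSet(requested_length=length, records=records)


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff_genes(coords: Iterable[GeneCoordinate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in coords:
            fh.write(
                f"{c.contig_id}\tgelnet\tgene\t{c.start}\t{c.end}\t.\t{c.strand}\t.\t"
                f"ID={c.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# GMT / motif TSV / edge lists

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``set_id <tab> description <tab>
    member1 <tab> member2 ...``."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs set id, description and >= 1 member"
                )
            set_id, description, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} is empty")
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            if len(set(members)) != len(members):
                raise FormatError(f"{path}:{lineno}: duplicate member in set {set_id!r}")
            sets[set_id] = GeneSet(set_id, description, tuple(members))
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


def read_motif_tsv(path: str | Path) -> MotifLibrary:
    """Read a two-column TSV of ``motif_id <tab> IUPAC consensus``."""
    motifs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            motif_id, consensus = parts
            if motif_id in motifs:
                raise FormatError(f"{path}:{lineno}: duplicate motif id {motif_id!r}")
            consensus = consensus.upper()
            bad = set(consensus) - IUPAC_LETTERS
            if bad:
                raise FormatError(
                    f"{path}:{lineno}: motif {motif_id!r} has invalid IUPAC letter(s) "
                    f"{sorted(bad)}"
                )
            if not consensus:
                raise FormatError(f"{path}:{lineno}: motif {motif_id!r} has empty consensus")
            motifs[motif_id] = consensus
    if not motifs:
        raise FormatError(f"{path}: no motifs")
    return MotifLibrary(motifs)


def write_motif_tsv(library: MotifLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for motif_id, consensus in library:
            fh.write(f"{motif_id}\t{consensus}\n")


EDGE_COLUMNS = ["gene_a", "gene_b", "pcc", "sign"]


def canonical_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Order each pair so gene_a < gene_b lexicographically, then sort rows."""
    edges = edges.copy()
    swap = edges["gene_a"] > edges["gene_b"]
    edges.loc[swap, ["gene_a", "gene_b"]] = edges.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    if (edges["gene_a"] == edges["gene_b"]).any():
        g = edges.loc[edges["gene_a"] == edges["gene_b"], "gene_a"].iloc[0]
        raise ValidationError(f"self-loop on gene {g!r}")
    return edges.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an edge-list TSV with columns gene_a, gene_b, pcc[, sign]."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = {"gene_a", "gene_b", "pcc"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if "sign" not in df.columns:
        df["sign"] = np.where(df["pcc"] >= 0, "positive", "negative")
    bad_sign = ~df["sign"].isin(["positive", "negative"])
    if bad_sign.any():
        raise FormatError(f"{path}: invalid sign value {df.loc[bad_sign, 'sign'].iloc[0]!r}")
    if not np.issubdtype(df["pcc"].dtype, np.number):
        raise FormatError(f"{path}: non-numeric pcc column")
    return canonical_edges(df[EDGE_COLUMNS])


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    df = edges.copy()
    if "sign" not in df.columns:
        df["sign"] = np.where(df["pcc"] >= 0, "positive", "negative")
    canonical_edges(df[EDGE_COLUMNS]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
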