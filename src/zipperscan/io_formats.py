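"""Readers and writers for the external formats the pipeline touches.

FASTA parsing is delegated to :mod:`Bio.SeqIO` and GFF3 parsing to
:mod:`gffutils`; this module adds alphabet validation, representative-model
selection, and the bundled family-catalog / paralog-pair fixture tables.

Coordinates follow the GFF3 convention (1-based, inclusive) at every public
boundary; internal arithmetic converts to 0-based half-open and back.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "NucleotideRecord",
    "GeneModel",
    "FamilyCatalogEntry",
    "ParalogPairRecord",
    "ZipperscanError",
    "FastaFormatError",
    "SequenceValidationError",
    "Gff3StructureError",
    "CoordinateRangeError",
    "FixtureIntegrityError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "load_table1_fixture",
    "load_table2_fixture",
    "read_catalog",
    "read_expression_matrix",
    "read_de_table",
    "VALID_GROUPS",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

#: Functional groups of the plant bZIP classification (A-N plus S).
VALID_GROUPS = frozenset("ABCDEFGHIJKMNS")

_FIXTURE_SHA256 = {
    "table1_stbzip.tsv": "0c09ebc85a63ce97305acfa978770215b7179598d3e7b67cf5ec9ff6bfe90e45",
    "table2_kaks.tsv": "24f86e6df57eaf3256bac587c94404ed0088b76b9291b8d71b580f153aa7bf9c",
}


class ZipperscanError(Exception):
    """Base class for every error raised by this package."""


class FastaFormatError(ZipperscanError):
    pass


class SequenceValidationError(ZipperscanError):
    pass


class Gff3StructureError(ZipperscanError):
    pass


class CoordinateRangeError(ZipperscanError):
    pass


class FixtureIntegrityError(ZipperscanError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (20 canonical letters plus X)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in PROTEIN_ALPHABET:
                raise SequenceValidationError(
                    f"record {self.id!r}: illegal protein residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NucleotideRecord:
    """An identified nucleotide sequence over A, C, G, T, N."""

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.bases, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise SequenceValidationError(
                    f"record {self.id!r}: illegal nucleotide {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class GeneModel:
    """One representative transcript model of a gene.

    ``exons`` and ``cds_spans`` are 1-based inclusive genomic intervals,
    sorted in genomic order regardless of strand. ``tss`` is the 5'-most
    transcribed genomic coordinate respecting strand. ``partial`` marks
    models whose total CDS length is not divisible by three.
    """

    gene_id: str
    chrom: str
    strand: int  # +1 or -1
    exons: tuple[tuple[int, int], ...]
    cds_spans: tuple[tuple[int, int], ...]
    tss: int
    partial: bool = False
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"{self.gene_id}: strand must be +1 or -1")
        for name, spans in (("exons", self.exons), ("cds_spans", self.cds_spans)):
            prev_end = 0
            for start, end in spans:
                if start < 1 or end < start:
                    raise Gff3StructureError(
                        f"{self.gene_id}: malformed {name} interval ({start},{end})"
                    )
                if start <= prev_end:
                    raise Gff3StructureError(
                        f"{self.gene_id}: {name} intervals overlap or are unsorted"
                    )
                prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_spans)


@dataclass(frozen=True)
class FamilyCatalogEntry:
    gene_name: str
    locus_id: str
    group: str
    synonym: str = ""

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"{self.gene_name}: unknown functional group {self.group!r}")


@dataclass(frozen=True)
class ParalogPairRecord:
    gene_a: str
    gene_b: str
    ka: float
    ks: float
    ratio: float

    def __post_init__(self) -> None:
        if self.ka < 0 or self.ks < 0 or self.ratio < 0:
            raise ValueError(f"{self.gene_a}/{self.gene_b}: negative Ka/Ks quantities")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path, mode: Literal["protein", "nucleotide"] = "protein"
) -> list[ProteinRecord] | list[NucleotideRecord]:
    """Read a multi-record FASTA file, uppercasing and validating sequences.

    Parameters
    ----------
    path
        FASTA file to read.
    mode
        ``"protein"`` validates against the 20 canonical residues plus X;
        ``"nucleotide"`` against A, C, G, T, N.

    Raises
    ------
    FastaFormatError
        If the file is empty or contains no records.
    SequenceValidationError
        On an illegal character, naming the record and 1-based position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list = []
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if mode == "protein":
            out.append(ProteinRecord(id=rec.id, residues=seq, description=rec.description))
        elif mode == "nucleotide":
            out.append(NucleotideRecord(id=rec.id, bases=seq, description=rec.description))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def write_fasta(
    records: Iterable[ProteinRecord | NucleotideRecord], path: str | Path, width: int = 60
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            seq = rec.residues if isinstance(rec, ProteinRecord) else rec.bases
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _tss(strand: int, exons: Sequence[tuple[int, int]]) -> int:
    return min(s for s, _ in exons) if strand == 1 else max(e for _, e in exons)


def read_gff3(path: str | Path, fasta_path: str | Path | None = None) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    When a gene carries several mRNAs, the representative model is the one
    with the longest total CDS, ties broken lexicographically by transcript
    id. Minus-strand models keep genomic coordinates but mark ``strand=-1``.

    Raises
    ------
    Gff3StructureError
        On a missing version pragma, a CDS without an mRNA parent, or a
        gene without transcripts.
    CoordinateRangeError
        When ``fasta_path`` is given and a feature exceeds sequence bounds.
    """
    import gffutils

    path = Path(path)
    text = path.read_text()
    if not text.startswith("##gff-version"):
        raise Gff3StructureError(f"{path}: missing ##gff-version pragma")

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    seq_lengths: dict[str, int] = {}
    if fasta_path is not None:
        for rec in read_fasta(fasta_path, mode="nucleotide"):
            seq_lengths[rec.id] = len(rec.bases)

    for cds in db.features_of_type("CDS"):
        if not cds.attributes.get("Parent"):
            raise Gff3StructureError(f"{path}: CDS at {cds.seqid}:{cds.start} has no parent")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise Gff3StructureError(f"{path}: gene {gene.id} has no mRNA children")

        def cds_len(m) -> int:
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

        rep = sorted(mrnas, key=lambda m: (-cds_len(m), m.id))[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(rep, featuretype="exon")
        )
        cds_spans = sorted(
            (f.start, f.end) for f in db.children(rep, featuretype="CDS")
        )
        if not exons:
            exons = cds_spans
        if not cds_spans:
            raise Gff3StructureError(f"{path}: mRNA {rep.id} has no CDS features")
        strand = 1 if gene.strand != "-" else -1

        if seq_lengths:
            limit = seq_lengths.get(gene.seqid)
            if limit is None:
                raise CoordinateRangeError(f"{path}: unknown sequence {gene.seqid!r}")
            for s, e in list(exons) + list(cds_spans):
                if e > limit or s < 1:
                    raise CoordinateRangeError(
                        f"{path}: feature ({s},{e}) outside {gene.seqid} bounds 1..{limit}"
                    )

        total = sum(e - s + 1 for s, e in cds_spans)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=strand,
                exons=tuple(exons),
                cds_spans=tuple(cds_spans),
                tss=_tss(strand, exons),
                partial=total % 3 != 0,
                transcript_id=rep.id,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path | None = None) -> str:
    """Serialize gene models back to GFF3 text (and optionally a file)."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for m in models:
        strand = "+" if m.strand == 1 else "-"
        gstart = min(s for s, _ in m.exons)
        gend = max(e for _, e in m.exons)
        tid = m.transcript_id or f"{m.gene_id}.1"
        buf.write(
            f"{m.chrom}\tzipperscan\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={m.gene_id}\n"
        )
        buf.write(
            f"{m.chrom}\tzipperscan\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={m.gene_id}\n"
        )
        for i, (s, e) in enumerate(m.exons, 1):
            buf.write(
                f"{m.chrom}\tzipperscan\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={tid}.exon{i};Parent={tid}\n"
            )
        # CDS phase column: fraction of a codon left over upstream of each span,
        # accumulated in transcript orientation.
        spans = list(m.cds_spans) if m.strand == 1 else list(m.cds_spans)[::-1]
        phases = []
        cum = 0
        for s, e in spans:
            phases.append((3 - cum % 3) % 3)
            cum += e - s + 1
        ordered = list(zip(spans, phases))
        if m.strand == -1:
            ordered = ordered[::-1]
        for i, ((s, e), ph) in enumerate(ordered, 1):
            buf.write(
                f"{m.chrom}\tzipperscan\tCDS\t{s}\t{e}\t.\t{strand}\t{ph}\t"
                f"ID={tid}.cds{i};Parent={tid}\n"
            )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Bundled fixtures and tabular inputs


def _fixture_text(name: str) -> str:
    data = resources.files("zipperscan.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureIntegrityError(
            f"bundled fixture {name} is corrupted (sha256 {digest})"
        )
    return data.decode()


def load_table1_fixture() -> list[FamilyCatalogEntry]:
    """The bundled family catalog: the 80 potato bZIP genes with their
    locus ids, functional groups, and synonyms."""
    rows = csv.DictReader(io.StringIO(_fixture_text("table1_stbzip.tsv")), delimiter="\t")
    entries = [
        FamilyCatalogEntry(
            gene_name=r["gene_name"],
            locus_id=r["locus_id"],
            group=r["group"],
            synonym=r.get("synonym") or "",
        )
        for r in rows
    ]
    names = [e.gene_name for e in entries]
    if len(names) != len(set(names)):
        raise FixtureIntegrityError("family catalog contains duplicate gene names")
    return entries


def load_table2_fixture() -> list[ParalogPairRecord]:
    """The bundled duplicated-gene-pair table: 22 rows of Ka, Ks and their
    ratio as printed for the paralog pairs."""
    rows = csv.DictReader(io.StringIO(_fixture_text("table2_kaks.tsv")), delimiter="\t")
    return [
        ParalogPairRecord(
            gene_a=r["gene_a"],
            gene_b=r["gene_b"],
            ka=float(r["ka"]),
            ks=float(r["ks"]),
            ratio=float(r["ratio"]),
        )
        for r in rows
    ]


def read_catalog(path: str | Path) -> list[FamilyCatalogEntry]:
    """Read a family catalog TSV (gene_name, locus_id, group[, synonym])."""
    with Path(path).open() as fh:
        rows = csv.DictReader(fh, delimiter="\t")
        return [
            FamilyCatalogEntry(
                gene_name=r["gene_name"],
                locus_id=r.get("locus_id", ""),
                group=r["group"],
                synonym=r.get("synonym") or "",
            )
            for r in rows
        ]


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a log2 gene-by-sample expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ZipperscanError(f"{path}: expression matrix contains missing values")
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV with gene_id, log2fc, padj columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ZipperscanError(f"{path}: DE table must have columns {sorted(required)}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ZipperscanError(f"{path}: padj outside [0, 1]")
    return df
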