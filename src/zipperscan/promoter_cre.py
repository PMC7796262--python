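"""Promoter extraction and cis-regulatory element (CRE) counting.

Promoters are the 2000 bases immediately 5' of the transcription start
site in transcript orientation. Motifs are IUPAC nucleotide patterns
counted with a sliding window (overlapping matches count) on both strands;
patterns equal to their own reverse complement (e.g. the G-box CACGTG) are
counted on one strand only so palindromes are not double counted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .io_formats import GeneModel, NucleotideRecord, SequenceValidationError, ZipperscanError

__all__ = [
    "CREMotif",
    "CREProfile",
    "IUPAC",
    "load_motifs",
    "reverse_complement",
    "is_palindromic",
    "extract_promoter",
    "scan_motifs",
    "family_cre_matrix",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = ("development", "hormone", "stress", "core")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindromic(pattern: str) -> bool:
    """True when an IUPAC pattern equals its own reverse complement."""
    return pattern == reverse_complement(pattern)


@dataclass(frozen=True)
class CREMotif:
    name: str
    pattern: str
    category: str

    def __post_init__(self) -> None:
        for ch in self.pattern:
            if ch not in IUPAC:
                raise SequenceValidationError(
                    f"motif {self.name!r}: invalid IUPAC letter {ch!r}"
                )
        if self.category not in CATEGORIES:
            raise ValueError(f"motif {self.name!r}: unknown category {self.category!r}")

    @property
    def regex(self) -> re.Pattern:
        body = "".join(f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch] for ch in self.pattern)
        return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


@dataclass(frozen=True)
class CREProfile:
    gene_id: str
    counts: dict[str, int]
    category_totals: dict[str, int]


def load_motifs(path: str | Path | None = None) -> list[CREMotif]:
    """Load a motif table from YAML; without a path, the bundled default."""
    if path is None:
        text = resources.files("zipperscan.data").joinpath("cre_motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    spec = yaml.safe_load(text)
    motifs = [CREMotif(**entry) for entry in spec["motifs"]]
    names = [m.name for m in motifs]
    if len(names) != len(set(names)):
        raise ZipperscanError("motif table contains duplicate names")
    return motifs


def extract_promoter(
    model: GeneModel,
    genome: Mapping[str, NucleotideRecord],
    length: int = 2000,
) -> NucleotideRecord:
    """The ``length`` bases immediately 5' of the TSS in transcript
    orientation (reverse-complemented for minus-strand genes), clipped at
    the chromosome edge with a warning."""
    if model.chrom not in genome:
        raise ZipperscanError(f"{model.gene_id}: chromosome {model.chrom!r} not in genome")
    chrom_seq = genome[model.chrom].bases
    if model.strand == 1:
        start0 = max(0, model.tss - 1 - length)
        end0 = model.tss - 1
        seq = chrom_seq[start0:end0]
    else:
        start0 = model.tss
        end0 = min(len(chrom_seq), model.tss + length)
        seq = reverse_complement(chrom_seq[start0:end0])
    if not seq:
        raise ZipperscanError(f"{model.gene_id}: TSS at chromosome edge, zero-length promoter")
    if len(seq) < length:
        warnings.warn(
            f"{model.gene_id}: promoter clipped to {len(seq)} bp at chromosome edge",
            stacklevel=2,
        )
    return NucleotideRecord(id=f"{model.gene_id}_promoter", bases=seq)


def scan_motifs(
    promoter: NucleotideRecord,
    motifs: Sequence[CREMotif],
    both_strands: bool = True,
) -> CREProfile:
    """Count all (overlapping) matches of each motif in a promoter.

    With ``both_strands`` the reverse complement of the promoter is scanned
    too, except for reverse-complement-palindromic patterns, which match
    identically on either strand and are counted once.
    """
    gene_id = promoter.id.removesuffix("_promoter")
    seq = promoter.bases
    rc = reverse_complement(seq)
    counts: dict[str, int] = {}
    for motif in motifs:
        n = len(motif.regex.findall(seq))
        if both_strands and not is_palindromic(motif.pattern):
            n += len(motif.regex.findall(rc))
        counts[motif.name] = n
    totals = {cat: 0 for cat in CATEGORIES}
    for motif in motifs:
        totals[motif.category] += counts[motif.name]
    return CREProfile(gene_id=gene_id, counts=counts, category_totals=totals)


def family_cre_matrix(
    profiles: Sequence[CREProfile], motifs: Sequence[CREMotif]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-by-motif count matrix with columns banded by category, plus the
    per-motif min/max across genes (the color-banding statistic)."""
    order = sorted(motifs, key=lambda m: (CATEGORIES.index(m.category), m.name))
    columns = [m.name for m in order]
    matrix = pd.DataFrame(
        [[p.counts.get(name, 0) for name in columns] for p in profiles],
        index=[p.gene_id for p in profiles],
        columns=columns,
    )
    summary = pd.DataFrame(
        {
            "category": [m.category for m in order],
            "min": matrix.min(axis=0).values,
            "max": matrix.max(axis=0).values,
        },
        index=columns,
    )
    return matrix, summary
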