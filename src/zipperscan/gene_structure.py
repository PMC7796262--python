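"""Intron phase and exon symmetry classification from gene models.

The phase of an intron is the position at which it interrupts the reading
frame: phase 0 falls between codons, phase 1 after the first base of a
codon, phase 2 after the second. Phases are computed on CDS only (UTR
exons and UTR-only introns are ignored), and each coding exon is labeled
with its flanking phase pair using a virtual phase 0 at the CDS start and
end, so terminal exons are classed like internal ones: a (0,0) exon is
symmetric, a (1,2) exon asymmetric. Conserved phase patterns within a gene
family are evidence of a common progenitor; random phases suggest exon
shuffling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import FamilyCatalogEntry, GeneModel, Gff3StructureError

__all__ = ["GeneStructureProfile", "intron_phases", "family_structure_table"]


@dataclass(frozen=True)
class GeneStructureProfile:
    """Per-gene intron phases (5'->3' in transcript orientation) and the
    flanking-phase class of each coding exon."""

    gene_id: str
    intron_phases: tuple[int, ...]
    exon_classes: tuple[tuple[int, int], ...]
    partial: bool = False

    @property
    def symmetric(self) -> tuple[bool, ...]:
        return tuple(left == right for left, right in self.exon_classes)

    @property
    def intronless(self) -> bool:
        return len(self.exon_classes) == 1

    @property
    def pattern(self) -> str:
        """Compact exon-class string, e.g. ``"(0,1)(1,2)(2,0)(0,0)"``."""
        return "".join(f"({l},{r})" for l, r in self.exon_classes)


def intron_phases(model: GeneModel) -> GeneStructureProfile:
    """Compute intron phases and exon classes for one gene model.

    CDS spans are ordered 5'->3' in transcript orientation (reversed for
    minus-strand genes); the phase of intron i is the cumulative coding
    length upstream of it modulo 3. Models whose total CDS length is not
    divisible by three are processed anyway and flagged ``partial``.
    """
    if not model.cds_spans:
        raise Gff3StructureError(f"{model.gene_id}: gene model has no CDS spans")
    spans = list(model.cds_spans)
    if model.strand == -1:
        spans = spans[::-1]
    lengths = [end - start + 1 for start, end in spans]

    phases: list[int] = []
    cumulative = 0
    for length in lengths[:-1]:
        cumulative += length
        phases.append(cumulative % 3)

    boundary = [0] + phases + [0]  # virtual phase 0 at CDS start and end
    classes = tuple((boundary[i], boundary[i + 1]) for i in range(len(lengths)))
    return GeneStructureProfile(
        gene_id=model.gene_id,
        intron_phases=tuple(phases),
        exon_classes=classes,
        partial=sum(lengths) % 3 != 0,
    )


def family_structure_table(
    models: Sequence[GeneModel], catalog: Sequence[FamilyCatalogEntry]
) -> pd.DataFrame:
    """Per functional group, the multiset of exon-class patterns and the
    number of intronless genes.

    Returns a DataFrame with one row per (group, pattern) holding the count
    of genes showing that pattern, plus per-group intronless totals.
    """
    group_of = {c.gene_name: c.group for c in catalog}
    per_group_patterns: dict[str, Counter] = {}
    per_group_intronless: Counter = Counter()
    for model in models:
        if model.gene_id not in group_of:
            raise ValueError(f"{model.gene_id}: not present in family catalog")
        group = group_of[model.gene_id]
        profile = intron_phases(model)
        per_group_patterns.setdefault(group, Counter())[profile.pattern] += 1
        if profile.intronless:
            per_group_intronless[group] += 1
    rows = []
    for group in sorted(per_group_patterns):
        for pattern, count in sorted(per_group_patterns[group].items()):
            rows.append(
                {
                    "group": group,
                    "pattern": pattern,
                    "n_genes": count,
                    "group_intronless": per_group_intronless[group],
                }
            )
    return pd.DataFrame(rows, columns=["group", "pattern", "n_genes", "group_intronless"])
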