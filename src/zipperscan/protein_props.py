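"""Protein physicochemical properties: length, molecular weight, pI.

Molecular weight uses average-isotope residue masses (conventional for
whole-protein reporting). The isoelectric point is the pH at which the
Henderson-Hasselbalch net charge over the ionizable groups (termini plus
K, R, H, D, E, C, Y side chains) is zero, found by bisection; the pKa
constants are the EMBOSS set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Data.IUPACData import protein_weights

from .io_formats import ProteinRecord, SequenceValidationError

__all__ = [
    "EMBOSS_PKA",
    "WATER_MASS",
    "ProteinProperties",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "family_properties",
]

#: Average mass of water released per peptide bond (Da).
WATER_MASS = 18.0153

# Average-isotope residue masses: free amino acid mass minus one water.
_RESIDUE_MASS = {aa: protein_weights[aa] - WATER_MASS for aa in "ACDEFGHIKLMNPQRSTVWY"}
_MEAN_RESIDUE_MASS = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)

#: EMBOSS pKa constants (as published in the EMBOSS source: Nterm 8.6,
#: Cterm 3.6; side chains C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
#: Y 10.1). Swappable for other sets via the pka argument.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length: int
    mw_kda: float
    pi: float


def molecular_weight(protein: ProteinRecord, x_as_average: bool = False) -> float:
    """Average-isotope molecular weight in kDa.

    X residues raise an error unless ``x_as_average`` substitutes the mean
    residue mass for each X.
    """
    total = WATER_MASS
    for pos, aa in enumerate(protein.residues, start=1):
        if aa == "X":
            if not x_as_average:
                raise SequenceValidationError(
                    f"{protein.id}: X residue at position {pos}; "
                    "pass x_as_average=True to substitute the mean residue mass"
                )
            total += _MEAN_RESIDUE_MASS
        else:
            total += _RESIDUE_MASS[aa]
    return total / 1000.0


def net_charge(residues: str, ph: float, pka: dict[str, float] = EMBOSS_PKA) -> float:
    """Net protein charge at a given pH: sum of protonated basic-group
    fractions minus deprotonated acidic-group fractions. Strictly
    decreasing in pH."""
    counts = Counter(residues)
    counts["Nterm"] = counts["Cterm"] = 1
    charge = 0.0
    for group in _POSITIVE:
        n = counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[group]))
    for group in _NEGATIVE:
        n = counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[group] - ph))
    return charge


def isoelectric_point(
    protein: ProteinRecord,
    pka: dict[str, float] = EMBOSS_PKA,
    tol: float = 1e-3,
) -> float:
    """The pH of zero net charge, by bisection on [0, 14].

    The charge function is strictly decreasing and has opposite signs at
    the interval ends (the N-terminus is positive at pH 0, the C-terminus
    negative at pH 14), so the root always exists.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein.residues, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def family_properties(
    proteins: Sequence[ProteinRecord], x_as_average: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein property table plus min/max summaries.

    Returns ``(table, summary)``: the table has one row per protein with
    length, MW (kDa, 2 decimals) and pI (2 decimals); the summary holds the
    min and max of each column. Family proteomes routinely contain X, so
    mean-mass substitution is the default here.
    """
    if not proteins:
        raise ValueError("family_properties requires proteins")
    rows = [
        {
            "protein_id": p.id,
            "length": len(p.residues),
            "mw_kda": round(molecular_weight(p, x_as_average=x_as_average), 2),
            "pi": round(isoelectric_point(p), 2),
        }
        for p in proteins
    ]
    table = pd.DataFrame(rows).set_index("protein_id")
    summary = pd.DataFrame({"min": table.min(), "max": table.max()})
    return table, summary
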