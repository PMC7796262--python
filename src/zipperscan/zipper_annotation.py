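"""Basic-region detection and leucine-zipper heptad register assignment.

A bZIP domain is a basic DNA-binding segment containing an invariant
asparagine followed by seven arbitrary residues and an arginine or lysine
(N-x7-R/K), then an alpha-helical leucine zipper whose seven-residue repeats
(heptads) are labeled a-g with leucine canonically at *d*. This module turns
that definition into deterministic sequence arithmetic: the *d* position of
the first heptad (L0) anchors at the first leucine downstream of the R/K,
and successive heptads tile every seven residues until a helix-disrupting
residue (proline by default), the end of the sequence, or a heptad cap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Sequence

from .io_formats import ProteinRecord

__all__ = [
    "BasicRegionHit",
    "Heptad",
    "ZipperAnnotation",
    "REGISTER_LETTERS",
    "find_basic_regions",
    "assign_register",
    "annotate_family",
]

#: Heptad register letters in order; offsets relative to the d position.
REGISTER_LETTERS = ("a", "b", "c", "d", "e", "f", "g")
_LETTER_OFFSET = {"a": -3, "b": -2, "c": -1, "d": 0, "e": 1, "f": 2, "g": 3}

#: Residues treated as alpha-helix disruptors that terminate heptad tiling.
DEFAULT_DISRUPTORS: FrozenSet[str] = frozenset("P")

#: Aliphatic residues tolerated at the d position when no leucine exists.
WEAK_ANCHOR_RESIDUES: FrozenSet[str] = frozenset("IVM")

_BASIC_MOTIF = re.compile(r"(?=(N.{7}[RK]))")

#: Length of the basic-region context reported upstream of (and including) R/K.
BASIC_REGION_CONTEXT = 16


@dataclass(frozen=True)
class BasicRegionHit:
    """One match of the N-x7-R/K basic-region motif.

    ``span`` is the 0-based half-open 16-residue context ending at (and
    including) the R/K, clipped at the start of the sequence.
    """

    n_pos: int
    rk_pos: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.rk_pos - self.n_pos != 8:
            raise ValueError("basic-region hit must have rk_pos == n_pos + 8")


@dataclass(frozen=True)
class Heptad:
    """One seven-residue repeat; ``residues`` maps register letters to the
    residues present (truncated heptads carry only the letters that exist)."""

    index: int
    residues: dict[str, str]

    @property
    def complete(self) -> bool:
        return len(self.residues) == 7

    def get(self, letter: str) -> str | None:
        return self.residues.get(letter)


@dataclass(frozen=True)
class ZipperAnnotation:
    """Full zipper annotation of one protein.

    ``anchor_pos`` is the 0-based index of the d position of heptad L0 (None
    when no anchor residue exists downstream of the basic region). Heptad k
    occupies sequence positions ``anchor_pos - 3 + 7k .. anchor_pos + 3 + 7k``.
    """

    protein_id: str
    basic_region: BasicRegionHit
    anchor_pos: int | None
    heptads: tuple[Heptad, ...]
    terminated_by: str  # disruptor | end_of_sequence | max_heptads
    weak_anchor: bool = False

    @property
    def n_complete(self) -> int:
        return sum(1 for h in self.heptads if h.complete)

    def d_position(self, k: int) -> int:
        if self.anchor_pos is None:
            raise ValueError(f"{self.protein_id}: no anchor position")
        return self.anchor_pos + 7 * k


def find_basic_regions(protein: ProteinRecord) -> list[BasicRegionHit]:
    """All (possibly overlapping) matches of the N-x7-R/K motif, left to right."""
    hits = []
    for m in _BASIC_MOTIF.finditer(protein.residues):
        n_pos = m.start()
        rk_pos = n_pos + 8
        span = (max(0, rk_pos + 1 - BASIC_REGION_CONTEXT), rk_pos + 1)
        hits.append(BasicRegionHit(n_pos=n_pos, rk_pos=rk_pos, span=span))
    return hits


def assign_register(
    protein: ProteinRecord,
    hit: BasicRegionHit,
    max_heptads: int = 10,
    disruptors: Iterable[str] = DEFAULT_DISRUPTORS,
) -> ZipperAnnotation:
    """Assign the heptad register downstream of a basic-region hit.

    The d position of L0 anchors at the first leucine strictly after the
    R/K; letters a, b, c are assigned to the three preceding positions
    (clipped at ``rk_pos + 1``) and subsequent heptads tile every seven
    residues. Tiling stops at the first heptad containing a disruptor
    residue (that heptad is dropped), at the end of the sequence (the final
    heptad is retained truncated), or after ``max_heptads``.

    When no leucine exists downstream the anchor falls back to the first
    aliphatic residue from {I, V, M} and the annotation is flagged
    ``weak_anchor``; with no anchor candidate at all the heptad list is
    empty and ``terminated_by`` is ``end_of_sequence`` — such proteins are
    retained, not rejected, because family surveys keep members whose
    heptads lack d-leucines.
    """
    seq = protein.residues
    if not (0 <= hit.n_pos < len(seq)) or hit.rk_pos >= len(seq):
        raise ValueError(f"{protein.id}: hit does not fit in sequence")
    if seq[hit.n_pos] != "N" or seq[hit.rk_pos] not in "RK":
        raise ValueError(f"{protein.id}: hit residues do not match N-x7-R/K")
    disruptors = frozenset(disruptors)

    start = hit.rk_pos + 1
    anchor = None
    weak = False
    for i in range(start, len(seq)):
        if seq[i] == "L":
            anchor = i
            break
    if anchor is None:
        for i in range(start, len(seq)):
            if seq[i] in WEAK_ANCHOR_RESIDUES:
                anchor = i
                weak = True
                break
    if anchor is None:
        return ZipperAnnotation(
            protein_id=protein.id,
            basic_region=hit,
            anchor_pos=None,
            heptads=(),
            terminated_by="end_of_sequence",
        )

    heptads: list[Heptad] = []
    terminated = "max_heptads"
    for k in range(max_heptads):
        d_pos = anchor + 7 * k
        lo = d_pos - 3
        hi = d_pos + 3  # inclusive
        if k == 0:
            lo = max(lo, hit.rk_pos + 1)
        if lo >= len(seq):
            terminated = "end_of_sequence"
            break
        truncated = hi >= len(seq)
        hi = min(hi, len(seq) - 1)
        residues = {}
        hit_disruptor = False
        for pos in range(lo, hi + 1):
            if seq[pos] in disruptors:
                hit_disruptor = True
                break
            letter = REGISTER_LETTERS[pos - d_pos + 3]
            residues[letter] = seq[pos]
        if hit_disruptor:
            terminated = "disruptor"
            break
        heptads.append(Heptad(index=k, residues=residues))
        if truncated:
            terminated = "end_of_sequence"
            break

    return ZipperAnnotation(
        protein_id=protein.id,
        basic_region=hit,
        anchor_pos=anchor,
        heptads=tuple(heptads),
        terminated_by=terminated,
        weak_anchor=weak,
    )


def annotate_family(
    proteins: Sequence[ProteinRecord],
    max_heptads: int = 10,
    disruptors: Iterable[str] = DEFAULT_DISRUPTORS,
) -> tuple[list[ZipperAnnotation], list[str]]:
    """Annotate every protein, returning ``(annotations, rejected_ids)``.

    For proteins with several basic-region hits, the chosen hit is the
    left-most one whose downstream region yields the greatest number of
    complete heptads. Proteins without any hit go to the rejected list.
    """
    if not proteins:
        raise ValueError("annotate_family requires a non-empty protein list")
    annotations: list[ZipperAnnotation] = []
    rejected: list[str] = []
    for protein in proteins:
        hits = find_basic_regions(protein)
        if not hits:
            rejected.append(protein.id)
            continue
        best = None
        for h in hits:
            ann = assign_register(protein, h, max_heptads=max_heptads, disruptors=disruptors)
            if best is None or ann.n_complete > best.n_complete:
                best = ann
        annotations.append(best)
    return annotations, rejected
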