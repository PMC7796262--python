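"""Position-composition statistics and coiled-coil dimerization pair rules.

In a parallel leucine-zipper dimer the residue at position *g* of heptad k
contacts the residue at position *e* of heptad k+1 on the partner helix
(the g<->e' salt bridge), and the *a* positions of equal heptads pack
against each other (a<->a'). Charged g/e residues (D, E, K, R) give
attractive pairs (opposite charge, homodimer-favoring) or repulsive pairs
(like charge, heterodimer-favoring); a-position asparagine/aliphatic
combinations modulate stability. Histidine is treated as uncharged.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import FamilyCatalogEntry
from .zipper_annotation import REGISTER_LETTERS, ZipperAnnotation

__all__ = [
    "CHARGED",
    "ACIDIC",
    "BASIC",
    "A_POSITION_SET",
    "PositionFrequencies",
    "HeptadPairAssessment",
    "position_frequencies",
    "classify_ge_pair",
    "classify_aa_pair",
    "homodimer_profile",
    "group_pattern_table",
]

ACIDIC = frozenset("DE")
BASIC = frozenset("KR")
CHARGED = ACIDIC | BASIC

#: Residues whose occupancy at the a position is reported as a family summary.
A_POSITION_SET = frozenset("NIVM")

PAIR_CLASSES = ("attractive", "repulsive", "incomplete")
AA_CLASSES = ("favorable", "destabilizing", "hetero_favoring", "neutral")


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PositionFrequencies:
    """Residue counts and percentages per register letter over a heptad window.

    ``counts`` maps register letter -> residue -> count. Percentages use as
    denominator the number of heptads contributing that letter, excluding X.
    """

    window: tuple[int, int]
    counts: dict[str, dict[str, int]]

    def denominator(self, letter: str) -> int:
        return sum(n for res, n in self.counts[letter].items() if res != "X")

    def percentage(self, letter: str, residues: str | Iterable[str]) -> float:
        """Exact percentage of heptads whose ``letter`` position holds one of
        ``residues`` (X excluded from the denominator)."""
        wanted = set(residues)
        denom = self.denominator(letter)
        if denom == 0:
            return 0.0
        num = sum(n for res, n in self.counts[letter].items() if res in wanted)
        return 100.0 * num / denom

    @property
    def percentages(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for letter, ctr in self.counts.items():
            denom = self.denominator(letter)
            out[letter] = {
                res: (100.0 * n / denom if denom else 0.0)
                for res, n in ctr.items()
                if res != "X"
            }
        return out

    def summary(self, rounded: bool = True) -> dict[str, float | int]:
        """The four family-survey scalars: %L at d, %charged at g and e,
        %{N,I,V,M} at a; rounded half-up to integers for reporting."""
        vals = {
            "pct_leu_d": self.percentage("d", "L"),
            "pct_charged_g": self.percentage("g", CHARGED),
            "pct_charged_e": self.percentage("e", CHARGED),
            "pct_a_nivm": self.percentage("a", A_POSITION_SET),
        }
        if rounded:
            return {k: _round_half_up(v) for k, v in vals.items()}
        return vals


@dataclass(frozen=True)
class HeptadPairAssessment:
    """Classification of the inter-helical contacts anchored at one heptad:
    the g_k <-> e'_{k+offset} electrostatic pair and the a_k <-> a'_k pair."""

    heptad_index: int
    ge_class: str
    aa_class: str


def position_frequencies(
    annotations: Sequence[ZipperAnnotation],
    window: tuple[int, int] = (0, 4),
    complete_only: bool = False,
) -> PositionFrequencies:
    """Residue composition at each register letter over heptads in ``window``.

    Parameters
    ----------
    annotations
        Zipper annotations (typically the whole family).
    window
        Inclusive heptad index range, default L0..L4.
    complete_only
        Count only heptads carrying all seven letters; by default truncated
        heptads contribute the letters they contain.
    """
    if not annotations:
        raise ValueError("position_frequencies requires annotations")
    lo, hi = window
    if hi < lo:
        raise ValueError(f"empty heptad window {window}")
    counts: dict[str, Counter] = {letter: Counter() for letter in REGISTER_LETTERS}
    for ann in annotations:
        for hep in ann.heptads:
            if not (lo <= hep.index <= hi):
                continue
            if complete_only and not hep.complete:
                continue
            for letter, res in hep.residues.items():
                counts[letter][res] += 1
    return PositionFrequencies(window=(lo, hi), counts={k: dict(v) for k, v in counts.items()})


def classify_ge_pair(res_g: str | None, res_e_next: str | None) -> str:
    """Classify a g<->e' electrostatic contact.

    Both residues acidic or both basic -> ``repulsive``; one acidic and one
    basic -> ``attractive``; any uncharged or missing residue ->
    ``incomplete``. Symmetric in its arguments.
    """
    if res_g is None or res_e_next is None:
        return "incomplete"
    if res_g not in CHARGED or res_e_next not in CHARGED:
        return "incomplete"
    same = (res_g in ACIDIC) == (res_e_next in ACIDIC)
    return "repulsive" if same else "attractive"


def classify_aa_pair(res_a_self: str, res_a_partner: str) -> str:
    """Classify an a<->a' packing contact by the family-survey rule table.

    Homotypic V, I, or R -> ``favorable``; an N<->V pair ->
    ``hetero_favoring``; an N<->I pair or two charged residues ->
    ``destabilizing``; every other combination -> ``neutral`` (the table is
    the minimal closure of the stated rules, not an energetic model).
    """
    pair = frozenset((res_a_self, res_a_partner))
    if res_a_self == res_a_partner and res_a_self in "VIR":
        return "favorable"
    if pair == frozenset("NV"):
        return "hetero_favoring"
    if pair == frozenset("NI"):
        return "destabilizing"
    if res_a_self in CHARGED and res_a_partner in CHARGED:
        return "destabilizing"
    return "neutral"


def homodimer_profile(
    annotation: ZipperAnnotation, ge_offset: int = 1
) -> list[HeptadPairAssessment]:
    """Assess a zipper paired against itself in parallel register.

    For each heptad k the g residue is paired with the e residue of heptad
    ``k + ge_offset`` on the (identical) partner helix, and a_k with a_k.
    Annotations with fewer than two heptads yield an empty list with a
    warning.
    """
    heps = {h.index: h for h in annotation.heptads}
    if len(heps) < 2:
        warnings.warn(
            f"{annotation.protein_id}: fewer than two heptads, no dimer profile",
            stacklevel=2,
        )
        return []
    out = []
    for k in sorted(heps):
        partner = heps.get(k + ge_offset)
        if partner is None:
            continue
        ge = classify_ge_pair(heps[k].get("g"), partner.get("e"))
        a = heps[k].get("a")
        aa = classify_aa_pair(a, a) if a is not None else "neutral"
        out.append(HeptadPairAssessment(heptad_index=k, ge_class=ge, aa_class=aa))
    return out


def group_pattern_table(
    annotations: Sequence[ZipperAnnotation],
    catalog: Sequence[FamilyCatalogEntry],
    ge_offset: int = 1,
) -> pd.DataFrame:
    """Per functional group and heptad index, the modal g<->e' pair class.

    Returns a DataFrame with columns ``group``, ``heptad_index``,
    ``modal_class``, ``frequency`` (modal share among members contributing
    that index) and ``n``. This makes the qualitative cross-species
    comparison of attraction/repulsion patterns a concrete table.
    """
    group_of = {c.gene_name: c.group for c in catalog}
    by_group: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for ann in annotations:
        if ann.protein_id not in group_of:
            raise ValueError(f"{ann.protein_id}: not present in family catalog")
        group = group_of[ann.protein_id]
        for assess in homodimer_profile(ann, ge_offset=ge_offset):
            by_group[(group, assess.heptad_index)][assess.ge_class] += 1
    rows = []
    for (group, idx), ctr in sorted(by_group.items()):
        modal, count = ctr.most_common(1)[0]
        rows.append(
            {
                "group": group,
                "heptad_index": idx,
                "modal_class": modal,
                "frequency": count / sum(ctr.values()),
                "n": sum(ctr.values()),
            }
        )
    return pd.DataFrame(rows, columns=["group", "heptad_index", "modal_class", "frequency", "n"])
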