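"""Nei-Gojobori (1986) Ka/Ks estimation and duplication-type classification.

The counting method: each sense codon contributes fractional synonymous
site counts (per position, the fraction of the three single-nucleotide
changes that are synonymous; changes creating stop codons count as
nonsynonymous). Differences between a codon pair are resolved by averaging
the synonymous/nonsynonymous step counts over all orderings of the
differing positions (mutational pathways), skipping pathways that pass
through stop codons. Proportions pS = Sd/S and pN = Nd/N are corrected for
multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).

Codon alignment is protein-guided: translate, globally align the proteins
(BLOSUM62, linear gap), and thread the codons back under the protein
alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import permutations
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .io_formats import GeneModel, NucleotideRecord, SequenceValidationError

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "GENETIC_CODE",
    "CodonAlignment",
    "DivergenceEstimate",
    "DuplicationEvent",
    "align_codons",
    "ng_sites",
    "ng_estimate",
    "classify_selection",
    "classify_duplication",
    "ratio_from_table",
]

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
_BASES = "ACGT"

_SITE_CACHE: dict[str, tuple[float, float]] = {}
_DIFF_CACHE: dict[tuple[str, str, bool], tuple[float, float]] = {}


@dataclass(frozen=True)
class CodonAlignment:
    """A pairwise codon alignment; each column holds a sense codon or None
    (gap) per sequence."""

    id_a: str
    id_b: str
    columns: tuple[tuple[str | None, str | None], ...]

    @property
    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in self.columns if a is not None and b is not None]


@dataclass(frozen=True)
class DivergenceEstimate:
    """NG86 quantities for one aligned pair.

    ``ratio`` is present only when the ``ok`` flag is set (Ks > 0 and
    neither Jukes-Cantor argument is non-positive).
    """

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    ratio: float | None
    flags: frozenset[str]

    @property
    def ok(self) -> bool:
        return "ok" in self.flags


@dataclass(frozen=True)
class DuplicationEvent:
    gene_a: str
    gene_b: str
    type: str  # "tandem" | "segmental"
    chrom_a: str
    chrom_b: str
    distance: int | None = None
    intervening: int | None = None

    def __post_init__(self) -> None:
        if self.type == "tandem" and self.chrom_a != self.chrom_b:
            raise ValueError("tandem duplication requires a shared chromosome")


# ---------------------------------------------------------------------------
# Site and difference counting


def ng_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one sense codon.

    For each of the three positions, the fraction of the three possible
    single-nucleotide changes that preserve the encoded amino acid;
    changes creating stop codons count as nonsynonymous. s + n == 3.
    """
    if codon in _SITE_CACHE:
        return _SITE_CACHE[codon]
    if codon not in GENETIC_CODE:
        raise SequenceValidationError(f"{codon!r} is not a sense codon")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and GENETIC_CODE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    result = (s, 3.0 - s)
    _SITE_CACHE[codon] = result
    return result


def _step_is_synonymous(c_from: str, c_to: str) -> bool:
    # stop-involving steps are nonsynonymous (only reachable in fallback mode)
    if c_from in STOP_CODONS or c_to in STOP_CODONS:
        return False
    return GENETIC_CODE[c_from] == GENETIC_CODE[c_to]


def _pair_differences(
    codon_a: str, codon_b: str, skip_stop_paths: bool = True
) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) increments for one codon pair.

    Averages synonymous/nonsynonymous step counts over the orderings of
    the differing positions; pathways passing through stop codons are
    skipped unless every pathway does, in which case all are counted.
    """
    key = (codon_a, codon_b, skip_stop_paths)
    if key in _DIFF_CACHE:
        return _DIFF_CACHE[key]
    for c in (codon_a, codon_b):
        if c not in GENETIC_CODE:
            raise SequenceValidationError(f"{c!r} is not a sense codon")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        _DIFF_CACHE[key] = (0.0, 0.0)
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        current = codon_a
        syn = non = 0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if skip_stop_paths and nxt in STOP_CODONS:
                return None
            if _step_is_synonymous(current, nxt):
                syn += 1
            else:
                non += 1
            current = nxt
        return float(syn), float(non)

    paths = [walk(order) for order in permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    if not valid and skip_stop_paths:
        # every pathway traverses a stop: fall back to counting all of them
        valid = [
            p
            for p in (
                _walk_all(codon_a, codon_b, order) for order in permutations(diff_positions)
            )
        ]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    _DIFF_CACHE[key] = (sd, nd)
    return sd, nd


def _walk_all(codon_a: str, codon_b: str, order: tuple[int, ...]) -> tuple[float, float]:
    current = codon_a
    syn = non = 0
    for pos in order:
        nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
        if _step_is_synonymous(current, nxt):
            syn += 1
        else:
            non += 1
        current = nxt
    return float(syn), float(non)


# ---------------------------------------------------------------------------
# Alignment


def _codons_of(record: NucleotideRecord, trim_terminal_stop: bool = True) -> list[str]:
    seq = record.bases
    if len(seq) % 3 != 0:
        raise SequenceValidationError(
            f"{record.id}: CDS length {len(seq)} is not divisible by 3"
        )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if trim_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for idx, c in enumerate(codons):
        if c in STOP_CODONS:
            raise SequenceValidationError(f"{record.id}: internal stop codon at codon {idx + 1}")
        if c not in GENETIC_CODE:
            raise SequenceValidationError(f"{record.id}: ambiguous codon {c!r} at codon {idx + 1}")
    return codons


def align_codons(
    cds_a: NucleotideRecord,
    cds_b: NucleotideRecord,
    gap_score: float = -8.0,
    trim_terminal_stop: bool = True,
) -> CodonAlignment:
    """Protein-guided codon alignment of two coding sequences.

    Both sequences are translated, the proteins are aligned globally
    (BLOSUM62, linear gap penalty ``gap_score``), and codons are threaded
    back under the protein alignment; columns with a gap in either protein
    become gap columns.
    """
    codons_a = _codons_of(cds_a, trim_terminal_stop)
    codons_b = _codons_of(cds_b, trim_terminal_stop)
    prot_a = str(Seq("".join(codons_a)).translate())
    prot_b = str(Seq("".join(codons_b)).translate())

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_score
    aligner.extend_gap_score = gap_score
    aln = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    columns: list[tuple[str | None, str | None]] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        cod_a = cod_b = None
        if ca != "-":
            cod_a = codons_a[ia]
            ia += 1
        if cb != "-":
            cod_b = codons_b[ib]
            ib += 1
        columns.append((cod_a, cod_b))
    return CodonAlignment(id_a=cds_a.id, id_b=cds_b.id, columns=tuple(columns))


# ---------------------------------------------------------------------------
# Estimation


def ng_estimate(alignment: CodonAlignment, skip_stop_paths: bool = True) -> DivergenceEstimate:
    """NG86 divergence estimate over the non-gap columns of an alignment."""
    pairs = alignment.ungapped_columns
    if not pairs:
        raise SequenceValidationError(
            f"{alignment.id_a}/{alignment.id_b}: no comparable codon columns"
        )
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        s_a += ng_sites(ca)[0]
        s_b += ng_sites(cb)[0]
        d_s, d_n = _pair_differences(ca, cb, skip_stop_paths)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(pairs) - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0

    flags: set[str] = set()
    ks = ka = ratio = None
    arg_s = 1.0 - 4.0 * ps / 3.0
    arg_n = 1.0 - 4.0 * pn / 3.0
    if arg_s <= 0.0 or arg_n <= 0.0:
        flags.add("jc_saturated")
    else:
        ks = -0.75 * math.log(arg_s)
        ka = -0.75 * math.log(arg_n)
        if ks == 0.0:
            flags.add("ks_zero")
        else:
            flags.add("ok")
            ratio = ka / ks
    return DivergenceEstimate(
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        ratio=ratio,
        flags=frozenset(flags),
    )


def classify_selection(est: DivergenceEstimate, tol: float = 0.05) -> str:
    """Label an estimate: Ka/Ks < 1 purifying, = 1 neutral, > 1 positive
    (within ``tol``); flagged estimates are undetermined."""
    if not est.ok or est.ratio is None:
        return "undetermined"
    if est.ratio < 1.0 - tol:
        return "purifying"
    if est.ratio > 1.0 + tol:
        return "positive"
    return "neutral"


def ratio_from_table(ka: float, ks: float) -> float:
    """Ka/Ks rounded half-up to two decimals, matching tabular reporting."""
    if ks <= 0:
        raise ValueError("ratio_from_table requires ks > 0")
    return float(
        (Decimal(repr(ka)) / Decimal(repr(ks))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


# ---------------------------------------------------------------------------
# Duplication classification


def _span(model: GeneModel) -> tuple[int, int]:
    return min(s for s, _ in model.exons), max(e for _, e in model.exons)


def classify_duplication(
    model_a: GeneModel,
    model_b: GeneModel,
    all_models: Sequence[GeneModel] | None = None,
    max_intervening: int = 5,
    max_distance: int = 100_000,
) -> DuplicationEvent:
    """Classify a paralog pair as a tandem or segmental duplication.

    Tandem requires the same chromosome and either at most
    ``max_intervening`` annotated genes between the pair (counted from
    ``all_models`` when given) or a genomic gap of at most ``max_distance``
    bases; everything else is segmental. The thresholds are exposed because
    tandem definitions vary between collinearity tools.
    """
    a_lo, a_hi = _span(model_a)
    b_lo, b_hi = _span(model_b)
    if model_a.chrom != model_b.chrom:
        return DuplicationEvent(
            gene_a=model_a.gene_id,
            gene_b=model_b.gene_id,
            type="segmental",
            chrom_a=model_a.chrom,
            chrom_b=model_b.chrom,
        )
    gap_lo, gap_hi = min(a_hi, b_hi), max(a_lo, b_lo)
    distance = max(0, gap_hi - gap_lo - 1)
    intervening = None
    if all_models is not None:
        intervening = sum(
            1
            for m in all_models
            if m.chrom == model_a.chrom
            and m.gene_id not in (model_a.gene_id, model_b.gene_id)
            and gap_lo < _span(m)[0] and _span(m)[1] < gap_hi
        )
    is_tandem = distance <= max_distance or (
        intervening is not None and intervening <= max_intervening
    )
    return DuplicationEvent(
        gene_a=model_a.gene_id,
        gene_b=model_b.gene_id,
        type="tandem" if is_tandem else "segmental",
        chrom_a=model_a.chrom,
        chrom_b=model_b.chrom,
        distance=distance,
        intervening=intervening,
    )
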