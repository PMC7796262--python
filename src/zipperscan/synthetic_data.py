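"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes — proteins with planted basic regions and heptad registers of
controlled composition, codon pairs diverged under a chosen dN/dS, gene
models with planted intron phases, promoters with planted motif counts,
and expression matrices with planted cluster structure — and returns
machine-readable truth sufficient to score the stage without re-derivation.
All randomness flows from one seeded generator per call; identical spec and
seed give byte-identical output.

Recoverability is structural, not statistical: planted zipper backgrounds
exclude the residues the annotator keys on (N, K, R for the basic-region
motif; L, I, V, M for the anchor; P as disruptor), so a planted register
cannot be shadowed by an accidental one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_structure import GeneStructureProfile
from .io_formats import GeneModel, NucleotideRecord, ProteinRecord, write_gff3
from .kaks_ng import GENETIC_CODE, SENSE_CODONS, STOP_CODONS
from .promoter_cre import CREMotif, IUPAC, is_palindromic, load_motifs, reverse_complement
from .zipper_annotation import (
    BasicRegionHit,
    Heptad,
    REGISTER_LETTERS,
    ZipperAnnotation,
)

__all__ = [
    "PlantedZipperSpec",
    "CodonPairSpec",
    "PlantedGeneSpec",
    "PlantedPromoterSpec",
    "gen_zipper_set",
    "gen_codon_pair",
    "gen_gene_models",
    "gen_promoters",
    "gen_expression",
]

_CHARGED = "DEKR"
_A_SET = "NIVM"
# Background residues: the 20 amino acids minus {N, K, R} (would seed
# spurious basic-region motifs), {L, I, V, M} (would mislead the anchor
# rule), and P (the default disruptor).
_BACKGROUND = "ACDEFGHQSTWY"
# At g/e positions the miss branch must not reintroduce charged residues,
# or the planted charged fraction would exceed its probability.
_BACKGROUND_UNCHARGED = "ACFGHQSTWY"


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


# ---------------------------------------------------------------------------
# Planted leucine zippers


@dataclass(frozen=True)
class PlantedZipperSpec:
    """Family of proteins with one planted basic region and zipper each.

    The per-position probabilities mirror the family-survey statistics:
    ``p_leu_d`` for leucine at d, ``p_charged_g``/``p_charged_e`` for a
    residue from {D, E, K, R} at g/e, ``p_a_set`` for one of {N, I, V, M}
    at a. Defaults are the observed family frequencies (65/43/28/30%).
    """

    n_proteins: int
    n_heptads: int | tuple[int, int] = (3, 10)
    p_leu_d: float = 0.65
    p_charged_g: float = 0.43
    p_charged_e: float = 0.28
    p_a_set: float = 0.30
    flank_len: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_leu_d", "p_charged_g", "p_charged_e", "p_a_set"):
            _check_prob(name, getattr(self, name))
        lo = self.n_heptads if isinstance(self.n_heptads, int) else self.n_heptads[0]
        if lo < 3:
            raise ValueError("n_heptads must be >= 3")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


def _draw(rng: np.random.Generator, alphabet: str, n: int = 1) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def gen_zipper_set(
    spec: PlantedZipperSpec,
) -> tuple[list[ProteinRecord], list[ZipperAnnotation]]:
    """Generate proteins with planted zippers and their truth annotations.

    Layout per protein: background flank, N + 7 background + R/K, then
    ``n_heptads`` contiguous a..g heptads (the d of L0 sits four residues
    after the R/K), a terminating proline, and a trailing flank. Truth
    heptads are complete and terminate by disruptor.
    """
    rng = np.random.default_rng(spec.seed)
    proteins: list[ProteinRecord] = []
    truths: list[ZipperAnnotation] = []
    for i in range(spec.n_proteins):
        if isinstance(spec.n_heptads, int):
            n_hep = spec.n_heptads
        else:
            n_hep = int(rng.integers(spec.n_heptads[0], spec.n_heptads[1] + 1))
        flank5 = _draw(rng, _BACKGROUND, spec.flank_len)
        basic = "N" + _draw(rng, _BACKGROUND, 7) + ("R" if rng.random() < 0.5 else "K")
        heptads: list[Heptad] = []
        zipper_parts: list[str] = []
        for k in range(n_hep):
            residues: dict[str, str] = {}
            for letter in REGISTER_LETTERS:
                if letter == "d":
                    res = "L" if rng.random() < spec.p_leu_d else _draw(rng, _BACKGROUND)
                elif letter == "a":
                    res = _draw(rng, _A_SET) if rng.random() < spec.p_a_set else _draw(rng, _BACKGROUND)
                elif letter == "g":
                    res = _draw(rng, _CHARGED) if rng.random() < spec.p_charged_g else _draw(rng, _BACKGROUND_UNCHARGED)
                elif letter == "e":
                    res = _draw(rng, _CHARGED) if rng.random() < spec.p_charged_e else _draw(rng, _BACKGROUND_UNCHARGED)
                else:
                    res = _draw(rng, _BACKGROUND)
                residues[letter] = res
            heptads.append(Heptad(index=k, residues=residues))
            zipper_parts.append("".join(residues[letter] for letter in REGISTER_LETTERS))
        seq = flank5 + basic + "".join(zipper_parts) + "P" + _draw(rng, _BACKGROUND, spec.flank_len)
        n_pos = spec.flank_len
        rk_pos = n_pos + 8
        anchor = rk_pos + 4
        protein = ProteinRecord(id=f"synthetic_zipper_{i:04d}", residues=seq)
        truth = ZipperAnnotation(
            protein_id=protein.id,
            basic_region=BasicRegionHit(
                n_pos=n_pos, rk_pos=rk_pos, span=(max(0, rk_pos - 15), rk_pos + 1)
            ),
            anchor_pos=anchor,
            heptads=tuple(heptads),
            terminated_by="disruptor",
            weak_anchor=False,
        )
        proteins.append(protein)
        truths.append(truth)
    return proteins, truths


# ---------------------------------------------------------------------------
# Diverged codon pairs


@dataclass(frozen=True)
class CodonPairSpec:
    """Two codon sequences diverged from a common ancestor under dN/dS
    ``omega``. ``expected_subs_per_codon`` is the Poisson intensity of
    proposed single-nucleotide events per codon per lineage; acceptance
    thinning (nonsynonymous with min(1, omega), synonymous with
    min(1, 1/omega)) then realizes the target rate ratio."""

    n_codons: int
    omega: float = 0.5
    expected_subs_per_codon: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.expected_subs_per_codon < 0:
            raise ValueError("expected_subs_per_codon must be >= 0")


_OTHER_BASES = {b: "ACGT".replace(b, "") for b in "ACGT"}


def _evolve(
    codons: list[str], spec: CodonPairSpec, rng: np.random.Generator
) -> tuple[list[str], int, int]:
    """One lineage: propose Poisson-many uniform single-nucleotide changes,
    reject stop-creating candidates, thin by the acceptance probabilities.
    Returns the descendant codons and the accepted (syn, nonsyn) counts."""
    out = list(codons)
    p_non = min(1.0, spec.omega)
    p_syn = min(1.0, 1.0 / spec.omega)
    n_events = int(rng.poisson(spec.n_codons * spec.expected_subs_per_codon))
    syn = non = 0
    for _ in range(n_events):
        idx = int(rng.integers(spec.n_codons))
        pos = int(rng.integers(3))
        base = _OTHER_BASES[out[idx][pos]][int(rng.integers(3))]
        mutant = out[idx][:pos] + base + out[idx][pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        if GENETIC_CODE[mutant] == GENETIC_CODE[out[idx]]:
            if rng.random() < p_syn:
                out[idx] = mutant
                syn += 1
        else:
            if rng.random() < p_non:
                out[idx] = mutant
                non += 1
    return out, syn, non


def gen_codon_pair(
    spec: CodonPairSpec,
) -> tuple[NucleotideRecord, NucleotideRecord, dict[str, int]]:
    """Generate a diverged codon-sequence pair with realized event counts.

    The ancestor is uniform over sense codons; two lineages evolve
    independently. Neither output contains internal stop codons. The
    returned counts are the accepted synonymous/nonsynonymous events per
    lineage — exact ground truth for estimator recovery.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=spec.n_codons)]
    codons_a, syn_a, non_a = _evolve(ancestor, spec, rng)
    codons_b, syn_b, non_b = _evolve(ancestor, spec, rng)
    realized = {
        "syn_a": syn_a,
        "nonsyn_a": non_a,
        "syn_b": syn_b,
        "nonsyn_b": non_b,
        "syn": syn_a + syn_b,
        "nonsyn": non_a + non_b,
    }
    return (
        NucleotideRecord(id="lineage_a", bases="".join(codons_a)),
        NucleotideRecord(id="lineage_b", bases="".join(codons_b)),
        realized,
    )


# ---------------------------------------------------------------------------
# Planted gene models


@dataclass(frozen=True)
class PlantedGeneSpec:
    """A gene model with planted intron phases.

    ``phase_pairs`` lists the (left, right) flanking-phase class of every
    coding exon except the last; the final exon closes the frame with
    class (last right, 0). Consecutive pairs must chain (the right phase
    of one exon is the left phase of the next) and the first left phase is
    0. An empty list gives a single-exon, intronless gene.
    """

    phase_pairs: tuple[tuple[int, int], ...] = ()
    exon_len_range: tuple[int, int] = (60, 300)
    intron_len_range: tuple[int, int] = (80, 200)
    gene_id: str = "synthetic_gene"
    chrom: str = "chr_s1"
    strand: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for left, right in self.phase_pairs:
            if left not in (0, 1, 2) or right not in (0, 1, 2):
                raise ValueError("intron phases must be 0, 1 or 2")
        if self.phase_pairs and self.phase_pairs[0][0] != 0:
            raise ValueError("first exon must open at phase 0")
        for (_, r), (l, _) in zip(self.phase_pairs, self.phase_pairs[1:]):
            if r != l:
                raise ValueError("phase_pairs must chain: right phase of exon i "
                                 "== left phase of exon i+1")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")


def gen_gene_models(spec: PlantedGeneSpec) -> tuple[str, str, GeneStructureProfile]:
    """Generate (GFF3 text, genome FASTA text, truth structure profile)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.exon_len_range

    # coding length of each exon must leave the right residue modulo 3
    lengths_tx: list[int] = []
    for left, right in spec.phase_pairs:
        base = int(rng.integers(lo, hi + 1))
        need = (right - left) % 3
        length = base - base % 3 + need
        lengths_tx.append(length + 3 if length < 3 else length)
    last_left = spec.phase_pairs[-1][1] if spec.phase_pairs else 0
    base = int(rng.integers(lo, hi + 1))
    need = (0 - last_left) % 3
    length = base - base % 3 + need
    lengths_tx.append(length + 3 if length < 3 else length)

    lengths_genomic = lengths_tx if spec.strand == 1 else lengths_tx[::-1]
    intron_lens = [
        int(rng.integers(spec.intron_len_range[0], spec.intron_len_range[1] + 1))
        for _ in range(len(lengths_genomic) - 1)
    ]
    spacer = 500
    spans: list[tuple[int, int]] = []
    pos = spacer + 1  # 1-based
    for i, length in enumerate(lengths_genomic):
        spans.append((pos, pos + length - 1))
        pos += length
        if i < len(intron_lens):
            pos += intron_lens[i]
    genome_len = pos + spacer
    genome = _draw(rng, "ACGT", genome_len)

    model = GeneModel(
        gene_id=spec.gene_id,
        chrom=spec.chrom,
        strand=spec.strand,
        exons=tuple(spans),
        cds_spans=tuple(spans),
        tss=spans[0][0] if spec.strand == 1 else spans[-1][1],
        partial=False,
        transcript_id=f"{spec.gene_id}.1",
    )
    gff3_text = write_gff3([model])
    fasta_text = f">{spec.chrom}\n" + "\n".join(
        genome[i : i + 60] for i in range(0, len(genome), 60)
    ) + "\n"

    phases = tuple(right for _, right in spec.phase_pairs)
    classes = tuple(spec.phase_pairs) + ((last_left, 0),)
    truth = GeneStructureProfile(
        gene_id=spec.gene_id, intron_phases=phases, exon_classes=classes, partial=False
    )
    return gff3_text, fasta_text, truth


# ---------------------------------------------------------------------------
# Planted promoters


@dataclass(frozen=True)
class PlantedPromoterSpec:
    """A promoter with planted, non-overlapping motif occurrences.

    ``motif_counts`` maps motif names (from ``motifs``, default bundled
    table) to intended planted counts. ``gc_background`` sets the GC
    fraction of the background; spurious background matches are scrubbed
    by point mutation so the final truth counts are exact.
    """

    motif_counts: Mapping[str, int] = field(default_factory=dict)
    length: int = 2000
    gc_background: float = 0.4
    promoter_id: str = "synthetic_promoter"
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("gc_background", self.gc_background)
        if self.length < 1:
            raise ValueError("length must be positive")
        for name, count in self.motif_counts.items():
            if count < 0:
                raise ValueError(f"negative planted count for {name}")


def _iupac_sets(pattern: str) -> list[frozenset[str]]:
    return [frozenset(IUPAC[ch]) for ch in pattern]


def _find_matches(seq: str, motif: CREMotif) -> list[tuple[int, int]]:
    """Forward-coordinate spans of all matches of a motif on both strands
    (palindromic patterns on the forward strand only). Independent of the
    scanner module: plain sliding-window set membership."""
    spans: list[tuple[int, int]] = []
    sets = _iupac_sets(motif.pattern)
    L = len(sets)
    for i in range(len(seq) - L + 1):
        if all(seq[i + j] in sets[j] for j in range(L)):
            spans.append((i, i + L))
    if not is_palindromic(motif.pattern):
        rc = reverse_complement(seq)
        n = len(seq)
        for i in range(n - L + 1):
            if all(rc[i + j] in sets[j] for j in range(L)):
                spans.append((n - i - L, n - i))
    return spans


def _concrete(pattern: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[ch][int(rng.integers(len(IUPAC[ch])))] for ch in pattern)


def gen_promoters(
    spec: PlantedPromoterSpec, motifs: Sequence[CREMotif] | None = None
) -> tuple[str, dict[str, int]]:
    """Generate (promoter FASTA text, truth counts per motif).

    Planted occurrences are concrete instantiations of each motif's IUPAC
    pattern at non-overlapping random positions. Background positions are
    drawn at the requested GC fraction, then any match not fully contained
    in planted material is destroyed by mutating one of its background
    positions and rescanning. Truth is the generator's own (scanner-
    independent) count over the final sequence, so nested planted patterns
    are reflected honestly.
    """
    if motifs is None:
        motifs = load_motifs()
    by_name = {m.name: m for m in motifs}
    for name in spec.motif_counts:
        if name not in by_name:
            raise ValueError(f"unknown motif {name!r}")
    rng = np.random.default_rng(spec.seed)

    planted: list[tuple[int, int]] = []  # 0-based half-open spans
    seq = list(_draw_background(rng, spec.length, spec.gc_background))
    for name, count in sorted(spec.motif_counts.items()):
        pattern = by_name[name].pattern
        for _ in range(count):
            placed = False
            for _try in range(2000):
                start = int(rng.integers(0, spec.length - len(pattern) + 1))
                span = (start, start + len(pattern))
                if all(span[1] <= s or span[0] >= e for s, e in planted):
                    word = _concrete(pattern, rng)
                    seq[span[0] : span[1]] = list(word)
                    planted.append(span)
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place {count} non-overlapping copies of {name} "
                    f"in {spec.length} bp"
                )

    def in_planted(pos: int) -> bool:
        return any(s <= pos < e for s, e in planted)

    for _iteration in range(300):
        dirty = False
        text = "".join(seq)
        for motif in motifs:
            for s, e in _find_matches(text, motif):
                background_positions = [p for p in range(s, e) if not in_planted(p)]
                if not background_positions:
                    continue  # intrinsic to planted material: part of truth
                pos = background_positions[int(rng.integers(len(background_positions)))]
                current = seq[pos]
                seq[pos] = _OTHER_BASES[current][int(rng.integers(3))]
                dirty = True
        if not dirty:
            break
    else:
        raise RuntimeError("background scrubbing did not converge")

    final = "".join(seq)
    truth = {m.name: len(_find_matches(final, m)) for m in motifs}
    fasta_text = f">{spec.promoter_id}\n" + "\n".join(
        final[i : i + 60] for i in range(0, len(final), 60)
    ) + "\n"
    return fasta_text, truth


def _draw_background(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


# ---------------------------------------------------------------------------
# Planted expression structure


def gen_expression(
    groups: int,
    genes_per_group: int,
    samples: int,
    separation: float,
    seed: int = 0,
    noise_sd: float = 0.5,
    baseline: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Log2 expression matrix with planted row-cluster structure.

    Each gene group is elevated by ``separation`` in its own block of
    samples over a ``baseline`` log2 level, with Gaussian noise. Returns
    the gene-by-sample DataFrame and the true group label per gene.
    """
    if groups < 1 or genes_per_group < 1 or samples < groups:
        raise ValueError("need at least one sample per group")
    rng = np.random.default_rng(seed)
    block = np.array_split(np.arange(samples), groups)
    rows = []
    labels: dict[str, int] = {}
    index = []
    for g in range(groups):
        for j in range(genes_per_group):
            mean = np.full(samples, baseline)
            mean[block[g]] += separation
            rows.append(mean + rng.normal(0.0, noise_sd, size=samples))
            name = f"gene_g{g}_{j:03d}"
            index.append(name)
            labels[name] = g
    matrix = pd.DataFrame(
        np.vstack(rows), index=index, columns=[f"sample_{s:02d}" for s in range(samples)]
    )
    return matrix, labels
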