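"""NG86 estimator tests against independent enumeration oracles.

The oracles here use Biopython translation plus explicit permutation
walks, written separately from the implementation's cached tables.
"""

import math
from itertools import permutations

import pytest
from Bio.Seq import Seq

from zipperscan.io_formats import GeneModel, NucleotideRecord, SequenceValidationError
from zipperscan.kaks_ng import (
    CodonAlignment,
    SENSE_CODONS,
    STOP_CODONS,
    align_codons,
    classify_duplication,
    classify_selection,
    ng_estimate,
    ng_sites,
    ratio_from_table,
)
from zipperscan.synthetic_data import CodonPairSpec, gen_codon_pair


def _aa(codon):
    return str(Seq(codon).translate())


def oracle_sites(codon):
    """Independent per-codon synonymous site fraction by explicit
    enumeration of the nine single-nucleotide neighbors."""
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and _aa(mutant) == _aa(codon):
                s += 1 / 3
    return s


def oracle_pathways(ca, cb, skip_stops=True):
    """Independent pathway enumerator: average syn/nonsyn step counts over
    orderings of the differing positions."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur, syn, non = ca, 0, 0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if not allow_stops and nxt in STOP_CODONS:
                return None
            if nxt not in STOP_CODONS and cur not in STOP_CODONS and _aa(cur) == _aa(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    paths = [walk(o, not skip_stops) for o in permutations(diffs)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(o, True) for o in permutations(diffs)]
    return (
        sum(p[0] for p in valid) / len(valid),
        sum(p[1] for p in valid) / len(valid),
    )


class TestSites:
    @pytest.mark.parametrize(
        "codon,expected_s",
        [("TTT", 1 / 3), ("TTA", 2 / 3), ("TGG", 0.0)],
    )
    def test_known_codons(self, codon, expected_s):
        s, n = ng_sites(codon)
        assert s == pytest.approx(expected_s, abs=1e-12)
        assert s + n == pytest.approx(3.0)

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert ng_sites(codon)[0] == pytest.approx(oracle_sites(codon), abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(SequenceValidationError):
            ng_sites("TAA")


class TestEstimate:
    def test_identical_columns_flagged_ks_zero(self):
        est = ng_estimate(CodonAlignment("a", "b", (("TTT", "TTT"),) * 5))
        assert est.sd == est.nd == 0
        assert "ks_zero" in est.flags
        assert est.ratio is None

    def test_single_nonsynonymous_column_hand_values(self):
        est = ng_estimate(CodonAlignment("a", "b", (("TTT", "TTA"),)))
        assert est.s_sites == pytest.approx(0.5)
        assert est.n_sites == pytest.approx(2.5)
        assert (est.sd, est.nd) == (0.0, 1.0)
        assert est.pn == pytest.approx(0.4)
        assert est.ka == pytest.approx(-0.75 * math.log(1 - 4 * 0.4 / 3))
        assert "ks_zero" in est.flags

    def test_two_difference_columns_match_pathway_oracle(self):
        pairs = [("TTT", "TCA"), ("ATG", "AAA"), ("GGG", "GAC"), ("TGT", "AGA")]
        for ca, cb in pairs:
            est = ng_estimate(CodonAlignment("a", "b", ((ca, cb),)))
            sd, nd = oracle_pathways(ca, cb)
            assert est.sd == pytest.approx(sd, abs=1e-12)
            assert est.nd == pytest.approx(nd, abs=1e-12)

    def test_symmetry_in_sequence_order(self):
        cols = (("TTT", "TCA"), ("ATG", "ATG"), ("GGG", "GAC"))
        fwd = ng_estimate(CodonAlignment("a", "b", cols))
        rev = ng_estimate(CodonAlignment("b", "a", tuple((b, a) for a, b in cols)))
        assert (fwd.sd, fwd.nd, fwd.s_sites, fwd.n_sites) == (
            rev.sd, rev.nd, rev.s_sites, rev.n_sites,
        )
        assert fwd.ks == rev.ks and fwd.ka == rev.ka and fwd.flags == rev.flags

    def test_site_conservation_invariant(self):
        a, b, _ = gen_codon_pair(CodonPairSpec(n_codons=100, omega=0.5, seed=9))
        est = ng_estimate(align_codons(a, b))
        assert est.s_sites + est.n_sites == pytest.approx(3 * 100)

    def test_saturated_alignment_flagged(self):
        # maximally divergent synonymous-rich columns push pS over 3/4
        cols = (("TTA", "CTG"),) * 3  # Leu->Leu two synonymous changes each
        est = ng_estimate(CodonAlignment("a", "b", cols))
        if "jc_saturated" in est.flags:
            assert est.ks is None
        else:  # if not saturated the estimate must still be well-formed
            assert est.ks is not None


class TestAlignment:
    def test_identical_cds_no_gaps(self):
        rec = NucleotideRecord(id="a", bases="ATGGCTGCT")
        aln = align_codons(rec, NucleotideRecord(id="b", bases="ATGGCTGCT"))
        assert all(a == b for a, b in aln.columns)
        assert len(aln.columns) == 3

    def test_single_codon_deletion_gives_one_gap_column(self):
        a = NucleotideRecord(id="a", bases="ATGGCTAAGGAGTGGGCT")
        b = NucleotideRecord(id="b", bases="ATGGCTGAGTGGGCT")  # AAG removed
        aln = align_codons(a, b)
        gaps = [c for c in aln.columns if c[0] is None or c[1] is None]
        assert len(gaps) == 1

    def test_simulated_pair_column_count(self):
        a, b, _ = gen_codon_pair(CodonPairSpec(n_codons=200, omega=1.0, seed=4))
        aln = align_codons(a, b)
        assert len(aln.columns) == 200

    def test_internal_stop_rejected_with_codon_index(self):
        rec = NucleotideRecord(id="bad", bases="ATGTAAGCT")
        with pytest.raises(SequenceValidationError, match="codon 2"):
            align_codons(rec, rec)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(SequenceValidationError, match="divisible"):
            align_codons(
                NucleotideRecord(id="a", bases="ATGG"),
                NucleotideRecord(id="b", bases="ATGGCT"),
            )

    def test_terminal_stop_trimmed(self):
        rec = NucleotideRecord(id="a", bases="ATGGCTTAA")
        aln = align_codons(rec, NucleotideRecord(id="b", bases="ATGGCTTGA"))
        assert len(aln.columns) == 2


class TestSelectionAndTable:
    def test_purifying_call_for_printed_ratio(self):
        est = ng_estimate(CodonAlignment("a", "b", (("TTT", "TTA"), ("TTA", "TTG")) * 3))
        # force a concrete ratio check through the printed-table route
        assert ratio_from_table(0.18, 0.63) == 0.29

    @pytest.mark.parametrize(
        "ka,ks,expected", [(0.18, 0.63, 0.29), (0.69, 1.43, 0.48), (0.39, 2.86, 0.14)]
    )
    def test_printed_rows_reproduce(self, ka, ks, expected):
        assert ratio_from_table(ka, ks) == expected

    def test_half_up_rounding(self):
        assert ratio_from_table(0.25, 2.0) == 0.13  # 0.125 rounds up

    @pytest.mark.parametrize(
        "ratio,expected", [(0.29, "purifying"), (1.0, "neutral"), (1.2, "positive")]
    )
    def test_classify_selection_labels(self, ratio, expected):
        from zipperscan.kaks_ng import DivergenceEstimate

        est = DivergenceEstimate(
            s_sites=100.0,
            n_sites=200.0,
            sd=10.0,
            nd=10.0,
            ps=0.1,
            pn=0.05,
            ks=0.5,
            ka=0.5 * ratio,
            ratio=ratio,
            flags=frozenset({"ok"}),
        )
        assert classify_selection(est) == expected

    def test_flagged_estimate_undetermined(self):
        est = ng_estimate(CodonAlignment("a", "b", (("TTT", "TTT"),)))
        assert classify_selection(est) == "undetermined"


def _model(gene_id, chrom, start, end):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=1,
        exons=((start, end),),
        cds_spans=((start, end),),
        tss=start,
    )


class TestDuplication:
    def test_adjacent_same_chromosome_is_tandem(self):
        ev = classify_duplication(
            _model("a", "chr1", 1000, 2000), _model("b", "chr1", 10_000, 11_000)
        )
        assert ev.type == "tandem"

    def test_different_chromosomes_segmental(self):
        ev = classify_duplication(
            _model("a", "chr1", 1000, 2000), _model("b", "chr2", 1000, 2000)
        )
        assert ev.type == "segmental"

    def test_many_intervening_genes_segmental(self):
        a = _model("a", "chr1", 1000, 2000)
        b = _model("b", "chr1", 900_000, 901_000)
        between = [
            _model(f"x{i}", "chr1", 10_000 + 20_000 * i, 11_000 + 20_000 * i)
            for i in range(40)
        ]
        ev = classify_duplication(a, b, all_models=[a, b] + between)
        assert ev.intervening == 40
        assert ev.type == "segmental"
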