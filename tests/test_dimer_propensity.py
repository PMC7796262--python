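import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zipperscan.dimer_propensity import (
    classify_aa_pair,
    classify_ge_pair,
    group_pattern_table,
    homodimer_profile,
    position_frequencies,
)
from zipperscan.io_formats import FamilyCatalogEntry
from zipperscan.zipper_annotation import BasicRegionHit, Heptad, ZipperAnnotation

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def _ann(protein_id, heptad_residues):
    """Build an annotation from a list of letter->residue dicts."""
    heptads = tuple(Heptad(index=i, residues=r) for i, r in enumerate(heptad_residues))
    return ZipperAnnotation(
        protein_id=protein_id,
        basic_region=BasicRegionHit(n_pos=0, rk_pos=8, span=(0, 9)),
        anchor_pos=12,
        heptads=heptads,
        terminated_by="disruptor",
    )


def _full(d="L", a="A", e="A", g="A"):
    return {"a": a, "b": "A", "c": "A", "d": d, "e": e, "f": "A", "g": g}


class TestGePairs:
    @pytest.mark.parametrize(
        "g,e,expected",
        [
            ("E", "K", "attractive"),
            ("D", "R", "attractive"),
            ("E", "D", "repulsive"),
            ("K", "R", "repulsive"),
            ("E", "Q", "incomplete"),
            ("H", "E", "incomplete"),  # histidine counts as uncharged
            (None, "E", "incomplete"),
        ],
    )
    def test_rule_table(self, g, e, expected):
        assert classify_ge_pair(g, e) == expected

    @given(st.sampled_from(AMINO), st.sampled_from(AMINO))
    @settings(max_examples=100, derandomize=True)
    def test_symmetry(self, x, y):
        assert classify_ge_pair(x, y) == classify_ge_pair(y, x)


class TestAaPairs:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ("V", "V", "favorable"),
            ("I", "I", "favorable"),
            ("R", "R", "favorable"),
            ("N", "V", "hetero_favoring"),
            ("V", "N", "hetero_favoring"),
            ("N", "I", "destabilizing"),
            ("K", "E", "destabilizing"),
            ("D", "D", "destabilizing"),
            ("A", "S", "neutral"),
            ("L", "L", "neutral"),
            ("N", "N", "neutral"),
        ],
    )
    def test_rule_table(self, x, y, expected):
        assert classify_aa_pair(x, y) == expected


class TestPositionFrequencies:
    def test_all_leucine_d_gives_100(self):
        ann = _ann("p", [_full(), _full()])
        pf = position_frequencies([ann])
        assert pf.percentage("d", "L") == 100.0

    def test_counts_equal_recount_from_registers(self):
        heptads = [_full(d=d, a=a, g=g) for d, a, g in zip("LILVA", "NVAAM", "EKDAA")]
        ann = _ann("p", heptads)
        pf = position_frequencies([ann], window=(0, 4))
        # independent recount straight off the raw registers
        for letter in "adeg":
            for residue in set(h.residues[letter] for h in ann.heptads):
                expected = sum(1 for h in ann.heptads if h.residues[letter] == residue)
                assert pf.counts[letter].get(residue, 0) == expected

    def test_window_excludes_later_heptads(self):
        heptads = [_full(d="L")] * 5 + [_full(d="A")] * 3
        ann = _ann("p", heptads)
        assert position_frequencies([ann], window=(0, 4)).percentage("d", "L") == 100.0
        assert position_frequencies([ann], window=(0, 7)).percentage("d", "L") < 100.0

    def test_x_excluded_from_denominator(self):
        ann = _ann("p", [_full(d="X"), _full(d="L")])
        pf = position_frequencies([ann])
        assert pf.denominator("d") == 1
        assert pf.percentage("d", "L") == 100.0

    def test_complete_only_skips_truncated(self):
        ann = _ann("p", [_full(), {"d": "A"}])
        pf = position_frequencies([ann], complete_only=True)
        assert pf.counts["d"] == {"L": 1}

    def test_percentages_sum_to_100(self):
        heptads = [_full(d=d) for d in "LIVAK"]
        pf = position_frequencies([_ann("p", heptads)])
        assert sum(pf.percentages["d"].values()) == pytest.approx(100.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            position_frequencies([_ann("p", [_full()])], window=(3, 1))

    def test_rounding_within_half_unit(self):
        heptads = [_full(d="L")] * 2 + [_full(d="A")]  # 66.67%
        summary = position_frequencies([_ann("p", heptads)]).summary()
        assert summary["pct_leu_d"] == 67


class TestHomodimerProfile:
    def test_all_attractive(self):
        heptads = [_full(e="K", g="E") for _ in range(4)]
        profile = homodimer_profile(_ann("p", heptads))
        assert len(profile) == 3
        assert all(p.ge_class == "attractive" for p in profile)

    def test_all_repulsive(self):
        heptads = [_full(e="R", g="K") for _ in range(4)]
        profile = homodimer_profile(_ann("p", heptads))
        assert all(p.ge_class == "repulsive" for p in profile)

    def test_matches_explicit_contact_enumeration(self):
        import random

        rng = random.Random(5)
        heptads = [
            {letter: rng.choice(AMINO) for letter in "abcdefg"} for _ in range(4)
        ]
        ann = _ann("p", heptads)
        profile = homodimer_profile(ann)
        # enumerate the contacts by hand: g_k with e_{k+1}, a_k with a_k
        for k, assessment in enumerate(profile):
            assert assessment.ge_class == classify_ge_pair(
                heptads[k]["g"], heptads[k + 1]["e"]
            )
            assert assessment.aa_class == classify_aa_pair(
                heptads[k]["a"], heptads[k]["a"]
            )

    def test_single_heptad_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert homodimer_profile(_ann("p", [_full()])) == []


class TestGroupPatterns:
    def _catalog(self, names, group="A"):
        return [
            FamilyCatalogEntry(gene_name=n, locus_id=f"L{i}", group=group)
            for i, n in enumerate(names)
        ]

    def test_identical_zippers_modal_frequency_one(self):
        anns = [_ann(f"p{i}", [_full(e="K", g="E")] * 3) for i in range(5)]
        table = group_pattern_table(anns, self._catalog([a.protein_id for a in anns]))
        assert (table["frequency"] == 1.0).all()
        assert (table["modal_class"] == "attractive").all()

    def test_mixed_group_modal_frequency(self):
        attractive = [_ann(f"a{i}", [_full(e="K", g="E")] * 2) for i in range(3)]
        repulsive = [_ann(f"r{i}", [_full(e="K", g="K")] * 2) for i in range(2)]
        anns = attractive + repulsive
        table = group_pattern_table(anns, self._catalog([a.protein_id for a in anns]))
        row = table[table["heptad_index"] == 0].iloc[0]
        assert row["modal_class"] == "attractive"
        assert row["frequency"] == pytest.approx(0.6)

    def test_unknown_protein_rejected(self):
        ann = _ann("mystery", [_full()] * 2)
        with pytest.raises(ValueError, match="catalog"):
            group_pattern_table([ann], self._catalog(["other"]))
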