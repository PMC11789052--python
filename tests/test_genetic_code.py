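"""Codon tables, translation, permutations and Arg/Gly reassignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rg4rgg.genetic_code import (
    ALL_CODONS,
    SENSE_CODONS,
    CodonPermutation,
    CodonTable,
    Transcript,
    TranslationWarning,
    enumerate_arg_gly_assignments,
    guanine_content,
    recode,
    shuffle_codons,
    standard_table,
    translate,
)


class TestStandardTable:
    def test_structure(self):
        std = standard_table()
        sense = [c for c, aa in std.mapping.items() if aa != "*"]
        assert len(sense) == 61
        assert len(SENSE_CODONS) == 61
        assert std.codons_for("*") == ("TAA", "TAG", "TGA")

    def test_every_amino_acid_has_codons(self):
        deg = standard_table().degeneracy
        assert len(deg) == 20
        assert deg["R"] == 6 and deg["G"] == 4 and deg["M"] == 1 and deg["L"] == 6

    def test_matches_ncbi_table_one_spot_checks(self):
        std = standard_table()
        assert std.mapping["ATG"] == "M"
        assert std.mapping["TGG"] == "W"
        assert std.codons_for("G") == ("GGA", "GGC", "GGG", "GGT")


class TestTranslate:
    @pytest.mark.parametrize(
        "cds, expected",
        [
            ("CGGGGA", "RG"),
            ("ATGTAA", "M"),
            ("GGTGGCGGAGGG", "GGGG"),
            ("cgguga", "R"),  # RNA alphabet, lowercase, trailing stop
            ("ATGNNNTGG", "MXW"),  # N codon -> X
        ],
    )
    def test_examples(self, cds, expected):
        assert translate(cds) == expected

    def test_internal_stop_warns_and_keeps_placeholder(self):
        with pytest.warns(TranslationWarning):
            assert translate("ATGTAAATG") == "M*M"

    def test_non_triplet_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGA")


class TestGuanineContent:
    def test_arg_and_gly(self):
        std = standard_table()
        assert guanine_content(std, "R") == pytest.approx(8 / 18)
        assert guanine_content(std, "G") == pytest.approx(0.75)
        assert guanine_content(std, "M") == pytest.approx(1 / 3)

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            guanine_content(standard_table(), "B")

    def test_codon_weighted_mean_equals_pooled_g_fraction(self):
        # conservation: degeneracy-weighted mean over amino acids equals the
        # G fraction of the concatenated 61 sense codons
        std = standard_table()
        deg = std.degeneracy
        weighted = sum(guanine_content(std, aa) * deg[aa] for aa in deg) / 61
        pooled = "".join(SENSE_CODONS).count("G") / (3 * 61)
        assert weighted == pytest.approx(pooled)


class TestShuffle:
    def test_deterministic_and_bijective(self):
        p1, p2 = shuffle_codons(17), shuffle_codons(17)
        assert p1.mapping == p2.mapping
        assert sorted(p1.mapping.values()) == sorted(SENSE_CODONS)

    def test_degeneracy_profile_preserved_over_many_permutations(self):
        native = standard_table().degeneracy
        for seed in range(1000):
            assert shuffle_codons(seed).induced_table().degeneracy == native

    def test_identity_induces_native_table(self):
        ident = CodonPermutation.identity()
        assert ident.induced_table().mapping == standard_table().mapping

    def test_stop_codons_not_in_domain(self):
        p = shuffle_codons(3)
        assert "TAA" not in p.mapping and "TGA" not in p.mapping


class TestRecode:
    def test_identity_is_noop(self):
        cds = "ATGCGGGGATTTAAG"
        assert recode(cds, CodonPermutation.identity()) == cds

    def test_two_cycle(self):
        # sigma swapping AGA <-> CGG: recode replaces CGG by sigma^-1(CGG) = AGA
        mapping = {c: c for c in SENSE_CODONS}
        mapping["AGA"], mapping["CGG"] = "CGG", "AGA"
        perm = CodonPermutation(mapping=mapping)
        assert recode("CGGCGG", perm) == "AGAAGA"

    def test_trailing_stop_and_n_fixed(self):
        p = shuffle_codons(5)
        out = recode("ATGANNTAA", p)
        assert out[3:6] == "ANN" and out.endswith("TAA")

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=40),
    )
    def test_translate_recode_identity(self, seed, codons):
        """recode changes nucleotides but never the translated protein."""
        cds = "".join(codons)
        perm = shuffle_codons(seed)
        assert translate(recode(cds, perm), perm.induced_table()) == translate(cds)


class TestArgGlyAssignments:
    def test_count_and_flags(self):
        assignments = enumerate_arg_gly_assignments()
        assert len(assignments) == 380
        assert sum(a.native for a in assignments) == 1
        assert sum(a.gly_native for a in assignments) == 19

    def test_groups_are_indivisible(self):
        std = standard_table()
        for a in enumerate_arg_gly_assignments():
            assert a.table.codons_for("R") == std.codons_for(a.arg_source)
            assert a.table.codons_for("G") == std.codons_for(a.gly_source)

    def test_native_assignment_reproduces_rg_positions(self):
        native = next(a for a in enumerate_arg_gly_assignments() if a.native)
        cds = "CGGGGAATGTTT"
        full = translate(cds)
        reduced = translate(cds, native.table)
        assert [i for i, ch in enumerate(reduced) if ch in "RG"] == [
            i for i, ch in enumerate(full) if ch in "RG"
        ]


class TestCodonTableValidation:
    def test_wrong_stop_count_rejected(self):
        mapping = dict(standard_table().mapping)
        mapping["TAA"] = "K"
        with pytest.raises(ValueError):
            CodonTable(mapping=mapping)

    def test_missing_amino_acid_rejected_when_complete(self):
        mapping = dict(standard_table().mapping)
        mapping["ATG"] = "L"  # M loses its only codon
        with pytest.raises(ValueError):
            CodonTable(mapping=mapping)
        CodonTable(mapping=mapping, complete=False)  # relaxed mode accepts

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "code.tsv"
        standard_table().to_tsv(path)
        assert CodonTable.from_tsv(path).mapping == standard_table().mapping


class TestTranscript:
    def test_protein_and_spans(self):
        tx = Transcript(id="t", cds="ATGCGGTAA", utr5_flank="AAAA", utr3_flank="TT")
        assert tx.protein == "MR"
        assert tx.cds_span == (4, 13)
        assert tx.seq == "AAAAATGCGGTAATT"

    def test_flank_cap_enforced(self):
        with pytest.raises(ValueError):
            Transcript(id="t", cds="ATG", utr5_flank="A" * 51)
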