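"""Overlap classification and the descriptive statistics built on it."""

import numpy as np
import pandas as pd
import pytest

from rg4rgg.genetic_code import Transcript
from rg4rgg.overlap_stats import (
    classify_motif,
    composition,
    dataset_agreement,
    length_sweep,
    overlap_summary,
    profile_correlation,
    rg4_encoded_peptides,
)
from rg4rgg.rg4_detect import RG4Region
from rg4rgg.rgg_motifs import find_rgg_motifs

from conftest import oracle_consecutive_overlap


def motif_at(start, length):
    """A synthetic motif occupying protein residues [start, start+length)."""
    protein = "A" * start + "RG" * (length // 2) + ("G" if length % 2 else "")
    ms = find_rgg_motifs(protein)
    (m,) = [m for m in ms if m.start == start and m.length == length]
    return m


class TestClassify:
    def test_exact_cutoff_boundary(self):
        m = motif_at(10, 7)  # CDS interval [30, 51)
        rec = classify_motif(m, [(45, 60)])
        assert rec.max_single_overlap == 6 and rec.encoded

        rec = classify_motif(m, [(46, 60)])
        assert rec.max_single_overlap == 5 and not rec.encoded

    def test_disjoint_fragments_do_not_count_as_consecutive(self):
        m = motif_at(10, 7)  # CDS [30, 51)
        rec = classify_motif(m, [(30, 33), (40, 43)])
        assert rec.overlap_nt == 6
        assert rec.max_single_overlap == 3 and not rec.encoded

    def test_abutting_regions_merge_before_run_check(self):
        m = motif_at(10, 7)
        rec = classify_motif(m, [(30, 33), (33, 36)])
        assert rec.max_single_overlap == 6 and rec.encoded

    def test_flank_shift(self):
        m = motif_at(0, 4)  # CDS [0, 12); with 50-nt flank -> tx [50, 62)
        assert classify_motif(m, [(50, 62)], flank5=50).coverage == 1.0
        assert classify_motif(m, [(0, 12)], flank5=50).overlap_nt == 0

    def test_agrees_with_nucleotide_run_oracle(self, rng):
        """1,000 random motif/region instances against the marking oracle."""
        for _ in range(1000):
            start = int(rng.integers(0, 20))
            length = int(rng.integers(4, 30))
            m = motif_at(start, length)
            lo, hi = 3 * start, 3 * (start + length)
            n_regions = int(rng.integers(0, 5))
            ivs = []
            for _ in range(n_regions):
                s = int(rng.integers(max(0, lo - 30), hi + 30))
                ivs.append((s, s + int(rng.integers(1, 40))))
            cutoff = int(rng.integers(1, 13))
            rec = classify_motif(m, ivs, cutoff=cutoff)
            exp_enc, exp_nt, _ = oracle_consecutive_overlap((lo, hi), ivs, cutoff)
            assert rec.encoded == exp_enc
            assert rec.overlap_nt == exp_nt

    def test_increasing_cutoff_monotone(self, rng):
        for _ in range(50):
            m = motif_at(0, int(rng.integers(4, 20)))
            ivs = [(int(s), int(s) + int(l)) for s, l in
                   zip(rng.integers(0, 40, 3), rng.integers(1, 25, 3))]
            encoded = [classify_motif(m, ivs, cutoff=c).encoded for c in range(1, 15)]
            # once not encoded at some cutoff, never encoded at a larger one
            assert all(a or not b for a, b in zip(encoded, encoded[1:]))


class TestSummaryAndSweep:
    def make_records(self):
        m1, m2, m3 = motif_at(0, 4), motif_at(0, 10), motif_at(0, 20)
        return [
            classify_motif(m1, [(0, 12)]),  # fully covered
            classify_motif(m2, [(0, 15)]),  # half covered
            classify_motif(m3, []),  # not encoded
        ]

    def test_summary(self):
        recs = self.make_records()
        s = overlap_summary(recs)
        assert s["n_motifs"] == 3 and s["n_encoded"] == 2
        assert s["pct_encoded"] == pytest.approx(200 / 3)
        assert s["mean_coverage"] == pytest.approx((1.0 + 0.5) / 2)
        assert s["mean_overlap_nt"] == pytest.approx((12 + 15) / 2)

    def test_summary_no_encoded(self):
        recs = [classify_motif(motif_at(0, 6), [])]
        s = overlap_summary(recs)
        assert s["pct_encoded"] == 0.0 and s["mean_coverage"] is None

    def test_length_sweep(self):
        recs = self.make_records()
        df = length_sweep(recs, [0, 5, 15, 99])
        assert df.loc[0, "pct_encoded"] == pytest.approx(200 / 3)
        assert df.loc[1, "n_motifs"] == 2  # lengths 10 and 20
        assert df.loc[1, "pct_encoded"] == pytest.approx(50.0)
        assert df.loc[3, "n_motifs"] == 0 and np.isnan(df.loc[3, "pct_encoded"])


class TestComposition:
    def tx(self, tx_id, cds):
        return Transcript(id=tx_id, cds=cds)

    def test_all_g_interval(self):
        txs = {"t": self.tx("t", "GGGGGGTAA")}
        df = composition({"t": [(0, 6)]}, txs)
        assert df.loc["G", "mean"] == 1.0

    def test_counts_and_row_sum(self):
        # RGG RGG back-translated G-rich: CGG GGA GGG CGG GGA GGG
        cds = "CGGGGAGGGCGGGGAGGG"
        txs = {"t": self.tx("t", cds)}
        df = composition({"t": [(0, 18)]}, txs)
        assert df.loc["G", "mean"] == pytest.approx(cds.count("G") / 18)
        assert df["mean"].sum() == pytest.approx(1.0)

    def test_per_gene_vs_pooled_agree_on_identical_content(self):
        txs = {f"t{i}": self.tx(f"t{i}", "GGCATT") for i in range(3)}
        ivs = {k: [(0, 6)] for k in txs}
        pg = composition(ivs, txs, per_gene=True)
        pooled = composition(ivs, txs, per_gene=False)
        assert np.allclose(pg["mean"], pooled["mean"])
        assert np.allclose(pg["sd"], 0.0)

    def test_order_invariance(self):
        txs = {"a": self.tx("a", "GGGTTT"), "b": self.tx("b", "AAACCC")}
        ivs1 = {"a": [(0, 6)], "b": [(0, 6)]}
        ivs2 = {"b": [(0, 6)], "a": [(0, 6)]}
        assert composition(ivs1, txs)["mean"].equals(composition(ivs2, txs)["mean"])


class TestAgreement:
    def regions(self, label, ivs, tx="t"):
        return [RG4Region(tx, s, e, label) for s, e in ivs]

    def test_identical_and_disjoint(self):
        sets = {
            "a": self.regions("a", [(0, 10)]),
            "b": self.regions("b", [(0, 10)]),
            "c": self.regions("c", [(50, 60)]),
        }
        df = dataset_agreement(sets).set_index(["source_a", "source_b"])
        assert df.loc[("a", "b"), "jaccard"] == 1.0
        assert df.loc[("a", "c"), "jaccard"] == 0.0

    def test_partial_overlap_value(self):
        sets = {"a": self.regions("a", [(0, 10)]), "b": self.regions("b", [(5, 15)])}
        df = dataset_agreement(sets)
        assert df.loc[0, "jaccard"] == pytest.approx(5 / 15)
        assert df.loc[0, "frac_a_in_b"] == pytest.approx(0.5)

    def test_restriction_increases_focused_agreement(self):
        # both datasets agree inside the mask, disagree outside
        sets = {
            "a": self.regions("a", [(0, 10), (100, 140)]),
            "b": self.regions("b", [(0, 10), (200, 240)]),
        }
        full = dataset_agreement(sets).loc[0, "jaccard"]
        masked = dataset_agreement(sets, restrict_to={"t": [(0, 10)]}).loc[0, "jaccard"]
        assert masked == 1.0 and masked > full


class TestEncodedPeptides:
    def test_in_frame_region(self):
        tx = Transcript(id="t", cds="GGAGGAGGATAA")
        aa, tri = rg4_encoded_peptides([RG4Region("t", 0, 9, "x")], {"t": tx})
        assert aa.to_dict() == {"G": 3}
        assert tri.to_dict() == {"GGG": 1}

    def test_partial_codons_trimmed(self):
        tx = Transcript(id="t", cds="GGAGGAGGATAA")
        # region [1, 8) covers only codon 2 fully
        aa, tri = rg4_encoded_peptides([RG4Region("t", 1, 8, "x")], {"t": tx})
        assert aa.to_dict() == {"G": 1} and tri.empty

    def test_too_short_region_contributes_nothing(self):
        tx = Transcript(id="t", cds="GGAGGAGGATAA")
        aa, tri = rg4_encoded_peptides([RG4Region("t", 1, 3, "x")], {"t": tx})
        assert aa.empty and tri.empty

    def test_flank_offset_respected(self):
        tx = Transcript(id="t", cds="ATGCGGTAA", utr5_flank="A" * 10)
        aa, _ = rg4_encoded_peptides([RG4Region("t", 10, 16, "x")], {"t": tx})
        assert aa.to_dict() == {"M": 1, "R": 1}


class TestProfileCorrelation:
    SCALE = {aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}

    def test_constant_profiles_undefined(self):
        tx = Transcript(id="t", cds="GCA" * 30)
        out = profile_correlation(tx.cds, tx.protein, self.SCALE)
        assert out["pearson_r"] is None

    def test_perfect_anticorrelation(self):
        # scale = -(G count of the residue's codons): preference profile is
        # exactly -1 x density profile
        protein = "GGGGAAAAGGGGAAAA" * 3
        cds = "".join({"G": "GGG", "A": "GCA"}[aa] for aa in protein)
        scale = dict(self.SCALE, G=-3.0, A=-1.0)
        out = profile_correlation(cds, protein, scale, window=5)
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_random_profiles_near_zero(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        protein = "".join(rng.choice(aas, size=4000))
        cds = "".join("GGG" if rng.random() < 0.3 else "ACT" for _ in protein)
        scale = {aa: float(rng.normal()) for aa in aas}
        out = profile_correlation(cds, protein, scale, window=21)
        assert abs(out["pearson_r"]) < 0.15

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation("GGGAAA", "GA", self.SCALE, window=4)
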