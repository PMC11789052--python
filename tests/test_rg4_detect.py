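"""G4Hunter and QGRS predictors, RT-stop expansion, consensus, BED ingestion."""

import numpy as np
import pytest

from rg4rgg.intervals import merge_intervals
from rg4rgg.rg4_detect import (
    RG4Region,
    consensus_regions,
    g4hunter_profile,
    g4hunter_regions,
    ingest_bed,
    merge_regions,
    qgrs_gscore,
    qgrs_scan,
    rtstop_to_regions,
    write_bed,
    _qgrs_candidates,
)


def random_seq(rng, n, p_g=0.25):
    probs = [(1 - p_g) / 3] * 3 + [p_g]
    return "".join(rng.choice(list("ACTG"), size=n, p=probs))


class TestG4HunterProfile:
    def test_single_runs(self):
        assert g4hunter_profile("GC").tolist() == [1, -1]

    def test_run_capping(self):
        assert g4hunter_profile("GGGG").tolist() == [4, 4, 4, 4]
        assert g4hunter_profile("G" * 7).tolist() == [4] * 7
        assert g4hunter_profile("CCCCC").tolist() == [-4] * 5

    def test_telomeric_hand_computation(self):
        # 4 G-runs of length 3: 12 guanines scoring 3 each = 36 over 21 nt
        prof = g4hunter_profile("GGGTTAGGGTTAGGGTTAGGG")
        assert prof.sum() == 36
        assert prof.sum() / 21 == pytest.approx(36 / 21)

    def test_reverse_complement_antisymmetry(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(25):
            s = random_seq(rng, 80)
            rc = s.translate(comp)[::-1]
            assert g4hunter_profile(rc).sum() == -g4hunter_profile(s).sum()


class TestG4HunterRegions:
    def test_pure_g_window(self):
        (r,) = g4hunter_regions("G" * 25, window=25)
        assert (r.start, r.end) == (0, 25)
        assert r.score == pytest.approx(4.0)

    def test_all_a_empty(self):
        assert g4hunter_regions("A" * 100) == []

    def test_telomeric_region(self):
        regs = g4hunter_regions("GGGTTAGGGTTAGGGTTAGGG", window=21)
        assert len(regs) == 1
        assert regs[0].score >= 1.2

    def test_short_sequence_single_window(self):
        assert len(g4hunter_regions("G" * 10, window=25)) == 1

    def test_regions_trimmed_to_g(self, rng):
        for _ in range(20):
            s = random_seq(rng, 200, p_g=0.5)
            for r in g4hunter_regions(s):
                assert s[r.start] == "G" and s[r.end - 1] == "G"

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold only shrinks the covered nucleotide set."""
        for _ in range(15):
            s = random_seq(rng, 300, p_g=0.45)
            lo = g4hunter_regions(s, threshold=1.2)
            hi = g4hunter_regions(s, threshold=1.6)
            lo_nt = {p for r in lo for p in range(r.start, r.end)}
            hi_nt = {p for r in hi for p in range(r.start, r.end)}
            assert hi_nt <= lo_nt


class TestQgrs:
    def test_all_a_empty(self):
        assert qgrs_scan("A" * 60) == []

    def test_tetrad_monotonicity(self):
        s3 = qgrs_scan("GGGAGGGAGGGAGGG")[0].score
        s2 = qgrs_scan("GGAGGAGGAGG")[0].score
        assert s3 > s2

    def test_even_loops_beat_uneven(self):
        # exhaustive check of the scoring axiom over all loop splits <= 30 nt
        for total in range(3, 19):
            balanced = [total // 3] * 3
            for i in range(total % 3):
                balanced[i] += 1
            base = qgrs_gscore(2, tuple(balanced))
            for l1 in range(total + 1):
                for l2 in range(total - l1 + 1):
                    l3 = total - l1 - l2
                    assert qgrs_gscore(2, (l1, l2, l3)) <= base + 1e-9

    def test_shorter_loops_score_higher(self):
        assert qgrs_gscore(3, (1, 1, 1)) > qgrs_gscore(3, (2, 2, 2))

    def test_at_most_one_zero_loop(self):
        # G8 cannot be split into 4 tracts with >= 2 zero loops
        cands = _qgrs_candidates("GGGGGGGG", max_len=30, min_tract=2)
        assert cands == []

    def test_overlap_resolution_non_overlapping(self, rng):
        for _ in range(10):
            s = random_seq(rng, 200, p_g=0.5)
            regs = qgrs_scan(s)
            for a, b in zip(regs, regs[1:]):
                assert a.end <= b.start

    def test_matches_bruteforce_enumeration(self, rng):
        """Candidate set equals an independent window-by-window enumerator."""

        def brute(seq, max_len=20, min_tract=2):
            out = set()
            n = len(seq)
            for s in range(n):
                for e in range(s + 4 * min_tract, min(n, s + max_len) + 1):
                    w = seq[s:e]
                    for x in range(min_tract, len(w) // 4 + 1):
                        if not (w[:x] == "G" * x and w[-x:] == "G" * x):
                            continue
                        inner = range(s + x, e - 2 * x + 1)
                        for s2 in inner:
                            if seq[s2 : s2 + x] != "G" * x:
                                continue
                            for s3 in range(s2 + x, e - 2 * x + 1):
                                if seq[s3 : s3 + x] != "G" * x:
                                    continue
                                l1 = s2 - (s + x)
                                l2 = s3 - (s2 + x)
                                l3 = (e - x) - (s3 + x)
                                if l3 < 0 or (l1 == 0) + (l2 == 0) + (l3 == 0) > 1:
                                    continue
                                out.add((qgrs_gscore(x, (l1, l2, l3)), s, e, x))
            return out

        for _ in range(4):
            s = random_seq(rng, 70, p_g=0.45)
            assert set(_qgrs_candidates(s, 20, 2)) == brute(s)


class TestRtStops:
    def test_expansion_and_clamp(self):
        assert rtstop_to_regions([100], 500)[0].interval == (40, 100)
        assert rtstop_to_regions([30], 500)[0].interval == (0, 30)

    def test_merge(self):
        (r,) = rtstop_to_regions([100, 130], 500)
        assert r.interval == (40, 130)

    def test_out_of_bounds_skipped(self):
        with pytest.warns(UserWarning):
            assert rtstop_to_regions([600], 500) == []


class TestConsensus:
    def make(self, ivs, tx="t"):
        return [RG4Region(tx, s, e, "s") for s, e in ivs]

    def test_kept_when_supported(self):
        per = [self.make([(10, 30)]), self.make([(10, 30)]), [], []]
        (r,) = consensus_regions(per, min_samples=2)
        assert r.interval == (10, 30)

    def test_dropped_when_single_sample(self):
        per = [self.make([(10, 30)]), [], [], []]
        assert consensus_regions(per, min_samples=2) == []

    def test_staggered_positionwise(self):
        per = [self.make([(0, 10)]), self.make([(5, 15)])]
        (r,) = consensus_regions(per, min_samples=2)
        assert r.interval == (5, 10)

    def test_order_invariant(self, rng):
        per = [
            self.make([(0, 20), (40, 60)]),
            self.make([(10, 50)]),
            self.make([(15, 45)]),
        ]
        a = [r.interval for r in consensus_regions(per, 2)]
        b = [r.interval for r in consensus_regions(per[::-1], 2)]
        assert a == b


class TestMergeAndBed:
    def test_merge_idempotent_and_order_invariant(self, rng):
        regions = [
            RG4Region("t", int(s), int(s) + int(l), "x")
            for s, l in zip(rng.integers(0, 200, 30), rng.integers(1, 40, 30))
        ]
        merged = merge_regions(regions)
        assert merge_regions(merged) == merged
        assert merge_regions(regions[::-1]) == merged

    def test_ingest_merge_and_label(self, tmp_path):
        p = tmp_path / "calls.bed"
        p.write_text("tx1\t40\t100\ntx1\t90\t120\ntx2\t0\t10\n")
        regions = ingest_bed(p, "exp")
        assert [(r.transcript_id, r.start, r.end) for r in regions] == [
            ("tx1", 40, 120),
            ("tx2", 0, 10),
        ]
        assert all(r.source == "exp" for r in regions)

    @pytest.mark.parametrize(
        "line", ["tx1\t-5\t10", "tx1\t10\t10", "tx1\tten\t20", "tx1\t5"]
    )
    def test_malformed_lines_rejected_with_lineno(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("tx0\t0\t5\n" + line + "\n")
        with pytest.raises(ValueError, match=":2"):
            ingest_bed(p, "exp")

    def test_write_read_round_trip(self, tmp_path):
        regions = [RG4Region("tx1", 5, 25, "exp", 2.0), RG4Region("tx2", 0, 9, "exp")]
        p = tmp_path / "out.bed"
        write_bed(regions, p)
        back = ingest_bed(p, "exp")
        assert [r.interval for r in back] == [(5, 25), (0, 9)]
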