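"""Repeat detection, per-read assessment, deviation and attribution."""
import numpy as np
import pytest

from _util import (
    make_read,
    oracle_heteropolymers,
    oracle_homopolymers,
    oracle_trinucleotides,
)
from poreprof import low_complexity as lc
from poreprof.align_io import ReferenceGenome


def occ_set(seq, kind):
    return {
        (o.motif, o.start, o.end, o.copies) for o in lc.find_repeats(seq, kind)
    }


class TestFindRepeats:
    def test_homopolymer_example(self):
        assert occ_set("AATTTC", "homopolymer") == {("A", 0, 2, 2), ("T", 2, 5, 3)}

    def test_heteropolymer_example(self):
        assert occ_set("ACACAC", "heteropolymer") == {("AC", 0, 6, 3)}

    def test_heteropolymer_trailing_odd_base_excluded(self):
        assert occ_set("ACACA", "heteropolymer") == {("AC", 0, 4, 2)}

    def test_heteropolymer_pooling_case(self):
        # ACACCA: only the leading AC x2 is a maximal alternating stretch
        assert occ_set("ACACCA", "heteropolymer") == {("AC", 0, 4, 2)}

    def test_homopolymer_runs_are_not_trinucleotide_repeats(self):
        assert occ_set("AAAAAA", "trinucleotide") == set()

    def test_trinucleotide_phases_all_reported(self):
        got = occ_set("ACGACGACGA", "trinucleotide")
        assert ("ACG", 0, 9, 3) in got
        assert ("CGA", 1, 10, 3) in got
        assert ("GAC", 2, 8, 2) in got

    def test_trinucleotide_with_repeated_first_bases_allowed(self):
        # X=Y => Y!=Z allows units like AAT
        assert ("AAT", 0, 6, 2) in occ_set("AATAAT", "trinucleotide")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            lc.find_repeats("ACGT", "dinucleotide")

    def test_oracle_equivalence_quick(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            assert occ_set(s, "homopolymer") == oracle_homopolymers(s)
            assert occ_set(s, "heteropolymer") == oracle_heteropolymers(s)
            assert occ_set(s, "trinucleotide") == oracle_trinucleotides(s)

    def test_maximality_no_adjacent_same_motif(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            s = "".join("ACGT"[i] for i in rng.integers(0, 3, 80))
            occ = lc.find_repeats(s, "homopolymer", as_frame=True)
            occ = occ.sort_values("start")
            prev_end = {}
            for row in occ.itertuples(index=False):
                assert row.start >= prev_end.get(row.motif, -1)
                prev_end[row.motif] = row.end + 1  # adjacency would extend the run


class TestClassify:
    @pytest.mark.parametrize(
        "motif,group",
        [("ATT", "W-only"), ("GCG", "S-only"), ("ACG", "mostly-S"), ("TAG", "mostly-W")],
    )
    def test_groups(self, motif, group):
        assert lc.classify_trinucleotide(motif) == group

    def test_w_only_set_is_complete(self):
        w_only = {
            m
            for m in ("AAT", "ATA", "TAA", "ATT", "TAT", "TTA")
        }
        assert all(lc.classify_trinucleotide(m) == "W-only" for m in w_only)

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            lc.classify_trinucleotide("AXT")


class TestDistribution:
    def test_small_example_counts(self):
        dist = lc.repeat_length_distribution(ReferenceGenome("g", "AATTTC"), "homopolymer")
        got = {(r.motif_class, r.length): r.count for r in dist.itertuples(index=False)}
        assert got == {("A", 2): 1, ("T", 3): 1}

    def test_symmetric_dinucleotides_pooled(self):
        ref = ReferenceGenome("g", "ACACTTGCACA")
        dist = lc.repeat_length_distribution(ref, "heteropolymer")
        assert set(dist["motif_class"]) <= {"AC"}  # CA pools into AC

    def test_homopolymer_counts_decay_geometrically(self):
        rng = np.random.default_rng(29)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 200_000))
        dist = lc.repeat_length_distribution(s, "homopolymer")
        total = dist.groupby("length")["count"].sum()
        for length in (2, 3, 4):
            ratio = total[length] / total[length + 1]
            assert 3.0 < ratio < 5.5  # ~4 for uniform i.i.d. bases


class TestAssessment:
    def test_exact_rendering_is_correct(self):
        occ = lc.RepeatOccurrence("homopolymer", "T", 1, 4, 3)
        read = make_read("ATTTG", "ATTTG")
        a = lc.assess_repeat(read, occ)
        assert a.correct and a.observed_length == 3

    def test_deleted_base_underestimates_length(self):
        occ = lc.RepeatOccurrence("homopolymer", "A", 1, 5, 4)
        read = make_read("CAAAAG", "CAA-AG")
        a = lc.assess_repeat(read, occ)
        assert not a.correct
        assert a.observed_length == 3
        assert a.deletions == 1

    def test_insertions_overestimate_length(self):
        occ = lc.RepeatOccurrence("homopolymer", "A", 1, 3, 2)
        read = make_read("CAA---G", "CAAAAAG")
        a = lc.assess_repeat(read, occ)
        assert not a.correct
        assert a.observed_length == 5

    def test_partial_overlap_skipped(self):
        occ = lc.RepeatOccurrence("homopolymer", "A", 3, 8, 5)
        read = make_read("CAAA", "CAAA")  # covers [0, 4) only
        assert lc.assess_repeat(read, occ) is None

    def test_adjacent_same_base_extension_counts(self):
        # substitution next to the run extends the observed run
        occ = lc.RepeatOccurrence("homopolymer", "A", 1, 3, 2)
        read = make_read("CAAG", "AAAG")
        a = lc.assess_repeat(read, occ)
        assert a.observed_length == 3
        assert not a.correct

    def test_heteropolymer_exact_match_rule(self):
        occ = lc.RepeatOccurrence("heteropolymer", "AC", 1, 7, 3)
        good = make_read("TACACACG", "TACACACG")
        assert lc.assess_repeat(good, occ).correct
        bad = make_read("TACACACG", "TACAC-CG")
        b = lc.assess_repeat(bad, occ)
        assert not b.correct
        assert b.observed_length == 4  # ACAC then the broken tail

    def test_trinucleotide_assessment(self):
        occ = lc.RepeatOccurrence("trinucleotide", "ACG", 1, 7, 2)
        read = make_read("TACGACGT", "TACGACGT")
        a = lc.assess_repeat(read, occ)
        assert a.correct and a.observed_length == 6


class TestAggregations:
    def _assessments(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ref_length": [2, 2, 2, 3, 3, 6, 6],
                "observed_length": [2, 2, 3, 3, 3, 5, 5],
                "correct": [True, True, False, True, True, False, False],
                "motif": list("AATTTCC"),
            }
        )

    def test_accuracy_by_length(self):
        acc = lc.repeat_accuracy_by_length(self._assessments())
        by_len = dict(zip(acc["ref_length"], acc["accuracy"]))
        assert by_len[2] == pytest.approx(2 / 3)
        assert by_len[3] == 1.0
        assert by_len[6] == 0.0

    def test_min_count_suppression(self):
        acc = lc.repeat_accuracy_by_length(self._assessments(), min_count=3)
        assert acc["ref_length"].tolist() == [2]

    def test_deviation_profile_median_bias(self):
        dev = lc.length_deviation_profile(self._assessments())
        row = dev[dev["ref_length"] == 6].iloc[0]
        assert row["median"] == -1
        row2 = dev[dev["ref_length"] == 3].iloc[0]
        assert row2["median"] == 0 and row2["min"] == 0 and row2["max"] == 0


class TestAttribution:
    def test_all_errors_inside_gives_hundred_percent(self):
        ref = ReferenceGenome("g", "CAAAAG")
        read = make_read("CAAAAG", "CAACAG")  # one mismatch inside the A-run
        att = lc.attribute_errors_to_homopolymers([read], ref)
        assert att.ratio_percent("global") == pytest.approx(100.0)

    def test_half_inside(self):
        ref = ReferenceGenome("g", "CAAAAGTC")
        # one mismatch inside the run, one outside
        read = make_read("CAAAAGTC", "CACAAGTG")
        att = lc.attribute_errors_to_homopolymers([read], ref)
        assert att.a_mismatches == 2 and att.h_mismatches == 1
        assert att.ratio_percent("mismatches") == pytest.approx(50.0)

    def test_boundary_insertion_attributed(self):
        ref = ReferenceGenome("g", "CAAG")
        # insertion anchored at the base just before the run
        read = make_read("C-AAG", "CTAAG")
        att = lc.attribute_errors_to_homopolymers([read], ref)
        assert att.h_insertions == 1

    def test_conservation(self):
        rng = np.random.default_rng(31)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        ref = ReferenceGenome("g", seq)
        # mutate every 10th base
        read = list(seq)
        for i in range(0, 500, 10):
            read[i] = "ACGT"[("ACGT".index(read[i]) + 1) % 4]
        r = make_read(seq, "".join(read))
        att = lc.attribute_errors_to_homopolymers([r], ref)
        assert 0 <= att.h_mismatches <= att.a_mismatches
        assert att.a_mismatches == 50
        assert att.h_global == att.h_mismatches + att.h_insertions + att.h_deletions
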