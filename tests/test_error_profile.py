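"""Error decomposition, substitution bias, windows, GC and region analyses."""
import numpy as np
import pandas as pd
import pytest

from _util import make_read, random_alignment
from poreprof import error_profile as ep
from poreprof.align_io import ReferenceGenome, reverse_complement
from poreprof.synthetic import ErrorModelSpec, generate_reference, simulate_reads
from poreprof.align_io import load_run

GENOME = "ACGTCATTGC"
READ = "GCCAAGACCT"


@pytest.fixture
def worked_example():
    """The read aligned to the reverse-complemented genome, unchanged."""
    return make_read(reverse_complement(GENOME), READ, orientation="reverse")


class TestDecompose:
    def test_worked_example_thirty_percent(self, worked_example):
        c = ep.decompose_errors(worked_example)
        assert (c.mismatches, c.insertions, c.deletions) == (3, 0, 0)
        assert c.global_error_rate == pytest.approx(0.30)

    def test_identical_alignment_has_zero_rates(self):
        c = ep.decompose_errors(make_read("ACGTA" * 10, "ACGTA" * 10))
        assert c.global_error_rate == 0.0
        assert c.matches == 50

    def test_enumerated_columns(self):
        # (A,A)(GAP,C)(T,GAP)(G,G) -> 1 insertion, 1 deletion, global 0.5
        c = ep.decompose_errors(make_read("A-TG", "AC-G"))
        assert (c.insertions, c.deletions, c.mismatches) == (1, 1, 0)
        assert c.global_error_rate == pytest.approx(0.5)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            ep.decompose_errors(make_read("", ""))

    def test_n_columns_are_neither_match_nor_mismatch_errors(self):
        c = ep.decompose_errors(make_read("ANGT", "ATGT"))
        assert c.mismatches == 0  # N pairing carries no base identity
        assert c.alignment_length == 4

    def test_conservation_pooled_equals_sum(self):
        rng = np.random.default_rng(5)
        reads = [random_alignment(rng) for _ in range(30)]
        pooled = ep.pooled_errors(reads)
        per = [ep.decompose_errors(r) for r in reads]
        assert pooled.mismatches == sum(c.mismatches for c in per)
        assert pooled.alignment_length == sum(c.alignment_length for c in per)


class TestSubstitutionMatrix:
    def test_worked_example_labels(self, worked_example):
        mat = ep.substitution_matrix([worked_example])["all"]
        # genome-base/read-base labels in sequencing orientation
        assert mat.loc["A", "C"] == 1
        assert mat.loc["T", "A"] == 1
        assert mat.loc["G", "C"] == 1
        assert mat.values.sum() == 3
        # and NOT the rev(R)-vs-G labels
        assert mat.loc["C", "G"] == 0
        assert mat.loc["A", "T"] == 0
        assert mat.loc["T", "G"] == 0

    def test_no_mismatches_empty_matrix(self):
        mat = ep.substitution_matrix([make_read("ACGT", "ACGT")])["all"]
        assert mat.values.sum() == 0

    def test_relative_abundance_sums_to_one(self, worked_example):
        rel = ep.relative_substitution_abundance(
            ep.substitution_matrix([worked_example])["all"]
        )
        assert rel.values.sum() == pytest.approx(1.0)

    def test_modification_stratification(self):
        # one C->T mismatch whose read base carries a 5mC call
        r = make_read("ACGTC", "ATGTC", read_id="r1")
        calls = pd.DataFrame(
            [{"read_id": "r1", "read_pos": 1, "mod_type": "5mC"}]
        )
        mats = ep.substitution_matrix([r], calls)
        assert mats["modified:5mC"].loc["C", "T"] == 1
        assert mats["unmodified"].values.sum() == 0
        assert mats["all"].loc["C", "T"] == 1

    def test_call_beyond_read_length_rejected(self):
        r = make_read("ACGT", "ATGT", read_id="r1")
        calls = pd.DataFrame([{"read_id": "r1", "read_pos": 99, "mod_type": "5mC"}])
        with pytest.raises(ValueError, match="beyond read length"):
            ep.substitution_matrix([r], calls)


def _read_with_substitutions(rng, n_sub, transition_weight):
    """A small alignment whose substitutions follow a given transition bias."""
    bases = "ACGT"
    partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    ref, read = [], []
    for _ in range(n_sub):
        b = bases[rng.integers(4)]
        if rng.random() < transition_weight:
            t = partner[b]
        else:
            t = tv[b][rng.integers(2)]
        ref.append(b)
        read.append(t)
    for _ in range(10):
        b = bases[rng.integers(4)]
        ref.append(b)
        read.append(b)
    return make_read("".join(ref), "".join(read))


class TestTransitionTest:
    def test_biased_simulation_is_significant(self):
        rng = np.random.default_rng(11)
        # transition 4x more likely than each transversion: weight 4/(4+2)
        reads = [_read_with_substitutions(rng, 5, 4 / 6) for _ in range(500)]
        for res in ep.transition_transversion_test(reads):
            assert not res.flagged
            assert res.pvalue < 0.01
            assert res.statistic > 0

    def test_uniform_null_is_rarely_significant(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 200
        for _ in range(reps):
            # uniform over the 12 pairs: transition weight 2/6 per base
            reads = [_read_with_substitutions(rng, 4, 2 / 6) for _ in range(40)]
            res = ep.transition_transversion_test(reads)[0]
            if res.pvalue < 0.01:
                hits += 1
        assert hits <= 0.05 * reps

    def test_single_read_flagged(self):
        res = ep.transition_transversion_test([make_read("A", "G")])
        assert all(r.flagged and r.pvalue is None for r in res)


class TestGenomeWindows:
    def test_window_arithmetic(self):
        ref = ReferenceGenome("g", "A" * 1000)
        prof = ep.genome_window_error([], ref, 0.01)
        assert len(prof) == 100
        assert (prof["window_end"] - prof["window_start"]).unique().tolist() == [10]

    def test_uncovered_window_is_missing(self):
        ref = ReferenceGenome("g", "ACGT" * 25)
        r = make_read("ACGT" * 5, "ACGT" * 5, ref_start=0)
        prof = ep.genome_window_error([r], ref, 0.25)
        assert prof["mismatch_rate"].notna().tolist() == [True, False, False, False]

    def test_uniform_deletion_rate_recovered_per_window(self, tmp_path):
        model = ErrorModelSpec(
            substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.02,
            gc_error_slope=0.0, read_rate_sigma=0.0, base_rate_jitter=0.0,
            repeat_override=False, seed=21,
        )
        ref = generate_reference(50_000, 0.5, seed=21)
        run = simulate_reads(
            ref, model, tmp_path, coverage=8, read_length_median=4000, seed=21
        )
        bundle = load_run(
            run.paths["reference"], run.paths["forward_sam"], run.paths["reverse_sam"]
        )
        prof = ep.genome_window_error(bundle.reads, bundle.reference, 0.01)
        # genome edges are under-covered by uniform read starts; check the
        # well-supported windows
        good = prof[prof["columns"] >= 500]
        assert len(good) >= 80
        se = np.sqrt(0.02 * 0.98 / good["columns"])
        z = np.abs(good["deletion_rate"] - 0.02) / se
        # 3-sigma per window with ~95 windows: allow the expected binomial
        # tail across windows, and bound every window at 5 sigma
        assert (z <= 3).mean() >= 0.97
        assert (z <= 5).all()


class TestGcAnalyses:
    def test_single_bin_when_all_reads_same_gc(self):
        reads = [make_read("ACGT" * 5, "ACGT" * 5) for _ in range(3)]
        out = ep.error_vs_gc(reads)
        assert out["gc_percent"].tolist() == [50]
        assert out["n_reads"].tolist() == [3]

    def test_min_support_suppresses_bin(self):
        reads = [make_read("ACGT" * 5, "ACGT" * 5, read_id=f"r{i}") for i in range(99)]
        assert ep.error_vs_gc(reads, min_support=100).empty
        assert len(ep.error_vs_gc(reads, min_support=99)) == 1

    def test_gc_slope_sign_and_magnitude_recovered(self, tmp_path):
        model = ErrorModelSpec(
            gc_error_slope=0.0004, read_rate_sigma=0.05, base_rate_jitter=0.0,
            repeat_override=False, seed=31,
        )
        ref = generate_reference(400_000, 0.5, gc_block_sd=0.10, seed=31)
        run = simulate_reads(
            ref, model, tmp_path, n_reads=4000, read_length_median=1500,
            read_length_range=(800, 4000), seed=31,
        )
        bundle = load_run(
            run.paths["reference"], run.paths["forward_sam"], run.paths["reverse_sam"]
        )
        out = ep.error_vs_gc(bundle.reads, min_support=30)
        sel = out[(out["gc_percent"] >= 30) & (out["gc_percent"] <= 70)]
        slope = np.polyfit(
            sel["gc_percent"], sel["global"], 1, w=np.sqrt(sel["n_reads"])
        )[0]
        assert slope == pytest.approx(0.0004, rel=0.25)

    def test_relative_coverage_uniform_near_one(self, tmp_path):
        model = ErrorModelSpec(repeat_override=False, seed=41)
        ref = generate_reference(200_000, 0.5, seed=41)
        run = simulate_reads(
            ref, model, tmp_path, coverage=10, read_length_median=5000, seed=41
        )
        bundle = load_run(
            run.paths["reference"], run.paths["forward_sam"], run.paths["reverse_sam"]
        )
        cov = ep.relative_coverage_by_gc(
            bundle.reads, bundle.reference, window=100, min_windows=50
        )
        assert len(cov) >= 3
        # unbiased expectation line is 1.0
        assert np.average(cov["relative_coverage"], weights=cov["n_windows"]) == (
            pytest.approx(1.0, abs=0.05)
        )
        assert (np.abs(cov["relative_coverage"] - 1.0) < 0.35).all()

    def test_no_reads_relative_coverage_undefined(self):
        ref = ReferenceGenome("g", "ACGT" * 50)
        with pytest.raises(ValueError, match="undefined"):
            ep.relative_coverage_by_gc([], ref, window=10, min_windows=1)


class TestRegions:
    def test_whole_genome_region_equals_global(self):
        rng = np.random.default_rng(7)
        ref = ReferenceGenome("g", "ACGTACGTACGTACGTACGT")
        reads = []
        for i in range(5):
            r = make_read("ACGTACGT", "ACGAACGT", ref_start=2 * i)
            reads.append(r)
        pooled = ep.pooled_errors(reads)
        region = ep.region_error_rates(reads, [(0, ref.length)], ref)
        assert region == pooled

    def test_empty_region_pool_flagged(self):
        ref = ReferenceGenome("g", "ACGT" * 5)
        counts = ep.region_error_rates([], [(0, 4)], ref)
        assert counts.alignment_length == 0
        with pytest.raises(ValueError):
            _ = counts.global_error_rate

    def test_two_region_pool_is_column_weighted(self):
        ref = ReferenceGenome("g", "A" * 40)
        # region A: 10 columns with 2 mismatches; region B: 30 columns, 0 errors
        r1 = make_read("A" * 10, "CC" + "A" * 8, ref_start=0)
        r2 = make_read("A" * 30, "A" * 30, ref_start=10)
        pooled = ep.region_error_rates([r1, r2], [(0, 10), (10, 40)], ref)
        assert pooled.global_error_rate == pytest.approx(2 / 40)

    def test_malformed_interval_rejected_with_line_number(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr\t0\t10\nchr\t20\t5\n")
        with pytest.raises(ValueError, match=":2"):
            ep.read_bed(bed)
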