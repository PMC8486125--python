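"""Perfect k-mers, seed sizes, harmful k-mer mining and the automaton."""
import numpy as np
import pytest

from _util import make_read
from poreprof import kmer_analysis as ka
from poreprof.align_io import ReferenceGenome, reverse_complement

GENOME = "ACGTCATTGC"
READ = "GCCAAGACCT"


class TestLongestPerfect:
    def test_fully_matching_read(self):
        assert ka.longest_perfect_kmer(make_read("ACGT" * 75, "ACGT" * 75)) == 300

    def test_worked_example_longest_run_is_three(self):
        r = make_read(reverse_complement(GENOME), READ)
        assert ka.longest_perfect_kmer(r) == 3

    def test_alternating_match_mismatch(self):
        r = make_read("ACACACAC", "AAAAAAAA")
        assert ka.longest_perfect_kmer(r) == 1

    def test_indel_breaks_run(self):
        r = make_read("ACG-TAC", "ACGTTAC")
        assert ka.longest_perfect_kmer(r) == 3

    def test_expected_longest_run_matches_asymptotic(self):
        """Mean longest error-free run under i.i.d. errors ~ log_{1/(1-e)} n."""
        rng = np.random.default_rng(13)
        n, e = 10_000, 0.05
        lengths = []
        for _ in range(300):
            errors = rng.random(n) < e
            ref = "A" * n
            read = "".join("C" if x else "A" for x in errors)
            lengths.append(ka.longest_perfect_kmer(make_read(ref, read)))
        # longest success-run asymptotic in base 1/(1-e):
        # log(n*e) + Euler-gamma correction - 1/2
        log_base = -np.log(1 - e)
        expected = (np.log(n * e) + np.euler_gamma) / log_base - 0.5
        assert np.mean(lengths) == pytest.approx(expected, rel=0.10)


class TestDistribution:
    def test_curve_non_increasing_and_reaches_one(self):
        curve, _ = ka.perfect_kmer_distribution(np.array([5, 9, 3, 3, 12]))
        frac = curve["fraction_reads"].to_numpy()
        assert (np.diff(frac) <= 1e-12).all()
        assert frac[0] == 1.0  # k = 0
        assert curve.loc[curve["k"] == 1, "fraction_reads"].item() == 1.0

    def test_printed_skewness_values(self):
        assert ka.scp_mode(242, 212, 242) == pytest.approx(0.12, abs=0.005)
        assert ka.scp_median(242, 487, 242) == pytest.approx(-3.0, abs=0.05)
        assert ka.scp_median(224, 353, 224) == pytest.approx(-1.7, abs=0.05)

    def test_degenerate_distribution_flagged(self):
        _, stats = ka.perfect_kmer_distribution(np.array([7, 7, 7]))
        assert stats.sd == 0.0
        assert stats.scp_mode is None and stats.scp_median is None

    def test_mode_tie_break_toward_smallest(self):
        _, stats = ka.perfect_kmer_distribution(np.array([4, 4, 9, 9, 1]))
        assert stats.mode == 4.0


class TestSeedSize:
    def test_all_reads_carry_smallest_length(self):
        assert ka.seed_size_at_confidence(np.array([100, 200, 300]), 0.95) == 100

    def test_higher_confidence_never_larger(self):
        rng = np.random.default_rng(3)
        lengths = rng.integers(10, 500, 200)
        k95 = ka.seed_size_at_confidence(lengths, 0.95)
        k99 = ka.seed_size_at_confidence(lengths, 0.99)
        assert k99 <= k95

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(4)
        lengths = rng.geometric(0.01, 500)
        for conf in (0.5, 0.9, 0.95, 0.99):
            k = ka.seed_size_at_confidence(lengths, conf)
            frac = np.mean(lengths >= k)
            assert frac >= conf
            assert np.mean(lengths >= k + 1) < conf

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ka.seed_size_at_confidence(np.array([]), 0.95)


class TestHarmfulKmers:
    def test_single_deletion_context_before(self):
        # read bases ...TACGG immediately precede the deletion gap
        r = make_read("AATACGGCT", "AATACGG-T")
        t = ka.harmful_kmers([r], "deletion", "before", k=5, top=10)
        assert t.entries["kmer"].tolist() == ["TACGG"]
        assert t.entries["count"].tolist() == [1]

    def test_context_shorter_than_k_skipped(self):
        r = make_read("ACGTACGT", "AC-TACGT")  # only 2 read bases before gap
        t = ka.harmful_kmers([r], "deletion", "before", k=5)
        assert t.entries.empty

    def test_consecutive_deletion_columns_one_site(self):
        r = make_read("ACGTACGGG" + "T", "ACGTAC---" + "T")
        t = ka.harmful_kmers([r], "deletion", "before", k=3)
        assert t.entries["count"].sum() == 1

    def test_mismatch_context_excludes_error_base(self):
        r = make_read("AAACGTTTT", "AAACGATTT")  # mismatch at position 5 (T->A)
        before = ka.harmful_kmers([r], "mismatch", "before", k=3)
        assert before.entries["kmer"].tolist() == ["ACG"]
        after = ka.harmful_kmers([r], "mismatch", "after", k=3)
        assert after.entries["kmer"].tolist() == ["TTT"]

    def test_homopolymeric_errors_excluded_with_flag(self):
        ref = ReferenceGenome("g", "ACGTAAAAGTACG")
        r = make_read("ACGTAAAAGTACG", "ACGTAA-AGTACG")
        t = ka.harmful_kmers(
            [r], "deletion", "before", k=3, exclude_homopolymeric=True, reference=ref
        )
        assert t.entries.empty
        t2 = ka.harmful_kmers([r], "deletion", "before", k=3)
        assert len(t2.entries) == 1

    def test_seeded_motif_dominates_top(self):
        rng = np.random.default_rng(19)
        reads = []
        for _ in range(150):
            left = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
            right = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
            ref = left + "TAGAA" + "C" + right
            read = ref[: len(left) + 5] + "-" + right
            reads.append(make_read(ref, read))
        t = ka.harmful_kmers(reads, "deletion", "before", k=5, top=5)
        assert t.entries.iloc[0]["kmer"] == "TAGAA"
        assert t.entries.iloc[0]["count"] == 150


class TestPositionCountMatrix:
    def test_single_kmer(self):
        import pandas as pd

        t = ka.HarmfulKmerTable(
            "deletion", "before", 5, pd.DataFrame({"kmer": ["CCCCC"], "count": [3]})
        )
        pcm = ka.position_count_matrix(t)
        assert (pcm["C"] == 3).all()
        assert (pcm.sum(axis=1) == 3).all()

    def test_split_position(self):
        import pandas as pd

        t = ka.HarmfulKmerTable(
            "deletion", "before", 3,
            pd.DataFrame({"kmer": ["AAA", "CAA"], "count": [2, 2]}),
        )
        pcm = ka.position_count_matrix(t)
        assert pcm.loc[1, "A"] == 2 and pcm.loc[1, "C"] == 2
        assert (pcm.sum(axis=1) == 4).all()


def table(kmers_weights, k, cls="count"):
    import pandas as pd

    return ka.HarmfulKmerTable(
        "deletion", "before", k,
        pd.DataFrame(
            {"kmer": list(kmers_weights), cls: list(kmers_weights.values())}
        ),
    )


class TestAutomaton:
    def test_single_kmer_linear_path_pruned_away(self):
        auto = ka.build_automaton(table({"CAGAA": 1}, 5))
        assert len(auto.edges) == 5
        assert all(e.weight == 1 for e in auto.edges)
        pruned = auto.prune(4)
        assert [n.node_id for n in pruned.nodes] == [auto.initial]
        assert pruned.edges == []

    def test_suffix_sharing_merges_states(self):
        auto = ka.build_automaton(table({"CAA": 5, "GAA": 5}, 3))
        non_initial = [n for n in auto.nodes if n.node_id != auto.initial]
        assert len(non_initial) <= 5
        # C and G branches converge onto the shared "AA" suffix immediately
        assert len(non_initial) == 3
        assert auto.accepts("CAA") and auto.accepts("GAA")
        assert not auto.accepts("CAG") and not auto.accepts("AAA")

    def test_layer_weight_conservation(self):
        rng = np.random.default_rng(37)
        kmers = {
            "".join("ACGT"[i] for i in rng.integers(0, 4, 4)): int(w)
            for w in rng.integers(1, 9, 25)
        }
        auto = ka.build_automaton(table(kmers, 4))
        total = sum(kmers.values())
        for layer in range(1, 5):
            assert auto.layer_weight(layer) == total

    def test_language_equals_input_set(self):
        rng = np.random.default_rng(41)
        kmers = {
            "".join("ACGT"[i] for i in rng.integers(0, 4, 3)): 2 for _ in range(10)
        }
        auto = ka.build_automaton(table(kmers, 3))
        for x in range(64):
            word = "".join("ACGT"[(x >> (2 * j)) & 3] for j in range(3))
            assert auto.accepts(word) == (word in kmers)

    def test_inconsistent_k_rejected(self):
        with pytest.raises(ValueError):
            ka.build_automaton([table({"CAA": 1}, 3), table({"CAGAA": 1}, 5)])

    def test_merge_tables_per_gc_class(self):
        t_low = table({"CAAAT": 4}, 5, cls="low")
        t_high = table({"CAAAT": 2, "GGGCA": 3}, 5, cls="high")
        merged = ka.merge_harmful_tables([t_low, t_high])
        w = merged.weights()
        assert w["CAAAT"] == {"low": 4, "high": 2}
        assert w["GGGCA"]["high"] == 3
        auto = ka.build_automaton(merged)
        assert auto.node(auto.initial).weight == 9
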