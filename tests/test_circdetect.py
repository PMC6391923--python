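import numpy as np
import pytest

from circplasmid import circdetect, synth
from circplasmid.circdetect import (
    call_circular,
    circularize,
    count_junction_pairs,
    detect_all,
    find_end_overlap,
)
from circplasmid.seqio import DetectionParams, PairedAlignment, Scaffold

from conftest import longest_terminal_exact_repeat, planted_scaffold, smith_waterman


def junction_pair(L, read_id="r1"):
    """Canonical junction-spanning pair on a scaffold of length L."""
    return PairedAlignment(read_id, "s", 10, 110, "-", L - 120, L - 20, "+")


class TestFindEndOverlap:
    def test_planted_exact_repeat(self, rng):
        sc = planted_scaffold(10_000, 50, rng)
        ov = find_end_overlap(sc)
        assert ov is not None
        assert ov.length == 50 and ov.identity == 100.0
        assert ov.prefix_range == (0, 50)
        assert ov.suffix_range == (sc.length - 50, sc.length)

    def test_random_sequence_yields_no_overlap(self, rng):
        sc = Scaffold("r", synth.random_dna(10_000, rng))
        assert longest_terminal_exact_repeat(sc.seq) < 20  # sanity on input
        assert find_end_overlap(sc) is None

    def test_planted_repeat_with_one_mismatch(self, rng):
        # 40-bp repeat, one substitution in the middle of the suffix copy:
        # the full alignment (39 matches - 1 mismatch = 37) beats either
        # exact half, so the reported block covers all 40 columns.
        circle = synth.random_dna(10_000, rng)
        suffix = list(circle[:40])
        suffix[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[suffix[20]]
        sc = Scaffold("m", circle + "".join(suffix))
        ov = find_end_overlap(sc)
        assert ov is not None
        assert ov.length == 40 and ov.identity == pytest.approx(97.5)
        assert ov.score == 37

    def test_score_matches_independent_smith_waterman(self, rng):
        # cross-check the aligner against a numpy DP oracle on small windows
        p = DetectionParams(search_window_bp=120)
        sc = planted_scaffold(1_000, 45, rng)
        ov = find_end_overlap(sc, p)
        w = 120
        oracle = smith_waterman(sc.seq[:w], sc.seq[-w:])
        assert ov is not None and ov.score == oracle == 45

    def test_short_scaffold_windows_truncate(self, rng):
        sc = planted_scaffold(400, 40, rng)  # scaffold 440 bp < 2 windows
        ov = find_end_overlap(sc)
        assert ov is not None and ov.length == 40

    def test_evalue_scales_with_window_size(self, rng):
        sc = planted_scaffold(10_000, 50, rng)
        e_small = find_end_overlap(sc, DetectionParams(search_window_bp=200)).evalue
        e_big = find_end_overlap(sc, DetectionParams(search_window_bp=1000)).evalue
        assert e_small < e_big <= 1e-5


class TestCountJunctionPairs:
    def setup_method(self):
        self.L = 10_000
        self.sc = Scaffold("s", "A" * self.L)
        self.params = DetectionParams()

    def test_canonical_pair_counts_once(self):
        assert count_junction_pairs([junction_pair(self.L)], self.sc,
                                    self.params) == 1

    def test_mate_must_lie_wholly_in_window(self):
        L = self.L
        # end-proximal mate starting 501 bp from the end leaks out of the
        # terminal window -> not counted
        out = PairedAlignment("r", "s", 10, 110, "-", L - 501, L - 401, "+")
        inside = PairedAlignment("r", "s", 10, 110, "-", L - 500, L - 400, "+")
        assert count_junction_pairs([out], self.sc, self.params) == 0
        assert count_junction_pairs([inside], self.sc, self.params) == 1

    def test_orientation_required_in_strict_mode(self):
        L = self.L
        wrong = PairedAlignment("r", "s", 10, 110, "+", L - 120, L - 20, "-")
        assert count_junction_pairs([wrong], self.sc, self.params) == 0
        permissive = DetectionParams(require_junction_orientation=False)
        assert count_junction_pairs([wrong], self.sc, permissive) == 1

    def test_mate_order_is_irrelevant(self):
        L = self.L
        swapped = PairedAlignment("r", "s", L - 120, L - 20, "+", 10, 110, "-")
        assert count_junction_pairs([swapped], self.sc, self.params) == 1

    def test_both_mates_same_end_do_not_count(self):
        inner = PairedAlignment("r", "s", 10, 110, "-", 200, 300, "+")
        assert count_junction_pairs([inner], self.sc, self.params) == 0

    def test_foreign_pair_is_contract_violation(self):
        foreign = PairedAlignment("r", "other", 10, 110, "-", 200, 300, "+")
        with pytest.raises(ValueError, match="other"):
            count_junction_pairs([foreign], self.sc, self.params)

    def test_mapped_community_counts_match_truth_geometry(self, rng):
        # simulate one circular template, map with the built-in mapper, and
        # compare against the count derived from the truth fragment
        # coordinates and the window/orientation rule
        L, overlap, read_len = 8_000, 100, 150
        circle = synth.random_dna(L, rng)
        sc = Scaffold("t", synth.plant_terminal_repeat(circle, overlap, 0, rng))
        reads, truth = synth.simulate_read_pairs(
            circle, True, 2_000, read_len, 450.0, 50.0, 0.0, rng,
            template_id="t",
        )
        pairs, _ = synth.map_reads_naive(reads, [sc])
        win = 500
        expected = 0
        for t in truth:
            s, ins = t.frag_start, t.insert
            if not t.junction_spanning:
                continue
            r1 = (s, s + read_len)                    # '+' near the end
            w = s + ins - L
            r2 = (w - read_len, w)                    # '-' near the start
            if (r1[0] >= sc.length - win and r1[1] <= sc.length
                    and r2[0] >= 0 and r2[1] <= win):
                expected += 1
        got = count_junction_pairs(
            [p for p in pairs if p.scaffold_id == "t"], sc)
        assert got == expected > 2


class TestCallCircular:
    def make_inputs(self, rng, length, overlap_len, n_pairs):
        sc = planted_scaffold(length, overlap_len, rng)
        ov = find_end_overlap(sc)
        return sc, ov, n_pairs

    @pytest.mark.parametrize("length,expect", [(1900, False), (2000, False),
                                               (2001, True)])
    def test_length_criterion_is_strict(self, rng, length, expect):
        # scaffold length (not trimmed circle length) is what criterion (i)
        # thresholds; plant the repeat inside the stated total length
        circle = synth.random_dna(length - 100, rng)
        sc = Scaffold("s", synth.plant_terminal_repeat(circle, 100, 0, rng))
        assert sc.length == length
        call = call_circular(sc, find_end_overlap(sc), 5)
        assert call.passed_overlap and call.passed_pairs
        assert call.is_circular is expect

    @pytest.mark.parametrize("overlap_len,expect", [(34, False), (35, True)])
    def test_overlap_criterion_is_strict(self, rng, overlap_len, expect):
        sc, ov, n = self.make_inputs(rng, 5_000, overlap_len, 5)
        call = call_circular(sc, ov, n)
        assert call.passed_length and call.passed_pairs
        assert call.is_circular is expect

    @pytest.mark.parametrize("n_pairs,expect", [(0, False), (1, False),
                                                (2, True), (5, True)])
    def test_pair_criterion_is_at_least_two(self, rng, n_pairs, expect):
        sc, ov, n = self.make_inputs(rng, 5_000, 100, n_pairs)
        call = call_circular(sc, ov, n)
        assert call.is_circular is expect

    def test_absent_overlap_fails_criterion(self, rng):
        sc = Scaffold("r", synth.random_dna(5_000, rng))
        call = call_circular(sc, find_end_overlap(sc), 5)
        assert not call.passed_overlap and not call.is_circular

    def test_conjunction_law(self, rng):
        # flipping exactly one criterion to failure always kills the call
        sc, ov, _ = self.make_inputs(rng, 5_000, 100, 5)
        assert call_circular(sc, ov, 5).is_circular
        assert not call_circular(sc, None, 5).is_circular
        assert not call_circular(sc, ov, 1).is_circular
        short = call_circular(sc, ov, 5, DetectionParams(min_scaffold_bp=10_000))
        assert not short.is_circular

    def test_circular_seq_present_iff_circular(self, rng):
        sc, ov, _ = self.make_inputs(rng, 5_000, 100, 5)
        yes = call_circular(sc, ov, 5)
        no = call_circular(sc, ov, 0)
        assert yes.circular_seq is not None
        assert yes.circular_length == sc.length - 100
        assert no.circular_seq is None


class TestCircularize:
    def test_exact_repeat_trim(self, rng):
        x = synth.random_dna(50, rng)
        y = synth.random_dna(400, rng)
        sc = Scaffold("s", x + y + x)
        ov = find_end_overlap(sc, DetectionParams(search_window_bp=200))
        assert circularize(sc, ov) == x + y

    def test_doubling_property(self, rng):
        # the doubled circle must contain the original scaffold: rotation-
        # equivalence of the trimmed circle with the linearized input
        for L, k in ((1_000, 40), (5_000, 150), (2_345, 77)):
            sc = planted_scaffold(L, k, rng)
            circ = circularize(sc, find_end_overlap(sc))
            assert len(circ) == L
            assert sc.seq in circ + circ

    def test_degenerate_trim_is_error(self, rng):
        from circplasmid.circdetect import EndOverlap
        sc = Scaffold("s", "ACGTACGT")
        ov = EndOverlap(8, 100.0, 8.0, 1e-9, (0, 8), (0, 8))
        with pytest.raises(ValueError, match="empty"):
            circularize(sc, ov)

    def test_inconsistent_range_is_error(self, rng):
        from circplasmid.circdetect import EndOverlap
        sc = Scaffold("s", "ACGTACGT")
        ov = EndOverlap(4, 100.0, 4.0, 1e-9, (0, 4), (6, 12))
        with pytest.raises(ValueError, match="inconsistent"):
            circularize(sc, ov)


class TestDetectAll:
    def build_community(self, rng, n_circular=6, n_linear=4):
        scaffolds, alignments, truth = [], [], {}
        for i in range(n_circular):
            sc = planted_scaffold(3_000 + 1_000 * i, 100, rng)
            sc = Scaffold(f"circ_{i}", sc.seq)
            scaffolds.append(sc)
            truth[sc.id] = True
            for j in range(3):
                alignments.append(
                    PairedAlignment(f"c{i}_{j}", sc.id, 10 + j, 110 + j, "-",
                                    sc.length - 120, sc.length - 20, "+")
                )
        for i in range(n_linear):
            sc = Scaffold(f"lin_{i}", synth.random_dna(4_000, rng))
            scaffolds.append(sc)
            truth[sc.id] = False
        return scaffolds, alignments, truth

    def test_truth_recovery(self, rng):
        scaffolds, alignments, truth = self.build_community(rng)
        calls = detect_all(scaffolds, alignments)
        assert [c.scaffold_id for c in calls] == [s.id for s in scaffolds]
        assert {c.scaffold_id: c.is_circular for c in calls} == truth

    def test_empty_inputs(self):
        assert detect_all([], []) == []

    def test_withholding_pairs_kills_all_calls(self, rng):
        scaffolds, _, _ = self.build_community(rng)
        calls = detect_all(scaffolds, [])
        assert sum(c.is_circular for c in calls) == 0

    def test_determinism(self, rng):
        scaffolds, alignments, _ = self.build_community(rng)
        assert detect_all(scaffolds, alignments) == detect_all(
            scaffolds, alignments)

    def test_monotonicity_in_thresholds(self, rng):
        scaffolds, alignments, _ = self.build_community(rng)

        def n_calls(**kw):
            return sum(
                c.is_circular
                for c in detect_all(scaffolds, alignments, DetectionParams(**kw))
            )

        for field, grid in (
            ("min_scaffold_bp", [1000, 2000, 4000, 8000]),
            ("min_overlap_bp", [20, 34, 99, 100, 150]),
            ("min_junction_pairs", [1, 2, 3, 4]),
        ):
            counts = [n_calls(**{field: v}) for v in grid]
            assert counts == sorted(counts, reverse=True), field
        e_counts = [n_calls(max_evalue=v) for v in (1e-40, 1e-20, 1e-5, 1e-2)]
        assert e_counts == sorted(e_counts)


class TestOracleEquivalence:
    def test_overlap_length_equals_exact_repeat_oracle(self, rng):
        # error-free planted constructs: the aligner's reported overlap must
        # equal the brute-force longest terminal exact repeat
        for _ in range(25):
            L = int(rng.integers(3_000, 8_000))
            k = int(rng.integers(35, 300))
            sc = planted_scaffold(L, k, rng)
            ov = find_end_overlap(sc)
            assert ov is not None
            assert ov.length == longest_terminal_exact_repeat(sc.seq) == k
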