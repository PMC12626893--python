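import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixcharge import (
    Alignment,
    ProteinSequence,
    SegmentSpec,
    extract_segments,
    filter_by_coverage,
    first_helix_segment,
    greedy_identity_cluster,
    trim_by_gap_threshold,
)
from helixcharge.prep import pairwise_identity, predict_ss_propensity


class TestTrim:
    # non-gap fractions of {MK-, M-R, MKR} are (1, 2/3, 2/3), counted by hand
    def test_gap_threshold_half_keeps_all(self, small_aln):
        trimmed, kept = trim_by_gap_threshold(small_aln, 0.5)
        assert kept == [0, 1, 2]
        assert trimmed.rows == small_aln.rows

    def test_gap_threshold_three_quarters_keeps_first(self, small_aln):
        trimmed, kept = trim_by_gap_threshold(small_aln, 0.75)
        assert kept == [0]
        assert trimmed.rows == ["M", "M", "M"]

    def test_identity_on_gapless(self):
        aln = Alignment(ids=["a", "b"], rows=["MKR", "MER"])
        trimmed, kept = trim_by_gap_threshold(aln, 1.0)
        assert trimmed.rows == aln.rows and kept == [0, 1, 2]

    def test_all_columns_removed_warns(self):
        aln = Alignment(ids=["a", "b"], rows=["M-", "-R"])
        with pytest.warns(UserWarning, match="every column"):
            trimmed, kept = trim_by_gap_threshold(aln, 1.0)
        assert kept == [] and trimmed.n_cols == 0

    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent(self, seed, gt):
        rng = np.random.default_rng(seed)
        rows = [
            "".join(rng.choice(list("MKRDE-"), size=12)) for _ in range(5)
        ]
        rows = [r if set(r) != {"-"} else "M" + r[1:] for r in rows]
        aln = Alignment(ids=[f"s{i}" for i in range(5)], rows=rows)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            once, _ = trim_by_gap_threshold(aln, gt)
            if once.n_cols == 0:
                return
            twice, kept = trim_by_gap_threshold(once, gt)
        assert twice.rows == once.rows
        assert kept == list(range(once.n_cols))

    def test_precondition(self, small_aln):
        with pytest.raises(ValueError):
            trim_by_gap_threshold(small_aln, 0.0)


class TestCoverage:
    def test_low_coverage_row_dropped(self):
        rows = ["M" * 10 + "-" * 30, "M" * 40]
        aln = Alignment(ids=["low", "full"], rows=rows)
        assert filter_by_coverage(aln, 0.5).ids == ["full"]

    def test_counts_match_thresholds(self):
        # coverages 0.9, 0.4, 0.6 over 10 columns
        rows = ["M" * 9 + "-", "M" * 4 + "-" * 6, "M" * 6 + "-" * 4]
        aln = Alignment(ids=list("abc"), rows=rows)
        assert filter_by_coverage(aln, 0.5).ids == ["a", "c"]

    def test_zero_min_cov_rejected(self, small_aln):
        with pytest.raises(ValueError):
            filter_by_coverage(small_aln, 0.0)


class TestClustering:
    def test_identical_sequences_merge(self):
        seqs = [ProteinSequence("a", "MKRDE"), ProteinSequence("b", "MKRDE")]
        cs = greedy_identity_cluster(seqs, 0.95)
        assert len(cs) == 1 and sorted(cs.clusters[0][1]) == ["a", "b"]

    def test_divergent_sequences_split(self):
        # identity 1/4 by hand alignment
        seqs = [ProteinSequence("a", "MKKK"), ProteinSequence("b", "MEEE")]
        assert len(greedy_identity_cluster(seqs, 0.95)) == 2

    def test_threshold_one_on_distinct(self):
        # same length, each pair differs somewhere; identity is
        # matches / shorter length, so nested substrings would NOT count
        # as distinct here
        seqs = [
            ProteinSequence("s0", "MKRDE"),
            ProteinSequence("s1", "MKRDW"),
            ProteinSequence("s2", "AKRDE"),
        ]
        assert len(greedy_identity_cluster(seqs, 1.0)) == 3

    def test_substring_counts_as_identical(self):
        # CD-HIT convention: a perfect substring has identity 1.0 to the
        # longer representative
        seqs = [ProteinSequence("long", "MKRDEW"), ProteinSequence("short", "KRDE")]
        assert len(greedy_identity_cluster(seqs, 1.0)) == 1

    def test_members_meet_threshold_and_monotonicity(self, default_dataset):
        seqs = [
            ProteinSequence(s.id, s.residues[:60])
            for s in default_dataset.sequences[:30]
        ]
        by_id = {s.id: s.residues for s in seqs}
        counts = []
        for t in (0.9, 0.6, 0.3):
            cs = greedy_identity_cluster(seqs, t)
            counts.append(len(cs))
            for rep, members in cs.clusters:
                assert rep in members
                for m in members:
                    assert pairwise_identity(by_id[m], by_id[rep]) >= t - 1e-12
        # decreasing threshold never increases cluster count
        assert counts == sorted(counts, reverse=True)


class TestExtract:
    def test_column_range_strips_gaps(self):
        aln = Alignment(ids=["a"], rows=["MK-RQ"])
        spec = SegmentSpec(source="column_range", col_start=0, col_end=3)
        assert extract_segments(aln, spec)["a"] == ("MK", "RQ")

    def test_full_range_empties_internal(self, small_aln):
        spec = SegmentSpec(col_start=0, col_end=small_aln.n_cols)
        segs = extract_segments(small_aln, spec)
        assert all(internal == "" for _, internal in segs.values())

    def test_all_gap_window_warns_but_keeps_row(self):
        aln = Alignment(ids=["a", "b"], rows=["--MK", "RKMK"])
        spec = SegmentSpec(col_start=0, col_end=2)
        with pytest.warns(UserWarning, match="all-gap"):
            segs = extract_segments(aln, spec)
        assert segs["a"] == ("", "MK")

    def test_out_of_range_rejected(self, small_aln):
        with pytest.raises(ValueError, match="outside"):
            extract_segments(small_aln, SegmentSpec(col_start=0, col_end=99))

    def test_prefix_concatenation_recovers_sequence(self, default_dataset):
        aln = default_dataset.alignment
        spec = SegmentSpec(col_start=0, col_end=default_dataset.nterm_cols[1])
        segs = extract_segments(aln, spec)
        for sid, row in list(zip(aln.ids, aln.rows))[:20]:
            nterm, internal = segs[sid]
            assert nterm + internal == row.replace("-", "")


class TestFirstHelix:
    def test_run_scan(self):
        seq = ProteinSequence("a", "M" * 10, ss="CHHHHHHCCC")
        assert first_helix_segment(seq, min_run=4) == (1, 7)

    def test_no_helix(self):
        seq = ProteinSequence("a", "M" * 6, ss="CCCCCC")
        assert first_helix_segment(seq, min_run=4) is None

    def test_short_run_rejected(self):
        seq = ProteinSequence("a", "MMM", ss="HHH")
        assert first_helix_segment(seq, min_run=4) is None

    def test_requires_ss_unless_heuristic(self):
        seq = ProteinSequence("a", "MEEL" * 10)
        with pytest.raises(ValueError, match="secondary structure required"):
            first_helix_segment(seq, min_run=4)
        rng = first_helix_segment(seq, min_run=4, use_heuristic=True)
        assert rng is None or rng[1] - rng[0] >= 4

    def test_propensity_heuristic_calls_helix_on_helix_formers(self):
        ss = predict_ss_propensity("AELMAELMAELM")
        assert set(ss) <= {"H", "C"} and "H" in ss
        assert "H" not in predict_ss_propensity("GPGPGPGSGSGS")
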