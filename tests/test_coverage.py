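"""Read clipping, alignment filtering, and 5'-end coverage normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from orthotss.coverage import (
    Library,
    ReadAlignmentRecord,
    clip_read,
    coverage_from_alignments,
    filter_alignments,
    longest_homopolymer,
    records_to_frame,
)


def make_record(read_id="r1", read_length=50, start=100, end=149, strand="+",
                mismatches=0, gaps=0, evalue=1e-20, score=50.0, replicon="chr"):
    return ReadAlignmentRecord(read_id, read_length, replicon, start, end, strand,
                               mismatches, gaps, evalue, score)


class TestClipRead:
    @pytest.mark.parametrize(
        "seq,max_a,max_t,min_len,expected",
        [
            # a 5-A tail exceeding the genomic maximum of 4 is removed in full
            ("ACGTACGTACGTACGTACGTAAAAA", 4, 4, 1, "ACGTACGTACGTACGTACGT"),
            # a tail not exceeding the genomic maximum stays
            ("ACGTAAAA", 4, 4, 1, "ACGTAAAA"),
            # leading poly-T beyond the maximum is removed in full
            ("TTTTTACGTACGT", 4, 4, 1, "ACGTACGT"),
            ("TTTTACGT", 4, 4, 1, "TTTTACGT"),
            # 25 nt read clipped to 18 nt falls below the 20 nt floor -> DROP
            ("ACGTACGTACGTACGTAC" + "A" * 7, 4, 4, 20, None),
            ("", 4, 4, 1, None),
        ],
    )
    def test_examples(self, seq, max_a, max_t, min_len, expected):
        assert clip_read(seq, max_a, max_t, min_len) == expected

    @given(st.text(alphabet="ACGT", max_size=60), st.integers(0, 10), st.integers(0, 10))
    def test_never_lengthens_and_idempotent(self, seq, max_a, max_t):
        out = clip_read(seq, max_a, max_t, 1)
        if out is None:
            return
        assert len(out) <= len(seq)
        assert clip_read(out, max_a, max_t, 1) == out

    def test_longest_homopolymer(self):
        assert longest_homopolymer("AATAAAG", "A") == 3
        assert longest_homopolymer("CGCG", "A") == 0


class TestFilterAlignments:
    def test_eighty_percent_rule(self):
        # 40/50 aligned with 4 mismatches and no gaps passes; 39/50 does not
        kept = filter_alignments(
            records_to_frame(
                [
                    make_record("ok", read_length=50, start=100, end=139, mismatches=4),
                    make_record("short", read_length=50, start=100, end=138),
                ]
            )
        )
        assert list(kept["read_id"]) == ["ok"]

    def test_gapped_and_high_evalue_dropped(self):
        kept = filter_alignments(
            records_to_frame(
                [
                    make_record("gapped", gaps=1),
                    make_record("weak", evalue=1e-2),
                    make_record("ok"),
                ]
            )
        )
        assert list(kept["read_id"]) == ["ok"]

    def test_ambiguous_best_score_discards_read(self):
        frame = records_to_frame(
            [
                make_record("multi", start=100, end=149, score=50.0),
                make_record("multi", start=500, end=549, score=50.0),
                make_record("uniq", start=200, end=249, score=50.0),
                make_record("uniq", start=700, end=749, score=40.0),
            ]
        )
        kept = filter_alignments(frame)
        assert list(kept["read_id"]) == ["uniq"]
        assert kept.iloc[0]["start"] == 200  # the single best placement survives

    def test_rdna_overlap_discards_read(self):
        frame = records_to_frame([make_record("rrna", start=100, end=149),
                                  make_record("ok", start=900, end=949)])
        kept = filter_alignments(frame, rdna_regions=[("chr", 140, 300)])
        assert list(kept["read_id"]) == ["ok"]

    def test_empty_input(self):
        assert filter_alignments(records_to_frame([])).empty

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(1, 400), st.integers(0, 6),
                              st.integers(0, 1), st.floats(1e-30, 1.0)), max_size=25),
           st.randoms(use_true_random=False))
    def test_idempotent_and_order_independent(self, raw, rnd):
        records = [
            make_record(f"r{rid}", read_length=50, start=start, end=start + 44,
                        mismatches=mm, gaps=gap, evalue=ev, score=45.0 - mm)
            for rid, start, mm, gap, ev in raw
        ]
        frame = records_to_frame(records)
        once = filter_alignments(frame)
        assert filter_alignments(once).equals(once)
        shuffled = frame.sample(frac=1, random_state=rnd.randint(0, 10**6)).reset_index(drop=True)
        again = filter_alignments(shuffled)
        assert again.sort_values(list(again.columns)).reset_index(drop=True).equals(
            once.sort_values(list(once.columns)).reset_index(drop=True)
        )


class TestCoverage:
    def _libraries(self):
        lib_a = Library("A", "branchless", "plus", records_to_frame(
            [make_record(f"a{i}", start=10, end=59) for i in range(10)]
        ))
        lib_b = Library("B", "branchless", "minus", records_to_frame(
            [make_record(f"b{i}", start=100, end=140, strand="-", read_length=41, score=41)
             for i in range(5)]
        ))
        return [lib_a, lib_b]

    def test_normalization_to_smallest(self):
        tracks = coverage_from_alignments(
            self._libraries(), {"chr": 200}, library_sizes={"A": 1000, "B": 500}
        )
        # raw count 10 in the 1000-read library scales by 500/1000
        assert tracks[0].at("chr", "+", 10) == pytest.approx(5.0)

    def test_minus_strand_five_prime_is_end(self):
        tracks = coverage_from_alignments(self._libraries(), {"chr": 200})
        assert tracks[1].at("chr", "-", 140) == pytest.approx(5.0)
        assert tracks[1].at("chr", "-", 100) == 0.0

    def test_smallest_library_unchanged(self):
        tracks = coverage_from_alignments(self._libraries(), {"chr": 200})
        assert tracks[1].data[("chr", "-")].max() == pytest.approx(5.0)

    def test_totals_equal_smallest_raw_total(self):
        tracks = coverage_from_alignments(self._libraries(), {"chr": 200})
        for track in tracks:
            assert track.total() == pytest.approx(5.0, abs=1e-9)

    def test_zero_size_library_errors(self):
        with pytest.raises(ValueError, match="zero size"):
            coverage_from_alignments(self._libraries(), {"chr": 200},
                                     library_sizes={"A": 0, "B": 5})

    def test_record_validation(self):
        with pytest.raises(ValueError):
            make_record(start=10, end=5)
        with pytest.raises(ValueError):
            make_record(mismatches=-1)
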