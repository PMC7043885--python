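"""Read collapse, linker/UMI trimming, end-assigned coverage, rpm, WIG I/O."""

import collections
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdscan.tracks import (
    AlignmentRecord,
    CoverageTrack,
    LinkerSpec,
    RawRead,
    build_coverage,
    collapse_duplicates,
    preprocess_read,
    read_bed,
    rpm_normalize,
)
from asdscan.wig import WigParseError, read_wig, write_wig

LINKER = "CACTCGGGCACCAAGGAC"


class TestCollapse:
    def test_basic_multiplicities(self):
        reads = [RawRead("AAA"), RawRead("AAA"), RawRead("CCC")]
        assert [(r.seq, m) for r, m in collapse_duplicates(reads)] == [
            ("AAA", 2), ("CCC", 1)
        ]

    def test_thousand_copies_collapse_to_one(self):
        out = collapse_duplicates([RawRead("ACGT")] * 1000)
        assert len(out) == 1 and out[0][1] == 1000

    def test_multiset_matches_counting_oracle(self):
        rng = random.Random(7)
        reads = [
            RawRead("".join(rng.choices("ACGT", k=8))) for _ in range(100)
        ]
        oracle = collections.Counter(r.seq for r in reads)
        got = {r.seq: m for r, m in collapse_duplicates(reads)}
        assert got == dict(oracle)
        assert sum(got.values()) == 100

    def test_empty_input(self):
        assert collapse_duplicates([]) == []


class TestPreprocess:
    def test_full_layout_recovers_insert(self):
        umi5, insert, umi3 = "ACGT", "A" * 12 + "C" * 13, "GGGTTT"
        read = RawRead(umi5 + insert + umi3 + LINKER)
        result = preprocess_read(read)
        assert result.ok
        assert result.insert == insert
        assert (result.umi5, result.umi3) == (umi5, umi3)

    def test_missing_linker_rejected(self):
        result = preprocess_read(RawRead("ACGT" * 10))
        assert result.rejected == "no_linker"

    def test_short_insert_rejected(self):
        read = RawRead("ACGT" + "A" * 10 + "GGGTTT" + LINKER)
        assert preprocess_read(read).rejected == "too_short"

    def test_one_linker_mismatch_tolerated_by_default(self):
        mutated = "G" + LINKER[1:]
        read = RawRead("ACGT" + "A" * 20 + "GGGTTT" + mutated)
        assert preprocess_read(read).ok
        strict = LinkerSpec(max_mismatches=0)
        assert preprocess_read(read, linker=strict).rejected == "no_linker"


class TestBuildCoverage:
    LENGTHS = {"chr": 200}

    def test_plus_strand_three_prime_convention(self):
        track = build_coverage(
            [AlignmentRecord("chr", "+", 100, 130)], self.LENGTHS, "three_prime"
        )
        assert track.get("chr", "+")[129] == 1
        assert track.get("chr", "+").sum() == 1

    def test_minus_strand_three_prime_is_lowest_coordinate(self):
        track = build_coverage(
            [AlignmentRecord("chr", "-", 100, 130)], self.LENGTHS, "three_prime"
        )
        assert track.get("chr", "-")[100] == 1

    def test_five_prime_conventions(self):
        plus = build_coverage(
            [AlignmentRecord("chr", "+", 100, 130)], self.LENGTHS, "five_prime"
        )
        minus = build_coverage(
            [AlignmentRecord("chr", "-", 100, 130)], self.LENGTHS, "five_prime"
        )
        assert plus.get("chr", "+")[100] == 1
        assert minus.get("chr", "-")[129] == 1

    def test_random_alignments_conserve_counts(self):
        rng = random.Random(3)
        alns = []
        for _ in range(50):
            start = rng.randrange(0, 180)
            alns.append(
                AlignmentRecord(
                    "chr", rng.choice("+-"), start, start + rng.randrange(1, 20)
                )
            )
        track = build_coverage(alns, self.LENGTHS, "three_prime")
        assert sum(v.sum() for v in track.data.values()) == 50
        assert track.total_mapped == 50

    def test_out_of_bounds_is_hard_error(self):
        with pytest.raises(ValueError, match="outside replicon"):
            build_coverage(
                [AlignmentRecord("chr", "+", 190, 210)], self.LENGTHS,
                "three_prime",
            )

    def test_unknown_strand_symbol_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            AlignmentRecord("chr", ".", 0, 10)

    def test_blacklist_drops_overlapping_alignments(self):
        track = build_coverage(
            [AlignmentRecord("chr", "+", 10, 40),
             AlignmentRecord("chr", "+", 100, 120)],
            self.LENGTHS, "three_prime", blacklist=[("chr", 30, 50)],
        )
        assert track.total_mapped == 1
        assert track.n_blacklisted == 1

    def test_strand_mirror(self):
        """Mirrored alignments on the opposite strand give the mirrored track."""
        n = self.LENGTHS["chr"]
        alns = [AlignmentRecord("chr", "+", 20, 45),
                AlignmentRecord("chr", "+", 60, 88)]
        mirrored = [
            AlignmentRecord("chr", "-", n - a.end, n - a.start) for a in alns
        ]
        fwd = build_coverage(alns, self.LENGTHS, "three_prime")
        rev = build_coverage(mirrored, self.LENGTHS, "three_prime")
        assert np.array_equal(
            fwd.get("chr", "+"), rev.get("chr", "-")[::-1]
        )


class TestRpm:
    def test_scaling(self):
        track = CoverageTrack.zeros({"chr": 10})
        track.get("chr", "+")[3] = 4
        track.total_mapped = 2e6
        assert rpm_normalize(track).get("chr", "+")[3] == 2.0

    def test_totals_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        track = CoverageTrack.zeros({"chr": 100})
        track.get("chr", "+")[:] = rng.integers(0, 20, 100)
        track.get("chr", "-")[:] = rng.integers(0, 20, 100)
        track.total_mapped = float(
            sum(v.sum() for v in track.data.values())
        )
        rpm = rpm_normalize(track)
        assert sum(v.sum() for v in rpm.data.values()) == pytest.approx(1e6)

    def test_double_normalization_is_error(self):
        track = CoverageTrack.zeros({"chr": 10})
        track.get("chr", "+")[0] = 1
        track.total_mapped = 1
        with pytest.raises(ValueError, match="already"):
            rpm_normalize(rpm_normalize(track))

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="total_mapped"):
            rpm_normalize(CoverageTrack.zeros({"chr": 10}))


class TestWig:
    def test_sparse_round_trip_identity(self, tmp_path):
        track = CoverageTrack.zeros({"chrA": 500, "chrB": 100})
        track.get("chrA", "+")[[9, 99, 499]] = [1.5, 2.0, 7.25]
        track.get("chrA", "-")[42] = 3.0
        track.get("chrB", "-")[0] = 11.0
        track.total_mapped = 24.75
        path = tmp_path / "t.wig"
        write_wig(track, str(path))
        back = read_wig(str(path), {"chrA": 500, "chrB": 100})
        for key in track.data:
            assert np.array_equal(track.data[key], back.data[key]), key
        assert back.total_mapped == track.total_mapped
        assert back.normalized == track.normalized

    def test_one_based_file_positions(self, tmp_path):
        path = tmp_path / "t.wig"
        path.write_text(
            'track type=wiggle_0 name="chr:+"\nvariableStep chrom=chr\n100 5.0\n'
        )
        track = read_wig(str(path), {"chr": 200})
        assert track.get("chr", "+")[99] == 5.0

    def test_fixed_step_rejected(self, tmp_path):
        path = tmp_path / "t.wig"
        path.write_text(
            'track type=wiggle_0 name="chr:+"\nfixedStep chrom=chr start=1 step=1\n'
        )
        with pytest.raises(WigParseError, match="unsupported dialect"):
            read_wig(str(path), {"chr": 200})

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "t.wig"
        path.write_text(
            'track type=wiggle_0 name="chr:+"\nvariableStep chrom=chr\nbogus\n'
        )
        with pytest.raises(WigParseError, match="line 3"):
            read_wig(str(path), {"chr": 200})


class TestBed:
    def test_read_bed6(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr\t10\t40\tr1\t2\t+\nchr\t50\t70\tr2\t1\t-\n")
        alns = read_bed(str(path))
        assert [(a.start, a.end, a.strand, a.weight) for a in alns] == [
            (10, 40, "+", 2), (50, 70, "-", 1)
        ]


class TestConservation:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_counts_conserved_through_collapse_trim_coverage(self, seed):
        """Reads in = (assigned + rejected) out, through the whole ingest path."""
        rng = random.Random(seed)
        n_reads = 60
        reads = []
        for _ in range(n_reads):
            insert = "".join(rng.choices("ACGT", k=rng.randrange(10, 30)))
            if rng.random() < 0.8:
                seq = "ACGT" + insert + "GGGTTT" + LINKER
            else:
                seq = insert  # no linker
            reads.append(RawRead(seq))
        # duplicate some reads
        reads += rng.choices(reads, k=20)
        collapsed = collapse_duplicates(reads)
        assert sum(m for _, m in collapsed) == len(reads)
        alns, rejected = [], 0
        for read, mult in collapsed:
            result = preprocess_read(read)
            if not result.ok:
                rejected += mult
                continue
            start = rng.randrange(0, 100)
            alns.append(
                AlignmentRecord(
                    "chr", "+", start, start + len(result.insert), weight=mult
                )
            )
        track = build_coverage(alns, {"chr": 200}, "three_prime")
        assert track.total_mapped + rejected == len(reads)
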