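"""Interval algebra and text-format I/O."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preatlas.intervals import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    ParseError,
    distance_to_tss,
    merge_intervals,
    overlap_length,
    overlaps,
    read_bed,
    read_bedgraph,
    read_bedpe,
    write_bed,
    BedRecord,
)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


# ---- brute-force oracle ----------------------------------------------------

def union_bases(intervals):
    """Per-base set union, the oracle for merge/overlap arithmetic."""
    bases = {}
    for i in intervals:
        bases.setdefault(i.chrom, set()).update(range(i.start, i.end))
    return bases


def merge_oracle(intervals):
    """Connected components under the shares->=1-base relation.

    Adjacent-but-disjoint intervals stay separate (the strict-overlap
    merge convention), so plain base-run extraction is not the right
    oracle; component spans are.
    """
    ivs = list(intervals)
    n = len(ivs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = ivs[i], ivs[j]
            if a.chrom == b.chrom and set(range(a.start, a.end)) & set(
                range(b.start, b.end)
            ):
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(ivs[i])
    out = [
        GenomicInterval(
            members[0].chrom,
            min(m.start for m in members),
            max(m.end for m in members),
        )
        for members in comps.values()
    ]
    return sorted(out, key=lambda g: (g.chrom, g.start, g.end))


class TestValidation:
    def test_rejects_degenerate_interval(self):
        with pytest.raises(ValueError, match="end must exceed start"):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_gene_tss_must_be_in_body(self):
        with pytest.raises(ValueError, match="TSS"):
            GeneModel("g1", iv("chr1", 100, 200), tss=500)


class TestMerge:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([("chr1", 100, 200)], [("chr1", 100, 200)]),
            (
                [("chr1", 100, 200), ("chr1", 150, 300), ("chr1", 400, 500)],
                [("chr1", 100, 300), ("chr1", 400, 500)],
            ),
            (
                [("chr1", 100, 200), ("chr2", 100, 200)],
                [("chr1", 100, 200), ("chr2", 100, 200)],
            ),
            # half-open adjacency does not merge at the default gap rule
            (
                [("chr1", 0, 10), ("chr1", 10, 20)],
                [("chr1", 0, 10), ("chr1", 10, 20)],
            ),
        ],
    )
    def test_examples(self, intervals, expected):
        got = merge_intervals([iv(*t) for t in intervals])
        assert [(g.chrom, g.start, g.end) for g in got] == expected

    def test_min_gap_bridges_small_gaps(self):
        got = merge_intervals([iv("chr1", 0, 10), iv("chr1", 11, 20)], min_gap=2)
        assert [(g.start, g.end) for g in got] == [(0, 20)]
        got = merge_intervals([iv("chr1", 0, 10), iv("chr1", 12, 20)], min_gap=2)
        assert len(got) == 2

    def test_idempotent_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        ivs = [
            iv(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 50)))
            for s in rng.integers(0, 500, size=40)
        ]
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        perm = [ivs[i] for i in rng.permutation(len(ivs))]
        assert merge_intervals(perm) == merged

    def test_matches_per_base_oracle_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ivs = [
                iv(f"chr{rng.integers(1, 4)}", int(s), int(s) + int(rng.integers(1, 120)))
                for s in rng.integers(0, 2000, size=int(rng.integers(1, 60)))
            ]
            merged = merge_intervals(ivs)
            assert merged == merge_oracle(ivs)
            # the merged catalog covers exactly the union of input bases
            assert union_bases(merged) == union_bases(ivs)


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,min_bp,expected",
        [
            (("chr1", 0, 10), ("chr1", 10, 20), 1, False),
            (("chr1", 0, 10), ("chr1", 5, 20), 1, True),
            (("chr1", 0, 10), ("chr1", 8, 20), 3, False),  # overlap is 2 bp
            (("chr1", 0, 10), ("chr2", 0, 10), 1, False),
        ],
    )
    def test_examples(self, a, b, min_bp, expected):
        assert overlaps(iv(*a), iv(*b), min_bp) is expected

    @given(
        s1=st.integers(0, 200), l1=st.integers(1, 50),
        s2=st.integers(0, 200), l2=st.integers(1, 50),
        min_bp=st.integers(1, 10),
    )
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_base_counting(self, s1, l1, s2, l2, min_bp):
        a, b = iv("chr1", s1, s1 + l1), iv("chr1", s2, s2 + l2)
        shared = len(set(range(s1, s1 + l1)) & set(range(s2, s2 + l2)))
        assert overlap_length(a, b) == shared
        assert overlaps(a, b, min_bp) == (shared >= min_bp)


class TestDistanceToTss:
    def gene(self, chrom="chr1", tss=150):
        lo, hi = min(tss, 100), max(tss + 1, 5000)
        return GeneModel("g", GenomicInterval(chrom, lo, hi), tss=tss)

    def test_containment_is_zero(self):
        assert distance_to_tss(iv("chr1", 100, 200), self.gene(tss=150)) == 0

    def test_nearest_edge(self):
        # interval end base is 199; |199 - 2700| = 2501: distal at the
        # 2,500 bp rule (inclusive boundary)
        assert distance_to_tss(iv("chr1", 100, 200), self.gene(tss=2700)) == 2501

    def test_cross_chromosome_is_unlinked(self):
        assert distance_to_tss(iv("chr2", 100, 200), self.gene()) is None

    @given(s=st.integers(0, 3000), l=st.integers(1, 100), tss=st.integers(100, 3000))
    @settings(max_examples=200, derandomize=True)
    def test_matches_min_over_bases(self, s, l, tss):
        d = distance_to_tss(iv("chr1", s, s + l), self.gene(tss=tss))
        assert d == min(abs(b - tss) for b in range(s, s + l))


class TestBedIO:
    def test_round_trip(self, tmp_path):
        records = [
            BedRecord(GenomicInterval("chr1", 99, 200, "+"), "a", 5.0),
            BedRecord(GenomicInterval("chr1", 300, 400, "-"), "b", 1.5),
            BedRecord(GenomicInterval("chr2", 0, 10, "."), "c", 0.0),
        ]
        path = tmp_path / "x.bed"
        write_bed(path, records)
        assert read_bed(path) == records

    def test_parse_line(self):
        recs = read_bed(io.StringIO("chr1\t99\t200\t.\t5\t+\n"))
        assert recs[0].interval == GenomicInterval("chr1", 99, 200, "+")
        assert recs[0].score == 5.0

    @pytest.mark.parametrize(
        "line,match",
        [
            ("chr1\t200\t100\t.\t0\t+\n", "end 100 <= start 200"),
            ("chr1\t-5\t100\n", "non-integer|negative"),
            ("chr1\t5\t100\t.\t0\t?\n", "strand"),
        ],
    )
    def test_malformed_lines_report_position(self, line, match):
        with pytest.raises(ParseError, match="1:"):
            read_bed(io.StringIO(line))

    def test_bedpe_needs_fdr_column(self, tmp_path):
        p = tmp_path / "x.bedpe"
        p.write_text("chr1\t0\t5000\tchr1\t10000\t15000\n")
        with pytest.raises(ParseError, match="7 columns"):
            read_bedpe(p)
        p.write_text("chr1\t0\t5000\tchr1\t10000\t15000\t0.004\n")
        a1, a2, fdr = read_bedpe(p)[0]
        assert (a1.start, a2.start, fdr) == (0, 10000, 0.004)


class TestCoverageTrack:
    def test_per_base_sum(self, tmp_path):
        p = tmp_path / "x.bedGraph"
        p.write_text("chr1\t0\t10\t10\nchr1\t10\t20\t0\nchr1\t20\t30\t3\n")
        track = read_bedgraph(p)
        assert track.total_coverage == 10 * 10 + 0 * 10 + 3 * 10
        assert track.mean_depth(iv("chr1", 0, 30)) == pytest.approx(13 / 3)

    def test_rejects_overlapping_steps(self):
        with pytest.raises(ValueError, match="overlapping"):
            CoverageTrack([(iv("chr1", 0, 10), 1.0), (iv("chr1", 5, 15), 1.0)])

    def test_missing_chromosome_named(self):
        track = CoverageTrack([(iv("chr1", 0, 10), 1.0)])
        with pytest.raises(KeyError, match="chr9"):
            track.mean_depth(iv("chr9", 0, 5))

    def test_rpm_uses_library_size(self):
        track = CoverageTrack([(iv("chr1", 0, 100), 4.0)], library_size=2e6)
        assert track.mean_rpm(iv("chr1", 0, 100)) == pytest.approx(2.0)
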