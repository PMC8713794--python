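"""Gene locus windows, loop linkage, and the distal fraction."""

import pytest

from preatlas.catalog import OccupancyVector, PutativeRegulatoryElement
from preatlas.interactome import (
    BinPairInteraction,
    build_interactome,
    build_locus,
    count_gene_links,
    distal_fraction,
    loops_from_bedpe,
    promoter_bin,
)
from preatlas.intervals import DEFAULT_TFS, GeneModel, GenomicInterval


def gene(gene_id="g1", chrom="chr1", start=500_000, end=520_000, strand="+"):
    tss = start if strand == "+" else end - 1
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), tss, strand)


def pre(pre_id, chrom, start, end, count=3):
    bound = {tf: i < count for i, tf in enumerate(DEFAULT_TFS)}
    return PutativeRegulatoryElement(
        pre_id, GenomicInterval(chrom, start, end), OccupancyVector(bound)
    )


def loop(chrom, bin1, bin2, res=5000, fdr=0.001):
    return BinPairInteraction(
        GenomicInterval(chrom, bin1 * res, (bin1 + 1) * res),
        GenomicInterval(chrom, bin2 * res, (bin2 + 1) * res),
        resolution=res,
        fdr=fdr,
    )


class TestBinPairValidation:
    def test_anchor_must_match_resolution(self):
        with pytest.raises(ValueError, match="length != resolution"):
            BinPairInteraction(
                GenomicInterval("chr1", 0, 4000),
                GenomicInterval("chr1", 10000, 15000),
                resolution=5000, fdr=0.001,
            )

    def test_anchor_must_be_bin_aligned(self):
        with pytest.raises(ValueError, match="not aligned"):
            BinPairInteraction(
                GenomicInterval("chr1", 2500, 7500),
                GenomicInterval("chr1", 10000, 15000),
                resolution=5000, fdr=0.001,
            )

    def test_fdr_filter_applied_on_load(self):
        rows = [
            (GenomicInterval("chr1", 0, 5000), GenomicInterval("chr1", 10000, 15000), 0.005),
            (GenomicInterval("chr1", 0, 5000), GenomicInterval("chr1", 20000, 25000), 0.02),
        ]
        loops = loops_from_bedpe(rows, resolution=5000)
        assert len(loops) == 1 and loops[0].fdr == 0.005


class TestBuildLocus:
    def test_window_member_without_loops(self):
        g = gene()  # TSS at 500,000
        p = pre("p1", "chr1", 450_000, 450_500)  # 50 kb upstream of body
        locus = build_locus(g, [], [p])
        assert locus.members == {"p1": {"window"}}
        assert locus.window.start == 400_000
        assert locus.window.end == 620_000

    def test_loop_extends_window_and_links(self):
        g = gene()  # promoter bin = bin 100 at 5 kb
        p = pre("p1", "chr1", 801_000, 801_400)  # bin 160, 300 kb away
        lp = loop("chr1", 100, 160)
        locus = build_locus(g, [lp], [p])
        assert "loop5k" in locus.members["p1"]
        assert locus.window.end >= 805_000

    def test_promoter_bin_miss_by_one_bin_no_link(self):
        g = gene()
        p = pre("p1", "chr1", 801_000, 801_400)
        lp = loop("chr1", 99, 160)  # promoter-side anchor one bin short
        locus = build_locus(g, [lp], [p])
        assert locus.members.get("p1", set()) == set()

    def test_promoter_slop_recovers_neighbour_bin(self):
        g = gene()
        p = pre("p1", "chr1", 801_000, 801_400)
        lp = loop("chr1", 99, 160)
        locus = build_locus(g, [lp], [p], promoter_slop_bins=1)
        assert "loop5k" in locus.members["p1"]

    def test_anchor_swap_symmetry(self):
        g = gene()
        p = pre("p1", "chr1", 801_000, 801_400)
        fwd = build_locus(g, [loop("chr1", 100, 160)], [p])
        rev = build_locus(g, [loop("chr1", 160, 100)], [p])
        assert fwd.members == rev.members
        assert fwd.window == rev.window

    def test_window_monotone_under_added_loops(self):
        g = gene()
        pres = [pre("p1", "chr1", 450_000, 450_500),
                pre("p2", "chr1", 901_000, 901_400)]
        base = build_locus(g, [], pres)
        more = build_locus(g, [loop("chr1", 100, 180)], pres)
        assert more.window.start <= base.window.start
        assert more.window.end >= base.window.end
        assert set(base.members) <= set(more.members)

    def test_computational_links_tagged_and_validated(self):
        g = gene()
        p = pre("p1", "chr2", 0, 500)  # different chromosome, outside window
        locus = build_locus(g, [], [p], computational_links={"g1": ["p1"]})
        assert locus.members["p1"] == {"computational"}
        with pytest.raises(ValueError, match="unknown pRE"):
            build_locus(g, [], [p], computational_links={"g1": ["nope"]})

    def test_resolution_mismatch_rejected(self):
        g = gene()
        lp = loop("chr1", 50, 80, res=10000)
        with pytest.raises(ValueError, match="resolution"):
            build_locus(g, [lp], [], resolution=5000)


class TestDistalFraction:
    def test_all_distal(self):
        g = gene()
        loops = [loop("chr1", 100, 160), loop("chr1", 100, 200)]
        assert distal_fraction(loops, [g]) == 1.0

    def test_three_of_four(self):
        # TSS at 504,000 sits in bin 100; the contact bin 101 starts at
        # 505,000, so its nearest edge is 1,000 bp from the TSS: proximal.
        # The three far contacts are distal.
        g = GeneModel(
            "g2", GenomicInterval("chr1", 504_000, 530_000, "+"), 504_000, "+"
        )
        loops = [
            loop("chr1", 100, 101),
            loop("chr1", 100, 160),
            loop("chr1", 100, 200),
            loop("chr1", 100, 300),
        ]
        assert distal_fraction(loops, [g]) == 0.75

    def test_boundary_exactly_2500_counts_distal(self):
        # TSS 2,500 bp before the contact anchor's nearest edge
        g = GeneModel(
            "g", GenomicInterval("chr1", 502_500, 530_000, "+"), 502_500, "+"
        )
        lp = loop("chr1", 100, 101)  # anchor starts at 505,000
        assert distal_fraction([lp], [g]) == 1.0
        g_closer = GeneModel(
            "g", GenomicInterval("chr1", 502_501, 530_000, "+"), 502_501, "+"
        )
        assert distal_fraction([lp], [g_closer]) == 0.0

    def test_requires_loops(self):
        with pytest.raises(ValueError, match="loop"):
            distal_fraction([], [gene()])


class TestCountGeneLinks:
    def test_thresholds(self):
        g1, g2 = gene("g1"), gene("g2", chrom="chr2")
        p_hi = pre("p1", "chr1", 450_000, 450_500, count=5)
        p_lo = pre("p2", "chr2", 450_000, 450_500, count=2)
        loci = build_interactome([g1, g2], [], [p_hi, p_lo])
        flags, tally = count_gene_links(loci, [p_hi, p_lo], min_occupancy=3)
        assert flags == {"g1": True, "g2": False}
        assert tally == 1

    def test_toy_network_tally(self):
        genes, pres = [], []
        for i in range(38):
            g = gene(f"g{i}", chrom=f"chr{i + 1}", start=500_000, end=520_000)
            genes.append(g)
            if i < 30:
                pres.append(pre(f"p{i}", f"chr{i + 1}", 450_000, 450_500, count=4))
        loci = build_interactome(genes, [], pres)
        _, tally = count_gene_links(loci, pres, min_occupancy=3)
        assert tally == 30


def test_5k_links_subset_of_10k_links(catalog, dataset):
    """Coarsening 5-kb loops to 10-kb bins can only add members."""
    genes = dataset.genes
    loops5 = dataset.loops
    coarse = {}
    for lp in loops5:
        key = (
            lp.anchor1.chrom, lp.anchor1.start // 10000,
            lp.anchor2.chrom, lp.anchor2.start // 10000,
        )
        coarse.setdefault(key, lp.fdr)
    loops10 = [
        BinPairInteraction(
            GenomicInterval(c1, b1 * 10000, (b1 + 1) * 10000),
            GenomicInterval(c2, b2 * 10000, (b2 + 1) * 10000),
            resolution=10000, fdr=fdr,
        )
        for (c1, b1, c2, b2), fdr in coarse.items()
    ]
    fine = build_interactome(genes, loops5, catalog, resolution=5000)
    broad = build_interactome(genes, loops10, catalog, resolution=10000)
    for gid in fine:
        fine_loop = {p for p, t in fine[gid].members.items() if "loop5k" in t}
        broad_loop = {p for p, t in broad[gid].members.items() if "loop10k" in t}
        assert fine_loop <= broad_loop
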