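"""WT-vs-mutant differential calls, tallies, locus direction, concordance."""

import numpy as np
import pytest

from preatlas.catalog import OccupancyVector, PutativeRegulatoryElement
from preatlas.chromatin import ChromatinStateCall
from preatlas.differential import (
    DifferentialCall,
    LocusDirection,
    RnaDirectionRecord,
    binding_association,
    call_differential,
    concordance,
    locus_direction,
    tally_differential,
)
from preatlas.interactome import GeneLocus
from preatlas.intervals import (
    CoverageTrack,
    DEFAULT_TFS,
    GeneModel,
    GenomicInterval,
)


def pre(pre_id, start, end, count=1, chrom="chr1"):
    bound = {tf: i < count for i, tf in enumerate(DEFAULT_TFS)}
    return PutativeRegulatoryElement(
        pre_id, GenomicInterval(chrom, start, end), OccupancyVector(bound)
    )


def flat_track(depths, chrom="chr1", step=1000, library_size=1e6):
    """One step of ``step`` bp per depth value, abutting."""
    steps = [
        (GenomicInterval(chrom, i * step, (i + 1) * step), float(d))
        for i, d in enumerate(depths)
    ]
    return CoverageTrack(steps, library_size=library_size)


class TestCallDifferential:
    def test_identical_tracks_no_change(self):
        pres = [pre("p1", 0, 1000), pre("p2", 1000, 2000)]
        track = flat_track([10, 20])
        calls = call_differential(pres, track, track, "H3K27ac", "Emx2-KO")
        assert all(c.call == "NoChange" and c.log2fc == 0 for c in calls)

    def test_doubling_is_gain_at_boundary(self):
        pres = [pre("p1", 0, 1000)]
        wt = flat_track([10])
        # exact doubling with the pseudocount held: (2x + e)/(x + e) < 2,
        # so double (x + e) instead to land exactly on log2fc = 1
        mut = flat_track([2 * (10 + 0.25) - 0.25])
        (call,) = call_differential(pres, wt, mut, "H3K27ac", "Emx2-KO")
        assert call.log2fc == pytest.approx(1.0)
        assert call.call == "Gain"  # boundary inclusive

    def test_extinction_is_loss(self):
        pres = [pre("p1", 0, 1000)]
        (call,) = call_differential(
            pres, flat_track([10]), flat_track([0]), "H3K27ac", "Emx2-KO"
        )
        assert call.call == "Loss"
        assert np.isfinite(call.log2fc) and call.log2fc < -5

    def test_min_rpm_floor_forces_no_change(self):
        pres = [pre("p1", 0, 1000)]
        (call,) = call_differential(
            pres, flat_track([0.2]), flat_track([0.8]), "ATAC", "Emx2-KO"
        )
        assert call.call == "NoChange"

    def test_swap_symmetry_flips_all_calls(self, dataset, catalog):
        wt = dataset.tracks[("H3K27ac", "WT")]
        mut = dataset.tracks[("H3K27ac", "Pax6-KO")]
        fwd = call_differential(catalog, wt, mut, "H3K27ac", "Pax6-KO")
        rev = call_differential(catalog, mut, wt, "H3K27ac", "Pax6-KO")
        flip = {"Gain": "Loss", "Loss": "Gain", "NoChange": "NoChange"}
        for a, b in zip(fwd, rev):
            assert b.call == flip[a.call]
            assert b.log2fc == pytest.approx(-a.log2fc, abs=1e-9)

    def test_threshold_monotone(self):
        pres = [pre(f"p{i}", i * 1000, (i + 1) * 1000) for i in range(6)]
        wt = flat_track([10] * 6)
        mut = flat_track([10, 15, 25, 45, 5, 2])
        loose = call_differential(pres, wt, mut, "ATAC", "Emx2-KO", tau=0.5)
        strict = call_differential(pres, wt, mut, "ATAC", "Emx2-KO", tau=2.0)
        for a, b in zip(loose, strict):
            if b.call != "NoChange":
                assert a.call == b.call

    def test_missing_chromosome_named(self):
        pres = [pre("p1", 0, 1000, chrom="chr7")]
        with pytest.raises(KeyError, match="chr7"):
            call_differential(
                pres, flat_track([10]), flat_track([10]), "ATAC", "Emx2-KO"
            )


class TestTally:
    def make_calls(self, n_loss, n_nochange, n_gain, mark="H3K27ac"):
        calls = []
        i = 0
        for call_type, n in (
            ("Loss", n_loss), ("NoChange", n_nochange), ("Gain", n_gain)
        ):
            for _ in range(n):
                lfc = {"Loss": -2.0, "NoChange": 0.0, "Gain": 2.0}[call_type]
                calls.append(
                    DifferentialCall(
                        f"p{i}", mark, "Pax6-KO", lfc, call_type, 10.0, 10.0
                    )
                )
                i += 1
        return calls

    def test_81_of_118_is_69_percent(self):
        calls = self.make_calls(81, 37, 0)
        tally = tally_differential(calls)
        assert tally.loc["H3K27ac", "n_assessed"] == 118
        assert tally.loc["H3K27ac", "pct_loss"] == 69

    def test_no_differential_calls_is_all_no_change(self):
        tally = tally_differential(self.make_calls(0, 25, 0))
        assert tally.loc["H3K27ac", "pct_nochange"] == 100

    def test_permutation_invariance(self):
        calls = self.make_calls(5, 10, 3)
        t1 = tally_differential(calls)
        t2 = tally_differential(calls[::-1])
        assert t1.equals(t2)

    def test_assessed_denominator_uses_wt_marks(self):
        calls = self.make_calls(2, 8, 0)
        wt_states = [
            ChromatinStateCall(f"p{i}", accessible=False,
                               active=(i < 6), repressed=False)
            for i in range(10)
        ]
        tally = tally_differential(calls, wt_states=wt_states, catalog_size=10)
        # assessed = WT-marked (6) plus unmarked pREs with a call (p0, p1
        # are Loss and WT-marked already) -> 6
        assert tally.loc["H3K27ac", "n_assessed"] == 6
        assert tally.loc["H3K27ac", "pct_loss_of_catalog"] == 20

    def test_one_mutant_at_a_time(self):
        calls = self.make_calls(1, 1, 0) + [
            DifferentialCall("x", "ATAC", "Emx2-KO", 0.0, "NoChange", 1.0, 1.0)
        ]
        with pytest.raises(ValueError, match="one mutant"):
            tally_differential(calls)


class TestLocusDirection:
    def locus(self, gene_id, member_ids):
        g = GeneModel(gene_id, GenomicInterval("chr1", 0, 10_000, "+"), 0, "+")
        return GeneLocus(
            gene=g, window=GenomicInterval("chr1", 0, 100_000),
            members={m: {"window"} for m in member_ids},
        )

    def call(self, pre_id, mark, call_type, mutant="Pax6-KO"):
        lfc = {"Loss": -2.0, "Gain": 2.0, "NoChange": 0.0}[call_type]
        return DifferentialCall(pre_id, mark, mutant, lfc, call_type, 10.0, 10.0)

    def test_two_ac_losses_repressed(self):
        loci = {"g1": self.locus("g1", ["p1", "p2"])}
        calls = [self.call("p1", "H3K27ac", "Loss"),
                 self.call("p2", "H3K27ac", "Loss")]
        (d,) = locus_direction(loci, calls, "Pax6-KO")
        assert d.score == -2 and d.direction == "repressed"

    def test_gain_plus_me3_loss_activated(self):
        loci = {"g1": self.locus("g1", ["p1", "p2"])}
        calls = [self.call("p1", "H3K27ac", "Gain"),
                 self.call("p2", "H3K27me3", "Loss")]
        (d,) = locus_direction(loci, calls, "Pax6-KO")
        assert d.score == 2 and d.direction == "activated"

    def test_opposing_histone_losses_cancel(self):
        loci = {"g1": self.locus("g1", ["p1", "p2"])}
        calls = [self.call("p1", "H3K27ac", "Loss"),
                 self.call("p2", "H3K27me3", "Loss")]
        (d,) = locus_direction(loci, calls, "Pax6-KO")
        assert d.score == 0 and d.direction == "mixed/none"

    def test_atac_only_counts_when_enabled(self):
        loci = {"g1": self.locus("g1", ["p1"])}
        calls = [self.call("p1", "ATAC", "Loss")]
        (d0,) = locus_direction(loci, calls, "Pax6-KO")
        assert d0.score == 0 and d0.n_differential_pres == 0
        (d1,) = locus_direction(loci, calls, "Pax6-KO", include_atac=True)
        assert d1.score == -1 and d1.n_differential_pres == 1


class TestConcordance:
    def dirs(self, spec, mutant="Nr2f1-KO"):
        return [
            LocusDirection(g, mutant, score, n_diff)
            for g, (score, n_diff) in spec.items()
        ]

    def test_13_of_19_is_68_percent(self):
        spec = {f"g{i}": (-1, 1) for i in range(13)}
        spec.update({f"g{i}": (1, 1) for i in range(13, 19)})
        rna = [RnaDirectionRecord(f"g{i}", "Nr2f1-KO", "-") for i in range(19)]
        res = concordance(self.dirs(spec), rna, "Nr2f1-KO")
        assert (res["n_matches"], res["n_assessed"]) == (13, 19)
        assert res["rate_pct"] == 68

    def test_loci_without_differential_pres_not_assessed(self):
        spec = {"g0": (-1, 1), "g1": (0, 0)}
        rna = [RnaDirectionRecord("g0", "Nr2f1-KO", "-"),
               RnaDirectionRecord("g1", "Nr2f1-KO", "-")]
        res = concordance(self.dirs(spec), rna, "Nr2f1-KO")
        assert res["n_assessed"] == 1

    def test_zero_assessed_reports_na(self):
        res = concordance([], [RnaDirectionRecord("g", "Nr2f1-KO", "0")],
                          "Nr2f1-KO")
        assert res["rate_pct"] is None

    def test_rna_level_validation_and_direction(self):
        assert RnaDirectionRecord("g", "Emx2-KO", "++").direction == "up"
        assert RnaDirectionRecord("g", "Emx2-KO", "--").direction == "down"
        assert RnaDirectionRecord("g", "Emx2-KO", "0").direction == "none"
        with pytest.raises(ValueError, match="level"):
            RnaDirectionRecord("g", "Emx2-KO", "+++")


class TestBindingAssociation:
    def test_all_loss_bound_extreme(self):
        pres = [pre(f"p{i}", i * 1000, i * 1000 + 100,
                    count=(1 if i < 3 else 0)) for i in range(6)]
        calls = [
            DifferentialCall(f"p{i}", "H3K27ac", "Emx2-KO",
                             -2.0 if i < 3 else 0.0,
                             "Loss" if i < 3 else "NoChange", 10.0, 10.0)
            for i in range(6)
        ]
        res = binding_association(calls, pres, tf="EMX2", mark="H3K27ac")
        assert res["fraction_bound"]["Loss"] == pytest.approx(1.0)
        assert res["fraction_bound"]["NoChange"] == pytest.approx(0.0)
        assert res["fraction_bound"]["Gain"] is None

    def test_planted_rates_recovered(self):
        """0.7 bound in Loss vs 0.3 elsewhere at n=300: recovered +-0.07."""
        rng = np.random.default_rng(29)
        pres, calls = [], []
        for i in range(300):
            is_loss = i < 100
            bound = rng.random() < (0.7 if is_loss else 0.3)
            pres.append(pre(f"p{i}", i * 1000, i * 1000 + 100,
                            count=1 if bound else 0))
            calls.append(
                DifferentialCall(
                    f"p{i}", "H3K27ac", "Emx2-KO",
                    -2.0 if is_loss else 0.0,
                    "Loss" if is_loss else "NoChange", 10.0, 10.0,
                )
            )
        res = binding_association(calls, pres, tf="EMX2", mark="H3K27ac")
        assert res["fraction_bound"]["Loss"] == pytest.approx(0.7, abs=0.07)
        assert res["fraction_bound"]["NoChange"] == pytest.approx(0.3, abs=0.07)
        assert res["fisher_p_loss_vs_rest"] < 0.01

    def test_unknown_tf_rejected(self):
        with pytest.raises(ValueError, match="registry"):
            binding_association([], [], tf="SOX2", mark="H3K27ac")
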