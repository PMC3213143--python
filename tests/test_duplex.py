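import numpy as np
import pytest

from erisift import duplex_phasing as dp
from erisift.io import Feature
from erisift.mapper import LibraryScale, MappedLibrary, MappedRead


def make_library(reads, total=None):
    total = total or sum(r.count for r in reads)
    return MappedLibrary(reads=reads, scale=LibraryScale(total))


def guide_at(start, strand="-", chrom="chr1", count=10):
    return MappedRead("G" + "A" * 25, count, [(chrom, start, strand)])


class TestFindPassenger:
    def test_canonical_geometry_minus_strand_guide(self):
        """Guide at [100,126) on '-', sense read at [103,122): canonical
        geometry (passenger 19 nt, inset3 3 at the genomic left = guide 3'
        side, inset5 4)."""
        guide = guide_at(100)
        passenger = MappedRead("C" * 19, 2, [("chr1", 103, "+")])
        lib = make_library([guide, passenger])
        rec = dp.find_passenger(guide, guide.loci[0], lib)
        assert rec.window == (86, 140)
        assert (rec.passenger_length, rec.inset3, rec.inset5) == (19, 3, 4)
        assert rec.ratio == pytest.approx(2 / 10)

    def test_strand_symmetry(self):
        """Mirrored (+ strand) guide yields identical duplex geometry."""
        guide = MappedRead("G" + "A" * 25, 10, [("chr1", 100, "+")])
        passenger = MappedRead("C" * 19, 2, [("chr1", 104, "-")])  # [104,123)
        lib = make_library([guide, passenger])
        rec = dp.find_passenger(guide, guide.loci[0], lib)
        assert (rec.passenger_length, rec.inset3, rec.inset5) == (19, 3, 4)

    def test_no_candidate_means_absent_passenger(self):
        guide = guide_at(100)
        outside = MappedRead("C" * 19, 50, [("chr1", 200, "+")])
        lib = make_library([guide, outside])
        rec = dp.find_passenger(guide, guide.loci[0], lib)
        assert not rec.has_passenger and rec.ratio == 0.0

    def test_candidate_must_lie_fully_inside_window(self):
        guide = guide_at(100)
        straddling = MappedRead("C" * 19, 5, [("chr1", 130, "+")])  # ends at 149 > 140
        lib = make_library([guide, straddling])
        assert not dp.find_passenger(guide, guide.loci[0], lib).has_passenger

    def test_most_abundant_candidate_wins(self):
        guide = guide_at(100)
        weak = MappedRead("C" * 19, 2, [("chr1", 103, "+")])
        strong = MappedRead("T" * 20, 9, [("chr1", 110, "+")])
        lib = make_library([guide, weak, strong])
        rec = dp.find_passenger(guide, guide.loci[0], lib)
        assert rec.passenger_sequence == "T" * 20

    def test_tie_breaks_by_inset3_closest_to_3(self):
        guide = guide_at(100)
        at_three = MappedRead("C" * 19, 10, [("chr1", 103, "+")])  # inset3 = 3
        at_one = MappedRead("T" * 19, 10, [("chr1", 101, "+")])  # inset3 = 1
        lib = make_library([guide, at_one, at_three])
        rec = dp.find_passenger(guide, guide.loci[0], lib)
        assert rec.inset3 == 3 and rec.passenger_sequence == "C" * 19

    def test_protruding_passenger_records_negative_inset(self):
        guide = guide_at(100)
        protruding = MappedRead("C" * 26, 5, [("chr1", 98, "+")])  # [98,124)
        lib = make_library([guide, protruding])
        rec = dp.find_passenger(guide, guide.loci[0], lib)
        assert rec.inset3 == -2 and rec.inset5 == 2

    def test_unmapped_guide_locus_errors(self):
        guide = guide_at(100)
        lib = make_library([guide])
        with pytest.raises(ValueError, match="not mapped"):
            dp.find_passenger(guide, ("chr1", 999, "-"), lib)

    def test_candidates_equal_bruteforce_scan(self):
        """The sorted-index window query agrees with a brute-force scan of
        every read locus, over many random layouts."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            guide = guide_at(int(rng.integers(50, 900)))
            reads = [guide]
            for _i in range(int(rng.integers(1, 12))):
                L = int(rng.integers(18, 27))
                start = int(rng.integers(0, 1000))
                strand = "+" if rng.random() < 0.5 else "-"
                seq = "".join(rng.choice(list("ACGT"), L))
                reads.append(MappedRead(seq, int(rng.integers(1, 20)), [("chr1", start, strand)]))
            lib = make_library(reads)
            index = dp._StrandIndex(lib)
            lo, hi = guide.loci[0][1] - 14, guide.loci[0][1] + 26 + 14
            got = sorted(index.within("chr1", "+", lo, hi))
            expected = sorted(
                (s, s + len(mr.sequence), mr.sequence, mr.weight_per_locus)
                for mr in reads
                for c, s, strand in mr.loci
                if strand == "+" and s >= lo and s + len(mr.sequence) <= hi
            )
            assert got == expected


class TestConsensus:
    def test_uniform_geometry_is_the_consensus(self):
        guide = guide_at(100)
        passenger = MappedRead("C" * 19, 2, [("chr1", 103, "+")])
        lib = make_library([guide, passenger])
        recs = [dp.find_passenger(guide, guide.loci[0], lib)] * 4
        cons = dp.duplex_consensus(recs, guide_rpm_threshold=0.0)
        assert (cons.modal_passenger_length, cons.modal_inset3, cons.modal_inset5) == (19, 3, 4)
        assert cons.fraction_with_passenger == 1.0

    def test_empty_record_set_errors(self):
        with pytest.raises(ValueError):
            dp.duplex_consensus([])

    def test_jitter_free_simulation_recovers_exact_geometry(self):
        """With inset5 jitter off, every inferred duplex is exactly
        (19, 3, 4) and matches the generator's truth intervals."""
        from erisift import simdata
        from erisift.mapper import map_reads

        cfg = simdata.SimulationConfig(
            seed=42,
            inset5_jitter=0.0,
            library_depth=60_000,
            libraries=(("wt", "embryo"),),
        )
        genome, libs, truth = simdata.simulate(cfg)
        lib = map_reads(libs[("wt", "embryo")], genome.chroms)
        guides = []
        for f in genome.features:
            if f.truth_class == "ergo1_target":
                guides.extend(dp.guides_for_feature(f, lib))
        records = dp.find_passengers(guides, lib)
        assert records
        for rec in records:
            if rec.has_passenger:
                assert (rec.passenger_length, rec.inset3, rec.inset5) == (19, 3, 4)
        truth_pass = set(
            zip(truth.guides["chrom"], truth.guides["passenger_start"].astype(int))
        )
        found = {
            (r.passenger_locus[0], r.passenger_locus[1])
            for r in records
            if r.has_passenger
        }
        assert found <= truth_pass

    def test_default_wt_embryo_consensus(self, duplex_records_default):
        cons = dp.duplex_consensus(duplex_records_default[("wt", "embryo")])
        assert cons.modal_inset3 == 3
        assert cons.modal_passenger_length == 19
        assert cons.modal_inset5 == 4
        assert cons.median_ratio == pytest.approx(0.05, abs=0.02)

    def test_passenger_detection_drops_with_guide_depletion(
        self, duplex_records_default
    ):
        """In eri-1 embryos both duplex strands are co-depleted, so far
        fewer guide loci retain a detectable passenger."""
        wt = dp.duplex_consensus(duplex_records_default[("wt", "embryo")])
        eri1 = dp.duplex_consensus(duplex_records_default[("eri-1", "embryo")])
        assert eri1.fraction_with_passenger < 0.5 * wt.fraction_with_passenger


class TestFoldchange:
    def test_identity(self):
        guide = guide_at(100)
        passenger = MappedRead("C" * 19, 2, [("chr1", 103, "+")])
        lib = make_library([guide, passenger])
        recs = [dp.find_passenger(guide, guide.loci[0], lib)]
        assert dp.passenger_foldchange(recs, recs) == pytest.approx(1.0)

    def test_zero_wt_total_errors(self):
        guide = guide_at(100)
        lib = make_library([guide])
        recs = [dp.find_passenger(guide, guide.loci[0], lib)]
        with pytest.raises(ValueError):
            dp.passenger_foldchange(recs, recs)

    def test_ergo1_stabilization_and_eri7_codepletion(self, duplex_records_default):
        wt = duplex_records_default[("wt", "embryo")]
        assert dp.passenger_foldchange(
            wt, duplex_records_default[("ergo-1", "embryo")]
        ) == pytest.approx(2.0, abs=0.3)
        assert (
            dp.passenger_foldchange(wt, duplex_records_default[("eri-7", "embryo")])
            < 0.2
        )


class TestPhasing:
    FEAT = Feature("g", "chr1", "+", [(0, 200)], "coding")

    def test_regular_intervals(self):
        guides = [
            (MappedRead("G" + "A" * 25, 1, [("chr1", s, "-")]), ("chr1", s, "-"))
            for s in (0, 26, 52)
        ]
        # 5' end of a '-' guide is its right edge: positions 25, 51, 77
        prof = dp.phasing_profile(self.FEAT, guides)
        assert prof.intervals == [26, 26]
        assert prof.fraction_in_band == 1.0
        assert prof.histogram == {26: 2}

    def test_single_guide_has_undefined_fraction(self):
        guides = [(MappedRead("G" + "A" * 25, 1, [("chr1", 0, "-")]), ("chr1", 0, "-"))]
        prof = dp.phasing_profile(self.FEAT, guides)
        assert prof.intervals == [] and prof.fraction_in_band is None

    def test_minus_strand_feature_uses_template_coordinates(self):
        feat = Feature("g2", "chr1", "-", [(0, 200)], "coding")
        guides = [
            (MappedRead("G" + "A" * 25, 1, [("chr1", s, "+")]), ("chr1", s, "+"))
            for s in (100, 74, 48)
        ]
        prof = dp.phasing_profile(feat, guides)
        assert prof.intervals == [26, 26]

    def test_simulated_phasing_within_band(self, default_dataset, mapped_default):
        """Generated 23-29 nt spacing is recovered: >= 90% of successive
        intervals fall in [23, 29] on simulated target genes."""
        genome, _, _ = default_dataset
        lib = mapped_default[("wt", "embryo")]
        fracs = []
        for feat in genome.features:
            if feat.truth_class != "ergo1_target":
                continue
            prof = dp.phasing_profile(feat, dp.guides_for_feature(feat, lib))
            if prof.fraction_in_band is not None:
                fracs.append(prof.fraction_in_band)
        assert fracs and float(np.mean(fracs)) >= 0.9
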