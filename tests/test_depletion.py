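import numpy as np
import pandas as pd
import pytest

from erisift import depletion
from erisift.classify import LibraryProfile
from erisift.depletion import (
    call_overlap,
    call_sirnas,
    call_targets,
    class_depletion,
    window_starts,
    window_track,
)
from erisift.io import CollapsedRead, Feature
from erisift.mapper import map_reads


def make_profile(feature_rpm, guide_rpm=None, class_rpm=None, genotype="x"):
    """Minimal LibraryProfile for threshold-logic tests."""
    ft = pd.DataFrame(
        {
            "sense_rpm": 0.0,
            "antisense_rpm": pd.Series(feature_rpm, dtype=float),
            "antisense_26g_rpm": 0.0,
            "antisense_22g_rpm": 0.0,
        }
    )
    ft.index.name = "feature"
    gt = pd.DataFrame(
        {"rpm": pd.Series(guide_rpm or {}, dtype=float), "n_loci": 1}
    )
    gt.index.name = "sequence"
    return LibraryProfile(
        genotype=genotype,
        stage="embryo",
        matrix=pd.DataFrame(),
        feature_table=ft,
        class_rpm=class_rpm or {},
        guide_table=gt,
        library=None,
        annotation=None,
    )


class TestCallTargets:
    def test_below_wt_threshold_not_called(self):
        wt = make_profile({"f1": 9.9})
        mut = make_profile({"f1": 0.0})
        assert call_targets(wt, {"m": mut}, require={"m"}) == []

    def test_one_failing_genotype_blocks_the_call(self):
        wt = make_profile({"f1": 100.0})
        muts = {"eri-7": make_profile({"f1": 30.0}), "eri-1": make_profile({"f1": 50.0})}
        assert call_targets(wt, muts, require={"eri-7", "eri-1"}) == []
        # eri-7 alone qualifies
        assert len(call_targets(wt, muts, require={"eri-7"})) == 1

    def test_tie_at_one_third_passes(self):
        wt = make_profile({"f1": 90.0})
        mut = make_profile({"f1": 30.0})
        calls = call_targets(wt, {"m": mut}, require={"m"})
        assert [c.feature_id for c in calls] == ["f1"]

    def test_empty_require_gives_wt_threshold_set(self):
        wt = make_profile({"f1": 100.0, "f2": 5.0, "f3": 11.0})
        mut = make_profile({"f1": 100.0, "f2": 5.0, "f3": 11.0})
        calls = call_targets(wt, {"m": mut}, require=set())
        assert {c.feature_id for c in calls} == {"f1", "f3"}

    def test_missing_required_profile_errors(self):
        wt = make_profile({"f1": 100.0})
        with pytest.raises(ValueError, match="missing"):
            call_targets(wt, {}, require={"eri-7"})

    def test_sorted_by_wt_rpm_descending(self):
        wt = make_profile({"a": 50.0, "b": 500.0, "c": 20.0})
        mut = make_profile({"a": 0.0, "b": 0.0, "c": 0.0})
        calls = call_targets(wt, {"m": mut}, require={"m"})
        assert [c.feature_id for c in calls] == ["b", "a", "c"]

    def test_threshold_monotonicity(self):
        """Raising either threshold never adds a call."""
        rng = np.random.default_rng(7)
        wt = make_profile({f"f{i}": float(rng.uniform(0, 50)) for i in range(30)})
        mut = make_profile({f"f{i}": float(rng.uniform(0, 50)) for i in range(30)})
        base = {c.feature_id for c in call_targets(wt, {"m": mut}, require={"m"})}
        for thr in (15.0, 20.0, 40.0):
            got = {
                c.feature_id
                for c in call_targets(wt, {"m": mut}, rpm_threshold=thr, require={"m"})
            }
            assert got <= base
        for dep in (0.8, 0.9, 0.99):
            got = {
                c.feature_id
                for c in call_targets(wt, {"m": mut}, depletion=dep, require={"m"})
            }
            assert got <= base

    def test_default_simulation_recovers_truth_targets(
        self, profiles_default, ergo1_ids, default_dataset
    ):
        genome, _, _ = default_dataset
        wt = profiles_default[("wt", "embryo")]
        muts = {
            g: profiles_default[(g, "embryo")]
            for g in ("eri-6", "eri-7", "eri-1", "ergo-1")
        }
        calls = call_targets(wt, muts, require={"eri-7", "eri-1"})
        assert {c.feature_id for c in calls} == set(ergo1_ids)
        non_targets = {
            f.id for f in genome.features if f.truth_class in {"alg34_target", "csr1_wago"}
        }
        assert not ({c.feature_id for c in calls} & non_targets)


class TestCallSirnas:
    def test_below_threshold_excluded(self):
        wt = make_profile({}, guide_rpm={"G" * 26: 0.9})
        mut = make_profile({}, guide_rpm={"G" * 26: 0.0})
        assert call_sirnas(wt, {"m": mut}, require={"m"}) == []

    def test_fully_depleted_guide_called_with_zero_ratio(self):
        wt = make_profile({}, guide_rpm={"G" * 26: 5.0})
        mut = make_profile({}, guide_rpm={})
        calls = call_sirnas(wt, {"m": mut}, require={"m"})
        assert len(calls) == 1 and calls[0].ratio["m"] == 0.0

    def test_default_simulation_recovers_guides(self, profiles_default, default_dataset):
        """Nearly all true guides above 1 RPM are called as depleted in
        both eri-7 and eri-1 embryos."""
        _, _, truth = default_dataset
        wt = profiles_default[("wt", "embryo")]
        muts = {g: profiles_default[(g, "embryo")] for g in ("eri-7", "eri-1")}
        calls = call_sirnas(wt, muts, require={"eri-7", "eri-1"})
        called = {c.sequence for c in calls}
        truth_guides = set(
            truth.guides.loc[truth.guides["n_wt_embryo"] > 0, "sequence"]
        )
        assert len(called & truth_guides) / len(truth_guides) >= 0.95


class TestClassDepletion:
    def test_identical_profiles_give_zero(self):
        p = make_profile({}, class_rpm={"26G": 50.0})
        assert class_depletion(p, p, "26G") == pytest.approx(0.0)

    def test_fully_depleted_subset_gives_100(self):
        wt = make_profile({"f1": 40.0, "f2": 10.0})
        mut = make_profile({"f1": 0.0, "f2": 0.0})
        assert class_depletion(wt, mut, subset=["f1", "f2"]) == pytest.approx(100.0)

    def test_enrichment_is_negative(self):
        wt = make_profile({}, class_rpm={"26G": 10.0})
        mut = make_profile({}, class_rpm={"26G": 20.0})
        assert class_depletion(wt, mut, "26G") == pytest.approx(-100.0)

    def test_zero_wt_total_errors(self):
        wt = make_profile({}, class_rpm={"26G": 0.0})
        with pytest.raises(ValueError, match="zero"):
            class_depletion(wt, wt, "26G")

    def test_neither_class_nor_subset_errors(self):
        p = make_profile({})
        with pytest.raises(ValueError):
            class_depletion(p, p)


class TestWindows:
    def test_10kb_chromosome_has_six_windows(self):
        starts, widths = window_starts(10_000, 5000, 1000)
        assert starts.tolist() == [0, 1000, 2000, 3000, 4000, 5000]
        assert set(widths.tolist()) == {5000}

    def test_terminal_window_truncated(self):
        starts, widths = window_starts(10_400, 5000, 1000)
        assert starts.tolist() == [0, 1000, 2000, 3000, 4000, 5000, 6000]
        assert widths.tolist()[-1] == 4400
        assert all(b - a == 1000 for a, b in zip(starts, starts[1:]))

    def test_identical_libraries_give_flat_track(self):
        genome = {"chr1": "".join(np.random.default_rng(3).choice(list("ACGT"), 10_000))}
        reads = [CollapsedRead(genome["chr1"][i : i + 22], 5) for i in (100, 3000, 8000)]
        lib = map_reads(reads, genome)
        feats = [Feature("g", "chr1", "+", [(0, 10_000)], "coding")]
        from erisift import classify

        prof = classify.profile(lib, feats)
        tracks = window_track(prof, prof, {"chr1": 10_000})
        assert np.allclose(tracks["chr1"].log2_ratio, 0.0)

    def test_target_windows_drop_in_eri7(self, profiles_default, default_dataset):
        """Windows over simulated ERGO-1 target genes lose >4-fold signal
        in eri-7 embryos while background windows stay flat."""
        genome, _, _ = default_dataset
        wt = profiles_default[("wt", "embryo")]
        mut = profiles_default[("eri-7", "embryo")]
        tracks = window_track(wt, mut, genome.chrom_lengths, pseudocount=1.0)
        target_spans = [
            (f.chrom, f.start, f.end)
            for f in genome.features
            if f.truth_class == "ergo1_target"
        ]
        hit, background = [], []
        for chrom, t in tracks.items():
            for i, s in enumerate(t.starts):
                e = s + t.widths[i]
                over = any(
                    c == chrom and s < fe and e > fs for c, fs, fe in target_spans
                )
                (hit if over else background).append(t.log2_ratio[i])
        assert np.median(hit) < -2.0
        assert abs(np.median(background)) < 0.5


class TestOverlap:
    def test_overlap_is_symmetric(self):
        a = [_call(f"f{i}") for i in range(5)]
        b = [_call(f"f{i}") for i in range(3, 8)]
        shared_ab, only_a, only_b = call_overlap(a, b)
        shared_ba, only_b2, only_a2 = call_overlap(b, a)
        assert shared_ab == shared_ba and only_a == only_a2 and only_b == only_b2

    def test_printed_count_arithmetic(self):
        """78 embryo calls and 75 adult calls sharing 60 features leave
        18 embryo-only and 15 adult-only features."""
        embryo = [_call(f"s{i}") for i in range(60)] + [
            _call(f"e{i}") for i in range(18)
        ]
        adult = [_call(f"s{i}") for i in range(60)] + [
            _call(f"a{i}") for i in range(15)
        ]
        assert len(embryo) == 78 and len(adult) == 75
        shared, embryo_only, adult_only = call_overlap(embryo, adult)
        assert (len(shared), len(embryo_only), len(adult_only)) == (60, 18, 15)


def _call(fid):
    return depletion.TargetCall(
        feature_id=fid,
        wt_rpm=100.0,
        mutant_rpm={},
        ratio={},
        passes_wt_threshold=True,
        depleted_in=set(),
    )
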