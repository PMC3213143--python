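"""End-to-end orchestration: simulate -> map -> classify -> deplete ->
duplex/phasing -> homology, with one config, one seed, and a
deterministic consolidated JSON report."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import classify, depletion, duplex_phasing, homology, simdata
from .classify import AnnotationIndex, LibraryProfile
from .mapper import GenomeIndex, MappedLibrary, map_reads

log = logging.getLogger("erisift")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: simdata.SimulationConfig = field(default_factory=simdata.SimulationConfig)
    out_dir: Path = Path("erisift_run")
    rpm_threshold: float = 10.0
    sirna_rpm_threshold: float = 1.0
    depletion: float = 2 / 3
    identity_threshold: float = 82.0
    stretch_threshold: int = 27
    flank: int = 500
    duplex_flank: int = 14
    window_width: int = 5000
    window_step: int = 1000
    pseudocount: float = 1.0
    require_embryo: tuple[str, ...] = ("eri-7", "eri-1")
    require_adult: tuple[str, ...] = ("eri-7",)

    @property
    def seed(self) -> int:
        return self.sim.seed


def _stage_timer(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                log.error("stage %s: FAILED after %.1fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            log.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Timer()


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline and return (and write) the report bundle.

    Identical config + seed produce a byte-identical report file.
    Stage failures abort with the failing stage named; outputs written
    before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    with _stage_timer("simulate"):
        genome, libraries, truth = simdata.simulate(config.sim)
        simdata.write_dataset(genome, libraries, truth, out / "sim")
        report["stages"].append("simulate")

    with _stage_timer("map"):
        index = GenomeIndex(genome.chroms)
        mapped: dict[tuple[str, str], MappedLibrary] = {}
        for key, reads in libraries.items():
            mapped[key] = map_reads(reads, index)
        report["stages"].append("map")

    with _stage_timer("classify"):
        ann = AnnotationIndex(genome.features)
        profiles: dict[tuple[str, str], LibraryProfile] = {}
        for (genotype, stage), lib in mapped.items():
            profiles[(genotype, stage)] = classify.profile(
                lib, ann, genotype=genotype, stage=stage
            )
        report["class_rpm"] = {
            f"{g}_{s}": {k: v for k, v in p.class_rpm.items()}
            for (g, s), p in sorted(profiles.items())
        }
        report["stages"].append("classify")

    stage_genotypes = {
        s: sorted(g for g, s2 in profiles if s2 == s)
        for s in {s for _g, s in profiles}
    }
    calls = {}
    with _stage_timer("deplete"):
        depletion_matrix: dict[str, dict[str, float]] = {}
        for stage, genotypes in sorted(stage_genotypes.items()):
            if "wt" not in genotypes:
                continue
            wt = profiles[("wt", stage)]
            mutants = {
                g: profiles[(g, stage)] for g in genotypes if g != "wt"
            }
            if not mutants:
                report.setdefault("notices", []).append(
                    f"no mutant libraries for stage {stage}; depletion skipped"
                )
                continue
            for g, p in sorted(mutants.items()):
                row = depletion_matrix.setdefault(f"{g}_{stage}", {})
                for klass in ("26G", "22G", "mirna", "pirna"):
                    if wt.class_rpm[klass] > 0:
                        row[klass] = depletion.class_depletion(wt, p, klass)
            require = set(
                config.require_embryo if stage == "embryo" else config.require_adult
            ) & set(mutants)
            stage_calls = depletion.call_targets(
                wt,
                mutants,
                rpm_threshold=config.rpm_threshold,
                depletion=config.depletion,
                require=require,
            )
            calls[stage] = stage_calls
            depletion.write_target_calls(stage_calls, out / f"targets_{stage}.tsv")
            tracks_mut = sorted(mutants)[0]
            tracks = depletion.window_track(
                wt,
                mutants[tracks_mut],
                genome.chrom_lengths,
                width=config.window_width,
                step=config.window_step,
                pseudocount=config.pseudocount,
            )
            depletion.write_window_tracks(
                tracks, out / f"windows_{tracks_mut}_{stage}.tsv"
            )
        report["class_depletion_pct"] = depletion_matrix
        report["target_calls"] = {
            s: [c.feature_id for c in cs] for s, cs in sorted(calls.items())
        }
        if len(calls) == 2:
            shared, only_a, only_b = depletion.call_overlap(
                calls["embryo"], calls["adult"]
            )
            report["target_overlap"] = {
                "embryo_and_adult": sorted(shared),
                "embryo_only": sorted(only_a),
                "adult_only": sorted(only_b),
            }
        report["stages"].append("deplete")

    with _stage_timer("duplex"):
        duplex_summary = {}
        records_by_lib = {}
        for (genotype, stage), lib in sorted(mapped.items()):
            guides = []
            for feat in genome.features:
                if feat.truth_class in {"ergo1_target", "alg34_target"}:
                    guides.extend(duplex_phasing.guides_for_feature(feat, lib))
            if not guides:
                continue
            records = duplex_phasing.find_passengers(
                guides, lib, flank=config.duplex_flank
            )
            records_by_lib[(genotype, stage)] = records
            duplex_phasing.write_duplex_records(
                records, out / f"duplexes_{genotype}_{stage}.tsv"
            )
            cons = duplex_phasing.duplex_consensus(
                records, guide_rpm_threshold=config.sirna_rpm_threshold
            )
            duplex_summary[f"{genotype}_{stage}"] = {
                "modal_passenger_length": cons.modal_passenger_length,
                "modal_inset3": cons.modal_inset3,
                "modal_inset5": cons.modal_inset5,
                "median_ratio": cons.median_ratio,
                "fraction_with_passenger": cons.fraction_with_passenger,
                "n_records": cons.n_records,
            }
        if ("wt", "embryo") in records_by_lib:
            for g in ("eri-7", "ergo-1"):
                if (g, "embryo") in records_by_lib:
                    duplex_summary[f"passenger_foldchange_{g}_embryo"] = (
                        duplex_phasing.passenger_foldchange(
                            records_by_lib[("wt", "embryo")],
                            records_by_lib[(g, "embryo")],
                        )
                    )
        report["duplex"] = duplex_summary
        report["stages"].append("duplex")

    with _stage_timer("phasing"):
        phasing_summary = {}
        if ("wt", "embryo") in mapped:
            lib = mapped[("wt", "embryo")]
            fracs = []
            for feat in genome.features:
                if feat.truth_class != "ergo1_target":
                    continue
                prof = duplex_phasing.phasing_profile(
                    feat, duplex_phasing.guides_for_feature(feat, lib)
                )
                if prof.fraction_in_band is not None:
                    fracs.append(prof.fraction_in_band)
                    phasing_summary[feat.id] = {
                        "n_positions": len(prof.positions),
                        "fraction_in_band": prof.fraction_in_band,
                    }
            if fracs:
                phasing_summary["mean_fraction_in_band"] = sum(fracs) / len(fracs)
        report["phasing"] = phasing_summary
        report["stages"].append("phasing")

    with _stage_timer("homology"):
        target_ids = sorted(
            {c.feature_id for cs in calls.values() for c in cs}
        )
        target_feats = [genome.feature(i) for i in target_ids]
        hom_summary = {}
        if target_feats:
            edges = homology.build_edges(
                target_feats, genome.chroms, flank=config.flank
            )
            groups = homology.cluster(
                target_ids,
                edges,
                identity_threshold=config.identity_threshold,
                stretch_threshold=config.stretch_threshold,
            )
            hom_summary["groups"] = [sorted(g.members) for g in groups]
            hom_summary["n_qualifying_edges"] = sum(
                homology.qualifying_edge(
                    e, config.identity_threshold, config.stretch_threshold
                )
                for e in edges
            )
            hom_summary["structure"] = homology.gene_structure_stats(
                target_ids, genome.features
            )
        report["homology"] = hom_summary
        report["stages"].append("homology")

    report = _round_floats(report)
    payload = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(payload + "\n")
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    return report


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="[%(asctime)s] %(name)s %(levelname)s %(message)s",
    )
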