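"""Synthetic genome, annotation, and small-RNA library generator.

The generator emulates the library structure the downstream analysis
assumes, with full ground truth:

* a toy genome containing duplicated gene families (copies of a
  progenitor mutated at a configurable per-nt divergence), singleton
  siRNA-target genes, background genes, miRNA and piRNA loci;
* 26-nt 5'G guide siRNAs antisense to target-gene exons, phased at
  23-29-nt 5'-to-5' intervals, each opposite a template cytosine;
* ~19-nt sense passenger strands inset 3 nt from the guide 3' end and
  4 nt (optionally jittered +/-1) from the guide 5' end, with per-guide
  passenger:guide count ratios whose population median is configurable;
* 22-nt 5'G secondary siRNAs antisense to ERGO-1-class, ALG-3/4-class
  and CSR-1-class target genes, plus 22-nt 5'U miRNAs and 21-nt 5'U
  piRNAs as background;
* genotype- and stage-specific multiplicative depletion/stabilization
  factors applied per class to a shared per-stage wild-type draw, so
  mutant/wild-type count ratios recover the configured factors.

All randomness flows from one root seed; per-stage and per-library
substreams are derived deterministically from (genotype, stage), so
adding a library never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CollapsedRead,
    Feature,
    write_annotation,
    write_collapsed_library,
    write_config,
    write_genome,
)
from .mapper import revcomp

GENOTYPES = ("wt", "eri-6", "eri-7", "eri-1", "ergo-1")
STAGES = ("embryo", "adult")

GUIDE_CLASSES = {"26G_ergo1", "26G_alg34"}
CLASS_BY_STAGE = {
    # library composition (fraction of reads per class) in wild type
    "embryo": {
        "26G_ergo1": 0.05,
        "22G_ergo1": 0.015,
        "22G_alg34": 0.01,
        "22G_csr1": 0.245,
        "mirna": 0.40,
        "pirna": 0.28,
    },
    "adult": {
        "26G_alg34": 0.05,
        "22G_ergo1": 0.04,
        "22G_alg34": 0.10,
        "22G_csr1": 0.33,
        "mirna": 0.30,
        "pirna": 0.18,
    },
}

DEFAULT_LIBRARIES = (
    ("wt", "embryo"),
    ("eri-6", "embryo"),
    ("eri-7", "embryo"),
    ("eri-1", "embryo"),
    ("ergo-1", "embryo"),
    ("wt", "adult"),
    ("eri-7", "adult"),
)


def default_depletion_factors() -> dict[tuple[str, str, str], float]:
    """Class-level mutant/wild-type factors (wild type and unlisted = 1.0)."""
    factors: dict[tuple[str, str, str], float] = {}
    for g in ("eri-6", "eri-7", "eri-1"):
        factors[(g, "embryo", "26G_ergo1")] = 0.002
        factors[(g, "embryo", "22G_ergo1")] = 0.1
        factors[(g, "embryo", "passenger")] = 0.05
    factors[("ergo-1", "embryo", "26G_ergo1")] = 0.04
    factors[("ergo-1", "embryo", "22G_ergo1")] = 0.5
    factors[("ergo-1", "embryo", "passenger")] = 2.0
    factors[("eri-7", "adult", "22G_ergo1")] = 0.1
    return factors


class CapacityError(ValueError):
    """Feature demand exceeds chromosome capacity."""


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class DuplicationConfig:
    n_families: int = 3
    copies_per_family: int = 2
    divergence: float = 0.05  # substitutions per nt between copies


@dataclass
class DuplexGeometry:
    passenger_length: int = 19
    inset3: int = 3
    inset5: int = 4


@dataclass
class AbundanceModel:
    """Log-normal per-guide (and per-sequence) relative abundance."""

    mu: float = 0.0
    sigma: float = 0.7


@dataclass
class SimulationConfig:
    seed: int = 42
    n_chromosomes: int = 3
    chrom_length: int = 50_000
    n_ergo1_targets: int = 8
    n_alg34_targets: int = 6
    n_csr1_targets: int = 8
    n_mirna: int = 10
    n_pirna: int = 10
    duplication: DuplicationConfig = field(default_factory=DuplicationConfig)
    guide_length: int = 26
    phasing_interval: tuple[int, int] = (23, 29)
    duplex_geometry: DuplexGeometry = field(default_factory=DuplexGeometry)
    inset5_jitter: float = 0.3  # probability of a +/-1 nt inset5 shift
    passenger_guide_ratio_median: float = 0.05
    passenger_ratio_sigma: float = 0.5
    abundance_model: AbundanceModel = field(default_factory=AbundanceModel)
    depletion_factors: dict[tuple[str, str, str], float] = field(
        default_factory=default_depletion_factors
    )
    library_depth: int = 200_000
    libraries: tuple[tuple[str, str], ...] = DEFAULT_LIBRARIES
    # gene structure: siRNA targets are short, intron-poor genes compared
    # with the background gene set
    target_exons: int = 3
    target_exon_len: int = 280
    target_intron_len: int = 55
    background_exons: int = 5
    background_exon_len: int = 550
    background_intron_len: int = 60
    mirna_len: int = 80
    pirna_len: int = 60
    n_22g_per_gene: int = 20
    proximal_families: int = 1  # families whose copies sit within 5 kb

    def validate(self) -> None:
        g = self.duplex_geometry
        if self.guide_length != g.passenger_length + g.inset3 + g.inset5:
            raise ConfigurationError(
                "exact duplex geometry requires guide_length == "
                "passenger_length + inset3 + inset5"
            )
        lo, hi = self.phasing_interval
        if not (1 <= lo <= hi):
            raise ConfigurationError("phasing_interval must satisfy 1 <= min <= max")
        if any(f < 0 for f in self.depletion_factors.values()):
            raise ConfigurationError("depletion factors must be >= 0")
        known = {g for g, _ in self.libraries} | set(GENOTYPES)
        for gt, stage, _k in self.depletion_factors:
            if gt not in known:
                raise ConfigurationError(
                    f"unknown genotype {gt!r} in depletion_factors"
                )
            if stage not in STAGES:
                raise ConfigurationError(f"unknown stage {stage!r} in depletion_factors")
        if self.target_exon_len < max(self.guide_length, 42):
            raise ConfigurationError("target exons too short for guide placement")
        dup = self.duplication
        n_fam_genes = dup.n_families * dup.copies_per_family
        if self.n_ergo1_targets and n_fam_genes > self.n_ergo1_targets:
            raise ConfigurationError(
                "duplication families need more genes than n_ergo1_targets"
            )

    def factor(self, genotype: str, stage: str, klass: str) -> float:
        """Factor lookup; accepts exact class keys or bare-prefix aliases
        such as ``26G`` for ``26G_ergo1``."""
        if genotype == "wt":
            return 1.0
        f = self.depletion_factors.get((genotype, stage, klass))
        if f is None and "_" in klass:
            f = self.depletion_factors.get((genotype, stage, klass.split("_")[0]))
        return 1.0 if f is None else f

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depletion_factors"] = {
            "|".join(k): v for k, v in sorted(self.depletion_factors.items())
        }
        d["libraries"] = [list(x) for x in self.libraries]
        d["phasing_interval"] = list(self.phasing_interval)
        return d


@dataclass
class ReadPlan:
    """One planned read species, in feature-relative sense coordinates."""

    feature_id: str
    klass: str
    rel_start: int
    rel_end: int
    orientation: str  # "sense" | "antisense"
    passenger_rel: tuple[int, int] | None = None


@dataclass
class AnnotatedGenome:
    chroms: dict[str, str]
    features: list[Feature]
    plans: list[ReadPlan]
    config: SimulationConfig

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def feature(self, fid: str) -> Feature:
        cache = getattr(self, "_by_id", None)
        if cache is None:
            cache = {f.id: f for f in self.features}
            object.__setattr__(self, "_by_id", cache)
        return cache[fid]

    def sense_sequence(self, feature: Feature) -> str:
        s = self.chroms[feature.chrom][feature.start : feature.end]
        return revcomp(s) if feature.strand == "-" else s

    def genomic_interval(
        self, feature: Feature, rel_start: int, rel_end: int
    ) -> tuple[int, int]:
        if feature.strand == "+":
            return feature.start + rel_start, feature.start + rel_end
        return feature.end - rel_end, feature.end - rel_start

    def read_sequence(self, plan: ReadPlan) -> str:
        feat = self.feature(plan.feature_id)
        t = self.sense_sequence(feat)[plan.rel_start : plan.rel_end]
        return t if plan.orientation == "sense" else revcomp(t)

    def read_locus(self, plan: ReadPlan) -> tuple[str, int, str]:
        feat = self.feature(plan.feature_id)
        start, _end = self.genomic_interval(feat, plan.rel_start, plan.rel_end)
        if plan.orientation == "sense":
            strand = feat.strand
        else:
            strand = "-" if feat.strand == "+" else "+"
        return feat.chrom, start, strand


@dataclass
class TruthTable:
    """Ground truth linking every emitted read to its generating record."""

    features: pd.DataFrame  # index feature_id: biotype, truth_class
    reads: pd.DataFrame  # one row per (plan record): locus, class, counts
    guides: pd.DataFrame  # guide subset with passenger geometry columns

    def class_totals(self, genotype: str, stage: str) -> pd.Series:
        col = f"n_{genotype}_{stage}"
        return self.reads.groupby("klass")[col].sum()

    def to_tsv(self, path: str | Path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome construction

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte codes


def _rand_seq_array(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_NT, size=length)


def _mutate(
    rng: np.random.Generator, body: np.ndarray, rate: float
) -> np.ndarray:
    """Substitute each position with probability ``rate``, always to a
    different base, so expected identity is exactly 1 - rate."""
    out = body.copy()
    hits = np.nonzero(rng.random(len(body)) < rate)[0]
    for i in hits:
        choices = _NT[_NT != out[i]]
        out[i] = rng.choice(choices)
    return out


def _exon_layout(n_exons: int, exon_len: int, intron_len: int) -> list[tuple[int, int]]:
    exons = []
    pos = 0
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    return exons


@dataclass
class _GeneSpec:
    fid: str
    biotype: str
    truth_class: str | None
    exons_rel: list[tuple[int, int]]
    family: int | None = None  # duplication family index
    progenitor: str | None = None  # fid of family progenitor
    adjacent_to: str | None = None  # place within 5 kb of this gene

    @property
    def span(self) -> int:
        return self.exons_rel[-1][1]


def _gene_specs(config: SimulationConfig) -> list[_GeneSpec]:
    specs: list[_GeneSpec] = []
    dup = config.duplication
    target_exons = _exon_layout(
        config.target_exons, config.target_exon_len, config.target_intron_len
    )
    bg_exons = _exon_layout(
        config.background_exons, config.background_exon_len, config.background_intron_len
    )
    n_fam = dup.n_families if config.n_ergo1_targets else 0
    made = 0
    for f in range(n_fam):
        prog = f"ergo1_f{f}c0"
        for c in range(dup.copies_per_family):
            fid = f"ergo1_f{f}c{c}"
            specs.append(
                _GeneSpec(
                    fid=fid,
                    biotype="pseudogene" if f % 2 else "coding",
                    truth_class="ergo1_target",
                    exons_rel=target_exons,
                    family=f,
                    progenitor=None if c == 0 else prog,
                    adjacent_to=(
                        f"ergo1_f{f}c{c-1}"
                        if c > 0 and f < config.proximal_families
                        else None
                    ),
                )
            )
            made += 1
    for i in range(config.n_ergo1_targets - made):
        specs.append(
            _GeneSpec(
                fid=f"ergo1_s{i}",
                biotype="coding" if i % 2 else "pseudogene",
                truth_class="ergo1_target",
                exons_rel=target_exons,
            )
        )
    for i in range(config.n_alg34_targets):
        specs.append(
            _GeneSpec(
                fid=f"alg34_{i}",
                biotype="coding",
                truth_class="alg34_target",
                exons_rel=target_exons,
            )
        )
    for i in range(config.n_csr1_targets):
        specs.append(
            _GeneSpec(
                fid=f"csr1_{i}",
                biotype="coding",
                truth_class="csr1_wago",
                exons_rel=bg_exons,
            )
        )
    for i in range(config.n_mirna):
        specs.append(
            _GeneSpec(
                fid=f"mir_{i}",
                biotype="mirna",
                truth_class="mirna",
                exons_rel=[(0, config.mirna_len)],
            )
        )
    for i in range(config.n_pirna):
        specs.append(
            _GeneSpec(
                fid=f"pi_{i}",
                biotype="pirna_locus",
                truth_class="pirna",
                exons_rel=[(0, config.pirna_len)],
            )
        )
    return specs


def _place_features(
    specs: list[_GeneSpec], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, tuple[str, int, str]]:
    """Assign (chrom, start, strand) to every gene spec, non-overlapping."""
    chrom_names = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    cursors = {c: 600 for c in chrom_names}
    placed: dict[str, tuple[str, int, str]] = {}
    # neighbouring genes must sit further apart than two homology flanks
    # (2 x 500 nt), or unrelated flanked sequences would share genomic
    # sequence and fake homology
    margin = 1100
    order = 0
    for spec in specs:
        strand = "+" if rng.random() < 0.5 else "-"
        if spec.adjacent_to is not None and spec.adjacent_to in placed:
            chrom, prev_start, _ = placed[spec.adjacent_to]
            prev_end = prev_start + next(
                s.span for s in specs if s.fid == spec.adjacent_to
            )
            gap = int(rng.integers(1500, 3500))  # < 5 kb: "close proximity"
            start = prev_end + gap
            if start + spec.span + margin > config.chrom_length:
                raise CapacityError(
                    f"chromosome capacity exceeded placing {spec.fid} "
                    f"adjacent to {spec.adjacent_to}"
                )
            placed[spec.fid] = (chrom, start, strand)
            cursors[chrom] = max(cursors[chrom], start + spec.span + margin)
            continue
        # round-robin over chromosomes, falling back to any with room
        candidates = chrom_names[order % len(chrom_names) :] + chrom_names[
            : order % len(chrom_names)
        ]
        for chrom in candidates:
            start = cursors[chrom] + int(rng.integers(0, 400))
            if start + spec.span + margin <= config.chrom_length:
                placed[spec.fid] = (chrom, start, strand)
                cursors[chrom] = start + spec.span + margin
                break
        else:
            raise CapacityError(
                f"feature demand exceeds chromosome capacity at {spec.fid} "
                f"({len(placed)} of {len(specs)} features placed)"
            )
        order += 1
    return placed


def _guide_register(
    exons_rel: list[tuple[int, int]], config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Guide intervals (relative sense coords) phased within exons.

    Successive 5' ends within an exon are spaced by uniform draws from
    the configured phasing interval; the register restarts in each exon
    so no guide spans an intron.
    """
    lo, hi = config.phasing_interval
    L = config.guide_length
    register = []
    for a, b in exons_rel:
        x = a + int(rng.integers(0, max(lo // 2, 1)))
        while x + L <= b:
            register.append((x, x + L))
            x += int(rng.integers(lo, hi + 1))
    return register


def _jitters(n: int, config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    out = []
    for _ in range(n):
        if rng.random() < config.inset5_jitter:
            out.append(-1 if rng.random() < 0.5 else 1)
        else:
            out.append(0)
    return out


def _sirna_register(
    exons_rel: list[tuple[int, int]],
    n: int,
    length: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Random non-identical 22G start positions, each within one exon."""
    starts = []
    for a, b in exons_rel:
        starts.extend(range(a, b - length + 1))
    n = min(n, len(starts))
    chosen = sorted(rng.choice(len(starts), size=n, replace=False))
    return [(starts[i], starts[i] + length) for i in chosen]


def simulate_genome(config: SimulationConfig) -> AnnotatedGenome:
    """Build the toy genome, annotation and read plan for one config."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    chrom_names = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    chrom_arrays = {
        c: _rand_seq_array(rng, config.chrom_length) for c in chrom_names
    }

    specs = _gene_specs(config)
    placed = _place_features(specs, config, rng)

    # family progenitor bodies and registers, inherited by copies
    bodies: dict[str, np.ndarray] = {}
    guide_registers: dict[str, list[tuple[int, int]]] = {}
    jitters: dict[str, list[int]] = {}
    sirna_registers: dict[str, list[tuple[int, int]]] = {}
    geo = config.duplex_geometry

    for spec in specs:
        if spec.truth_class in {"ergo1_target", "alg34_target"}:
            key = spec.progenitor or spec.fid
            if key not in guide_registers:
                guide_registers[key] = _guide_register(spec.exons_rel, config, rng)
                jitters[key] = _jitters(len(guide_registers[key]), config, rng)
                sirna_registers[key] = _sirna_register(
                    spec.exons_rel, config.n_22g_per_gene, 22, rng
                )
        elif spec.truth_class == "csr1_wago":
            sirna_registers[spec.fid] = _sirna_register(
                spec.exons_rel, config.n_22g_per_gene, 22, rng
            )

    # write duplicated gene bodies (sense orientation) into the genome
    for spec in specs:
        if spec.family is None:
            continue
        key = spec.progenitor or spec.fid
        if key not in bodies:
            bodies[key] = _rand_seq_array(rng, spec.span)
        body = bodies[key]
        if spec.progenitor is not None:
            body = _mutate(rng, body, config.duplication.divergence)
        chrom, start, strand = placed[spec.fid]
        arr = chrom_arrays[chrom]
        if strand == "+":
            arr[start : start + spec.span] = body
        else:
            arr[start : start + spec.span] = np.array(
                [_COMP[b] for b in body[::-1]], dtype=np.uint8
            )

    features = []
    for spec in specs:
        chrom, start, strand = placed[spec.fid]
        features.append(
            Feature(
                id=spec.fid,
                chrom=chrom,
                strand=strand,
                exons=sorted((start + a, start + b) for a, b in spec.exons_rel),
                biotype=spec.biotype,
                truth_class=spec.truth_class,
            )
        )
    by_id = {f.id: f for f in features}

    def set_template_base(feat: Feature, rel: int, base: str) -> None:
        arr = chrom_arrays[feat.chrom]
        code = ord(base)
        if feat.strand == "+":
            arr[feat.start + rel] = code
        else:
            arr[feat.end - 1 - rel] = _COMP[code]

    plans: list[ReadPlan] = []
    for spec in specs:
        feat = by_id[spec.fid]
        if spec.truth_class in {"ergo1_target", "alg34_target"}:
            key = spec.progenitor or spec.fid
            klass = "26G_ergo1" if spec.truth_class == "ergo1_target" else "26G_alg34"
            for (x, y), dj in zip(guide_registers[key], jitters[key]):
                # template C opposite the guide 5' end (guide reads 5' G)
                set_template_base(feat, y - 1, "C")
                p_start = x + geo.inset3
                p_end = y - (geo.inset5 + dj)
                plans.append(
                    ReadPlan(
                        feature_id=spec.fid,
                        klass=klass,
                        rel_start=x,
                        rel_end=y,
                        orientation="antisense",
                        passenger_rel=(p_start, p_end),
                    )
                )
            klass22 = "22G_ergo1" if spec.truth_class == "ergo1_target" else "22G_alg34"
            for x, y in sirna_registers[key]:
                set_template_base(feat, y - 1, "C")
                plans.append(
                    ReadPlan(spec.fid, klass22, x, y, "antisense")
                )
        elif spec.truth_class == "csr1_wago":
            for x, y in sirna_registers[spec.fid]:
                set_template_base(feat, y - 1, "C")
                plans.append(ReadPlan(spec.fid, "22G_csr1", x, y, "antisense"))
        elif spec.truth_class == "mirna":
            set_template_base(feat, 10, "T")
            plans.append(ReadPlan(spec.fid, "mirna", 10, 32, "sense"))
        elif spec.truth_class == "pirna":
            set_template_base(feat, 10, "T")
            plans.append(ReadPlan(spec.fid, "pirna", 10, 31, "sense"))

    chroms = {c: arr.tobytes().decode("ascii") for c, arr in chrom_arrays.items()}
    return AnnotatedGenome(
        chroms=chroms, features=features, plans=plans, config=config
    )


# ---------------------------------------------------------------------------
# libraries

def _integerize(weights: np.ndarray, total: int) -> np.ndarray:
    """Scale non-negative weights to integers summing exactly to ``total``
    (largest-remainder rounding)."""
    w = np.asarray(weights, dtype=float)
    if total <= 0 or len(w) == 0 or w.sum() == 0:
        return np.zeros(len(w), dtype=int)
    x = w / w.sum() * total
    base = np.floor(x).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(x - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, 21, zlib.crc32(stage.encode())])


def _library_rng(
    config: SimulationConfig, genotype: str, stage: str
) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, 31, zlib.crc32(genotype.encode()), zlib.crc32(stage.encode())]
    )


def _scale_counts(
    counts: np.ndarray, factor: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiply counts by a factor with stochastic (floor + Bernoulli)
    rounding, so the expectation is exact for any factor."""
    if factor == 1.0:
        return counts.copy()
    x = counts * factor
    base = np.floor(x).astype(int)
    frac = x - base
    return base + (rng.random(len(x)) < frac)


@dataclass
class _StageDraw:
    """Shared wild-type base counts for one stage."""

    plans: list[ReadPlan]
    counts: np.ndarray  # per plan
    passenger_counts: np.ndarray  # per plan; 0 where not a guide


def _draw_stage(genome: AnnotatedGenome, stage: str) -> _StageDraw:
    config = genome.config
    rng = _stage_rng(config, stage)
    shares = CLASS_BY_STAGE[stage]
    budgets = _integerize(
        np.array([shares[c] for c in sorted(shares)]),
        config.library_depth,
    )
    budget_by_class = dict(zip(sorted(shares), budgets))

    plans: list[ReadPlan] = []
    counts: list[int] = []
    passengers: list[int] = []
    sigma = config.abundance_model.sigma
    for klass in sorted(shares):
        class_plans = [p for p in genome.plans if p.klass == klass]
        budget = budget_by_class[klass]
        if not class_plans:
            continue
        if klass in GUIDE_CLASSES:
            r_sigma = config.passenger_ratio_sigma
            ratios = np.exp(
                rng.normal(
                    np.log(config.passenger_guide_ratio_median),
                    r_sigma,
                    len(class_plans),
                )
            )
            expected_ratio = config.passenger_guide_ratio_median * np.exp(
                r_sigma**2 / 2
            )
            guide_budget = int(round(budget / (1.0 + expected_ratio)))
            weights = rng.lognormal(config.abundance_model.mu, sigma, len(class_plans))
            c = _integerize(weights, guide_budget)
            p = np.floor(c * ratios + 0.5).astype(int)
        else:
            weights = rng.lognormal(config.abundance_model.mu, sigma, len(class_plans))
            c = _integerize(weights, budget)
            p = np.zeros(len(class_plans), dtype=int)
        plans.extend(class_plans)
        counts.extend(c.tolist())
        passengers.extend(p.tolist())
    return _StageDraw(
        plans=plans,
        counts=np.array(counts, dtype=int),
        passenger_counts=np.array(passengers, dtype=int),
    )


def simulate_libraries(
    genome: AnnotatedGenome, config: SimulationConfig | None = None
) -> tuple[dict[tuple[str, str], list[CollapsedRead]], TruthTable]:
    """Emit collapsed libraries for every configured (genotype, stage).

    Returns the libraries plus the :class:`TruthTable` that attributes
    every emitted read to its generating record.
    """
    config = config or genome.config
    config.validate()
    stage_draws = {
        stage: _draw_stage(genome, stage)
        for stage in sorted({s for _g, s in config.libraries})
    }

    lib_counts: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for genotype, stage in config.libraries:
        draw = stage_draws[stage]
        rng = _library_rng(config, genotype, stage)
        factors = np.array(
            [config.factor(genotype, stage, p.klass) for p in draw.plans]
        )
        counts = np.empty(len(draw.plans), dtype=int)
        for f in np.unique(factors):
            mask = factors == f
            counts[mask] = _scale_counts(draw.counts[mask], float(f), rng)
        pf = config.factor(genotype, stage, "passenger")
        passengers = _scale_counts(draw.passenger_counts, pf, rng)
        lib_counts[(genotype, stage)] = (counts, passengers)

    libraries: dict[tuple[str, str], list[CollapsedRead]] = {}
    truth_rows = []
    for (genotype, stage), (counts, passengers) in lib_counts.items():
        draw = stage_draws[stage]
        collapsed: dict[str, int] = {}
        for plan, c, pc in zip(draw.plans, counts, passengers):
            if c > 0:
                seq = genome.read_sequence(plan)
                collapsed[seq] = collapsed.get(seq, 0) + int(c)
            if pc > 0 and plan.passenger_rel is not None:
                pplan = ReadPlan(
                    plan.feature_id,
                    "passenger",
                    plan.passenger_rel[0],
                    plan.passenger_rel[1],
                    "sense",
                )
                pseq = genome.read_sequence(pplan)
                collapsed[pseq] = collapsed.get(pseq, 0) + int(pc)
        libraries[(genotype, stage)] = [
            CollapsedRead(seq, n)
            for seq, n in sorted(collapsed.items(), key=lambda kv: (-kv[1], kv[0]))
        ]

    # truth table: one row per plan record with per-library counts
    all_rows: dict[tuple[str, str, int], dict] = {}
    for stage, draw in stage_draws.items():
        for i, plan in enumerate(draw.plans):
            feat = genome.feature(plan.feature_id)
            chrom, start, strand = genome.read_locus(plan)
            key = (stage, plan.klass, i)
            row = {
                "sequence": genome.read_sequence(plan),
                "klass": plan.klass,
                "feature_id": plan.feature_id,
                "chrom": chrom,
                "start": start,
                "end": start + (plan.rel_end - plan.rel_start),
                "strand": strand,
                "stage_drawn": stage,
            }
            if plan.passenger_rel is not None:
                ps, pe = genome.genomic_interval(feat, *plan.passenger_rel)
                pplan = ReadPlan(
                    plan.feature_id, "passenger", *plan.passenger_rel, "sense"
                )
                row.update(
                    passenger_sequence=genome.read_sequence(pplan),
                    passenger_start=ps,
                    passenger_end=pe,
                    passenger_length=pe - ps,
                )
            all_rows[key] = row
    for (genotype, stage), (counts, passengers) in lib_counts.items():
        draw = stage_draws[stage]
        for i, plan in enumerate(draw.plans):
            row = all_rows[(stage, plan.klass, i)]
            row[f"n_{genotype}_{stage}"] = int(counts[i])
            if plan.passenger_rel is not None:
                row[f"n_passenger_{genotype}_{stage}"] = int(passengers[i])

    reads_df = pd.DataFrame(list(all_rows.values()))
    count_cols = [c for c in reads_df.columns if c.startswith("n_")]
    reads_df[count_cols] = reads_df[count_cols].fillna(0).astype(int)
    features_df = pd.DataFrame(
        {
            "biotype": {f.id: f.biotype for f in genome.features},
            "truth_class": {f.id: f.truth_class for f in genome.features},
        }
    )
    features_df.index.name = "feature_id"
    guides_df = reads_df[reads_df["klass"].isin(GUIDE_CLASSES)].copy()
    truth = TruthTable(features=features_df, reads=reads_df, guides=guides_df)
    return libraries, truth


def write_dataset(
    genome: AnnotatedGenome,
    libraries: dict[tuple[str, str], list[CollapsedRead]],
    truth: TruthTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genome FASTA, GFF3, collapsed libraries, truth TSV, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["genome"] = out / "genome.fa"
    write_genome(genome.chroms, paths["genome"])
    paths["annotation"] = out / "annotation.gff3"
    write_annotation(genome.features, paths["annotation"])
    for (genotype, stage), reads in libraries.items():
        p = out / f"library_{genotype}_{stage}.fa"
        write_collapsed_library(reads, p)
        paths[f"library_{genotype}_{stage}"] = p
    paths["truth"] = out / "truth.tsv"
    truth.to_tsv(paths["truth"])
    paths["config"] = out / "config.yaml"
    write_config(genome.config.to_dict(), paths["config"])
    return paths


def simulate(config: SimulationConfig | None = None):
    """Convenience: genome + libraries + truth in one call."""
    config = config or SimulationConfig()
    genome = simulate_genome(config)
    libraries, truth = simulate_libraries(genome, config)
    return genome, libraries, truth
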