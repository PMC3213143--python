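"""Length x 5'-nt profiles and small-RNA class assignment.

Classes follow the field's Argonaute-centric definitions: 26G siRNAs are
exactly 26 nt with a 5' G and antisense to a coding gene, pseudogene or
transposon exon; 22G siRNAs are the 22-nt equivalent; miRNAs are reads
sense to an annotated miRNA feature; piRNAs (21U RNAs) are 21 nt with a
5' U, sense to a piRNA locus.  Precedence when a locus overlaps several
annotations: mirna > pirna > 26G > 22G > other.  "Antisense to a
feature" means the locus strand is opposite the feature strand and the
locus overlaps the feature's exon set by >= 1 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import Feature
from .mapper import MappedLibrary, MappedRead

SIRNA_BIOTYPES = {"coding", "pseudogene", "transposon"}
CLASSES = ("26G", "22G", "mirna", "pirna", "other")
LENGTH_RANGE = range(18, 29)
_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


class AnnotationIndex:
    """Interval lookup from genomic loci to overlapping features."""

    def __init__(self, features: list[Feature]):
        self.features = {f.id: f for f in features}
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            tree = self._trees.setdefault(f.chrom, IntervalTree())
            for a, b in f.exons:
                tree.addi(a, b, f.id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start, end)}
        return [self.features[i] for i in sorted(ids)]


def classify_read(
    sequence: str,
    locus: tuple[str, int, str],
    annotation: AnnotationIndex,
) -> str:
    """Assign one (read, locus) pair to a small-RNA class."""
    chrom, start, strand = locus
    end = start + len(sequence)
    feats = annotation.overlapping(chrom, start, end)
    length = len(sequence)
    first = sequence[0]

    sense = [f for f in feats if f.strand == strand]
    antisense = [f for f in feats if f.strand != strand]

    if any(f.biotype == "mirna" for f in sense):
        return "mirna"
    if length == 21 and first == "T" and any(
        f.biotype == "pirna_locus" for f in sense
    ):
        return "pirna"
    has_sirna_target = any(f.biotype in SIRNA_BIOTYPES for f in antisense)
    if length == 26 and first == "G" and has_sirna_target:
        return "26G"
    if length == 22 and first == "G" and has_sirna_target:
        return "22G"
    return "other"


@dataclass
class LibraryProfile:
    """Per-library normalized summaries of a mapped small-RNA library.

    ``matrix`` holds RPM by (read length 18-28, 5' nucleotide A/C/G/U)
    and always totals 1e6 over all mapped reads.  ``feature_table`` has
    one row per annotated feature with sense/antisense RPM plus the
    antisense 26G/22G class breakdown used for subset-restricted
    depletion.  ``class_rpm`` sums RPM by class over all loci.
    """

    genotype: str
    stage: str
    matrix: pd.DataFrame
    feature_table: pd.DataFrame
    class_rpm: dict[str, float]
    guide_table: pd.DataFrame
    library: MappedLibrary
    annotation: AnnotationIndex

    @property
    def total_rpm(self) -> float:
        return float(self.matrix.to_numpy().sum())


def profile(
    library: MappedLibrary,
    annotation: AnnotationIndex | list[Feature],
    genotype: str = "",
    stage: str = "",
) -> LibraryProfile:
    """Build the :class:`LibraryProfile` for one mapped library.

    Multi-locus reads contribute their fractional per-locus weight to
    each overlapped feature, so feature counts never double-count a
    read.  The (length, 5' nt) matrix is per *read copy* (each copy has
    one length and one 5' nt regardless of how many loci it maps to).
    """
    if not isinstance(annotation, AnnotationIndex):
        annotation = AnnotationIndex(annotation)

    matrix = pd.DataFrame(
        0.0, index=list(LENGTH_RANGE), columns=["A", "C", "G", "U"]
    )
    matrix.index.name = "length"
    feat_ids = sorted(annotation.features)
    feature_table = pd.DataFrame(
        0.0,
        index=pd.Index(feat_ids, name="feature"),
        columns=[
            "sense_rpm",
            "antisense_rpm",
            "antisense_26g_rpm",
            "antisense_22g_rpm",
        ],
    )
    class_rpm = {c: 0.0 for c in CLASSES}
    guide_rows: list[tuple[str, float, int]] = []

    factor = library.scale.rpm_factor
    for mr in library.reads:
        read_rpm = mr.count * factor
        matrix.loc[len(mr.sequence), _DNA_TO_RNA[mr.sequence[0]]] += read_rpm
        w_rpm = mr.weight_per_locus * factor
        is_26g_anywhere = False
        for locus in mr.loci:
            chrom, start, strand = locus
            end = start + len(mr.sequence)
            label = classify_read(mr.sequence, locus, annotation)
            class_rpm[label] += w_rpm
            if label == "26G":
                is_26g_anywhere = True
            for f in annotation.overlapping(chrom, start, end):
                col = "sense_rpm" if f.strand == strand else "antisense_rpm"
                feature_table.loc[f.id, col] += w_rpm
                if f.strand != strand and f.biotype in SIRNA_BIOTYPES:
                    if len(mr.sequence) == 26 and mr.sequence[0] == "G":
                        feature_table.loc[f.id, "antisense_26g_rpm"] += w_rpm
                    elif len(mr.sequence) == 22 and mr.sequence[0] == "G":
                        feature_table.loc[f.id, "antisense_22g_rpm"] += w_rpm
        if is_26g_anywhere:
            guide_rows.append((mr.sequence, mr.count * factor, mr.n_loci))

    guide_table = pd.DataFrame(
        guide_rows, columns=["sequence", "rpm", "n_loci"]
    ).set_index("sequence")
    return LibraryProfile(
        genotype=genotype,
        stage=stage,
        matrix=matrix,
        feature_table=feature_table,
        class_rpm=class_rpm,
        guide_table=guide_table,
        library=library,
        annotation=annotation,
    )


def five_prime_template(
    guide: MappedRead | str,
    locus: tuple[str, int, str],
    genome: dict[str, str],
    annotation: AnnotationIndex | None = None,
) -> str:
    """Sense-strand (mRNA) base paired with the guide's 5' nucleotide.

    For a 5'G guide this is C by Watson-Crick complementarity; the
    function reads the base off the genome rather than the read so that
    it reports the *template* identity.  If an annotation index is
    given, a locus that is not antisense to any siRNA-target feature
    raises ``ValueError``.
    """
    seq = guide.sequence if isinstance(guide, MappedRead) else guide
    chrom, start, strand = locus
    end = start + len(seq)
    if annotation is not None:
        feats = annotation.overlapping(chrom, start, end)
        if not any(
            f.strand != strand and f.biotype in SIRNA_BIOTYPES for f in feats
        ):
            raise ValueError(
                f"locus {locus} is not antisense to any annotated feature"
            )
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "-":
        # guide 5' end at genomic right edge; template is the + strand
        return genome[chrom][end - 1]
    # guide on + strand: template is the - strand; complement of genome base
    return comp[genome[chrom][start]]


def length_profile_for_features(
    library: MappedLibrary,
    annotation: AnnotationIndex,
    feature_ids: set[str] | list[str],
    orientation: str = "antisense",
) -> pd.Series:
    """RPM by read length restricted to loci (anti)sense to given features."""
    feature_ids = set(feature_ids)
    out = pd.Series(0.0, index=list(LENGTH_RANGE), name="rpm")
    factor = library.scale.rpm_factor
    for mr in library.reads:
        w_rpm = mr.weight_per_locus * factor
        for chrom, start, strand in mr.loci:
            end = start + len(mr.sequence)
            for f in annotation.overlapping(chrom, start, end):
                if f.id not in feature_ids:
                    continue
                same = f.strand == strand
                if (orientation == "sense") == same:
                    out.loc[len(mr.sequence)] += w_rpm
                    break
    return out
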