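"""Readers and writers for the on-disk formats the pipeline touches.

Formats: genome FASTA, collapsed small-RNA FASTA (``>read<i>_x<count>``
headers, one record per distinct sequence), GFF3 annotation, BED6, TSV
tables and YAML/JSON config.

All coordinates are 0-based half-open internally; conversion to/from the
1-based inclusive GFF3 convention happens only in this module.  ``U`` in
input read sequences is normalized to ``T`` on read-in.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MIN_READ_LEN = 18  #: lower bound of the size selection window, nt
MAX_READ_LEN = 28  #: upper bound of the size selection window, nt

_VALID_NT = re.compile(r"^[ACGT]+$")
_HEADER_RE = re.compile(r"_x(\d+)$")

BIOTYPES = {"coding", "pseudogene", "transposon", "mirna", "pirna_locus"}


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct small-RNA sequence with its collapsed read count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class Feature:
    """A strand-aware annotated feature with exon structure.

    ``exons`` are 0-based half-open intervals, sorted by genomic
    coordinate and non-overlapping regardless of strand.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str
    truth_class: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        exons = sorted(self.exons)
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if c < b:
                raise ValueError(f"overlapping exons in {self.id}")
        for a, b in exons:
            if a < 0 or b <= a:
                raise ValueError(f"invalid exon ({a},{b}) in {self.id}")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class ReadFilterStats:
    """Bookkeeping from collapsed-library read-in."""

    n_kept: int = 0
    n_size_excluded: int = 0


def read_collapsed_library(
    path: str | Path,
    size_filter: bool = True,
) -> tuple[list[CollapsedRead], ReadFilterStats]:
    """Read a collapsed FASTA library.

    Headers must end in ``_x<count>``.  Sequences outside ACGTU are
    rejected; reads outside the 18-28 nt size-selection window are
    discarded and counted in the returned stats.  An empty file yields
    an empty list.
    """
    path = Path(path)
    reads: list[CollapsedRead] = []
    stats = ReadFilterStats()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        m = _HEADER_RE.search(rec.id)
        if m is None:
            raise FormatError(
                f"{path}: record {i} ({rec.id!r}): header lacks _x<count> suffix"
            )
        count = int(m.group(1))
        seq = str(rec.seq).upper().replace("U", "T")
        if not _VALID_NT.match(seq):
            raise FormatError(
                f"{path}: record {i} ({rec.id!r}): non-ACGTU characters in sequence"
            )
        if size_filter and not (MIN_READ_LEN <= len(seq) <= MAX_READ_LEN):
            stats.n_size_excluded += 1
            continue
        reads.append(CollapsedRead(seq, count))
        stats.n_kept += 1
    return reads, stats


def write_collapsed_library(
    reads: Iterable[CollapsedRead], path: str | Path
) -> None:
    """Write collapsed reads as ``>read<i>_x<count>`` FASTA."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f">read{i}_x{r.count}\n{r.sequence}\n")


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a dict of upper-case sequences."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_genome(chroms: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_annotation(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> list[Feature]:
    """Parse a GFF3 annotation into :class:`Feature` objects.

    Expects ``gene`` records carrying ``ID`` and ``biotype`` attributes
    (optionally ``truth_class``) with ``exon`` children.  GFF3 1-based
    inclusive coordinates are converted to 0-based half-open.  If
    ``chrom_lengths`` is given, exons outside chromosome bounds raise.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    features: list[Feature] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = [
            (e.start - 1, e.end) for e in db.children(gene, featuretype="exon")
        ]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        biotype = gene.attributes.get("biotype", [None])[0]
        if biotype is None:
            raise FormatError(f"{path}: gene {gene.id} lacks a biotype attribute")
        truth = gene.attributes.get("truth_class", [None])[0]
        feat = Feature(
            id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=sorted(exons),
            biotype=biotype,
            truth_class=truth,
        )
        if chrom_lengths is not None:
            limit = chrom_lengths.get(feat.chrom)
            if limit is None:
                raise FormatError(f"{path}: unknown chromosome {feat.chrom}")
            if feat.start < 0 or feat.end > limit:
                raise FormatError(
                    f"{path}: feature {feat.id} outside chromosome bounds"
                )
        features.append(feat)
    return features


def write_annotation(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as GFF3 (gene lines with exon children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id};biotype={f.biotype}"
            if f.truth_class is not None:
                attrs += f";truth_class={f.truth_class}"
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "erisift",
                        "gene",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for j, (a, b) in enumerate(f.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            f.chrom,
                            "erisift",
                            "exon",
                            str(a + 1),
                            str(b),
                            ".",
                            f.strand,
                            ".",
                            f"ID={f.id}.e{j};Parent={f.id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED6

def write_bed(mapped_reads, path: str | Path) -> None:
    """Write mapped read loci as BED6 (0-based half-open, score = count)."""
    with open(path, "w") as fh:
        for mr in mapped_reads:
            for chrom, start, strand in mr.loci:
                fh.write(
                    f"{chrom}\t{start}\t{start + len(mr.sequence)}\t"
                    f"{mr.sequence}\t{mr.count}\t{strand}\n"
                )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), name, int(score), strand))
    return rows


# ---------------------------------------------------------------------------
# config / tables

def read_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in {".yaml", ".yml"}:
            return yaml.safe_load(fh)
        return json.load(fh)


def write_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in {".yaml", ".yml"}:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        else:
            json.dump(cfg, fh, indent=2, sort_keys=True)


def read_feature_subset(path: str | Path) -> list[str]:
    """Read a plain-text feature-ID list, one ID per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
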