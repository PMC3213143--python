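"""Passenger-strand inference, duplex geometry, and 26G phasing.

The siRNA duplex precursor of a 26-nt guide is reconstructed from the
sequencing data alone: within a genomic window spanning the guide plus
14 nt of flank on each side (54 nt for a 26-nt guide), the most abundant
read on the opposite strand whose locus lies fully inside the window is
taken as the passenger strand.  Geometry is reported strand-aware in
duplex register: ``inset3`` is the distance between the guide's 3'
terminus and the nearest passenger terminus (genomic left end for a
minus-strand guide), ``inset5`` likewise at the guide's 5' end.  Insets
may be negative if the passenger protrudes; they are recorded, never
clamped.

Phasing: successive 5' positions of 26G guides along a transcript,
expressed in template (mRNA sense) coordinates; processive RdRP/Dicer
biogenesis shows up as regular-but-variable intervals, typically
23-29 nt.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Feature
from .mapper import MappedLibrary, MappedRead

DEFAULT_FLANK = 14  #: nt of flank on each side of the guide


@dataclass
class DuplexRecord:
    """A 26G guide at one locus paired with its inferred passenger."""

    guide_sequence: str
    guide_locus: tuple[str, int, str]
    window: tuple[int, int]
    guide_rpm: float
    passenger_sequence: str | None = None
    passenger_locus: tuple[str, int, str] | None = None
    passenger_length: int | None = None
    inset3: int | None = None
    inset5: int | None = None
    passenger_rpm: float = 0.0

    @property
    def ratio(self) -> float:
        return self.passenger_rpm / self.guide_rpm if self.guide_rpm else 0.0

    @property
    def has_passenger(self) -> bool:
        return self.passenger_sequence is not None


@dataclass
class DuplexConsensus:
    """Population summary of inferred duplex geometry for one library."""

    modal_passenger_length: int | None
    modal_inset3: int | None
    modal_inset5: int | None
    median_ratio: float
    fraction_with_passenger: float
    n_records: int


@dataclass
class PhasingProfile:
    """Ordered 26G 5' positions along one feature and their intervals."""

    feature_id: str
    positions: list[int]  # template (mRNA sense) coordinates, ascending
    intervals: list[int]
    fraction_in_band: float | None  # None when < 2 guides
    band: tuple[int, int] = (23, 29)

    @property
    def histogram(self) -> dict[int, int]:
        h: dict[int, int] = {}
        for iv in self.intervals:
            h[iv] = h.get(iv, 0) + 1
        return h


class _StrandIndex:
    """Per-(chrom, strand) sorted read-locus lists for window queries."""

    def __init__(self, library: MappedLibrary):
        self.rpm_factor = library.scale.rpm_factor
        buckets: dict[tuple[str, str], list] = defaultdict(list)
        for mr in library.reads:
            for chrom, start, strand in mr.loci:
                buckets[(chrom, strand)].append(
                    (start, start + len(mr.sequence), mr.sequence, mr.weight_per_locus)
                )
        self._sorted = {}
        for key, rows in buckets.items():
            rows.sort()
            self._sorted[key] = ([r[0] for r in rows], rows)

    def within(
        self, chrom: str, strand: str, lo: int, hi: int
    ) -> list[tuple[int, int, str, float]]:
        """Loci on (chrom, strand) fully contained in [lo, hi)."""
        entry = self._sorted.get((chrom, strand))
        if entry is None:
            return []
        starts, rows = entry
        i = bisect_left(starts, lo)
        j = bisect_right(starts, hi)
        return [r for r in rows[i:j] if r[1] <= hi]


def _geometry(
    guide_start: int, guide_end: int, guide_strand: str, ps: int, pe: int
) -> tuple[int, int]:
    """(inset3, inset5) in duplex register for a candidate at [ps, pe)."""
    if guide_strand == "-":
        # guide 3' terminus at genomic left (guide_start)
        return ps - guide_start, guide_end - pe
    return guide_end - pe, ps - guide_start


def find_passenger(
    guide: MappedRead,
    guide_locus: tuple[str, int, str],
    library: MappedLibrary | _StrandIndex,
    flank: int = DEFAULT_FLANK,
) -> DuplexRecord:
    """Infer the passenger strand of one 26G guide locus.

    Candidates are reads on the strand opposite the guide whose loci lie
    fully within the guide window (guide interval +/- ``flank``).  The
    passenger is the highest-weight candidate; ties break by
    |inset3 - 3| ascending, then longer read, then lexicographically
    smaller sequence.  With no candidate the record has no passenger and
    ratio 0.
    """
    if guide_locus not in guide.loci:
        raise ValueError(f"guide is not mapped at {guide_locus}")
    index = library if isinstance(library, _StrandIndex) else _StrandIndex(library)
    chrom, gstart, gstrand = guide_locus
    gend = gstart + len(guide.sequence)
    lo, hi = gstart - flank, gend + flank
    other = "+" if gstrand == "-" else "-"
    guide_rpm = guide.weight_per_locus * index.rpm_factor

    best = None
    best_key = None
    for ps, pe, seq, weight in index.within(chrom, other, lo, hi):
        i3, i5 = _geometry(gstart, gend, gstrand, ps, pe)
        key = (-weight, abs(i3 - 3), -(pe - ps), seq)
        if best_key is None or key < best_key:
            best_key = key
            best = (ps, pe, seq, weight, i3, i5)

    record = DuplexRecord(
        guide_sequence=guide.sequence,
        guide_locus=guide_locus,
        window=(lo, hi),
        guide_rpm=guide_rpm,
    )
    if best is not None:
        ps, pe, seq, weight, i3, i5 = best
        record.passenger_sequence = seq
        record.passenger_locus = (chrom, ps, other)
        record.passenger_length = pe - ps
        record.inset3 = i3
        record.inset5 = i5
        record.passenger_rpm = weight * index.rpm_factor
    return record


def find_passengers(
    guides: list[tuple[MappedRead, tuple[str, int, str]]],
    library: MappedLibrary,
    flank: int = DEFAULT_FLANK,
) -> list[DuplexRecord]:
    """Run :func:`find_passenger` over many guide loci with one index."""
    index = _StrandIndex(library)
    return [find_passenger(g, locus, index, flank) for g, locus in guides]


def _weighted_mode(values: list[int], weights: list[float]) -> int | None:
    if not values:
        return None
    acc: dict[int, float] = defaultdict(float)
    for v, w in zip(values, weights):
        acc[v] += w
    # deterministic tie-break: smaller value wins
    return min(acc, key=lambda v: (-acc[v], v))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half))
    return float(v[min(i, len(v) - 1)])


def duplex_consensus(
    records: list[DuplexRecord], guide_rpm_threshold: float = 1.0
) -> DuplexConsensus:
    """Summarize duplex geometry over one library's records.

    Modal geometry is computed over records with a passenger found,
    weighted by guide locus weight; the median passenger:guide ratio is
    over all records passing the guide RPM threshold, with an absent
    passenger counting as ratio 0.
    """
    if not records:
        raise ValueError("empty duplex record set")
    with_pass = [r for r in records if r.has_passenger]
    weights = [r.guide_rpm for r in with_pass]
    passing = [r for r in records if r.guide_rpm >= guide_rpm_threshold]
    if passing:
        ratios = np.array([r.ratio for r in passing])
        w = np.array([r.guide_rpm for r in passing])
        median_ratio = _weighted_median(ratios, w)
    else:
        median_ratio = 0.0
    return DuplexConsensus(
        modal_passenger_length=_weighted_mode(
            [r.passenger_length for r in with_pass], weights
        ),
        modal_inset3=_weighted_mode([r.inset3 for r in with_pass], weights),
        modal_inset5=_weighted_mode([r.inset5 for r in with_pass], weights),
        median_ratio=median_ratio,
        fraction_with_passenger=len(with_pass) / len(records),
        n_records=len(records),
    )


def passenger_foldchange(
    wt_records: list[DuplexRecord], mutant_records: list[DuplexRecord]
) -> float:
    """Fold-change of total passenger RPM, mutant over wild type.

    Values > 1 indicate passenger-strand stabilization (e.g. loss of the
    Argonaute slicer activity that normally destroys the passenger).
    """
    wt_total = sum(r.passenger_rpm for r in wt_records)
    if wt_total == 0:
        raise ValueError("wild-type passenger RPM total is zero")
    return sum(r.passenger_rpm for r in mutant_records) / wt_total


def template_coordinate(feature: Feature, genomic_pos: int) -> int:
    """Map a genomic position to mRNA-sense coordinates along the span."""
    if feature.strand == "+":
        return genomic_pos - feature.start
    return (feature.end - 1) - genomic_pos


def phasing_profile(
    feature: Feature,
    guides: list[tuple[MappedRead, tuple[str, int, str]]],
    band: tuple[int, int] = (23, 29),
) -> PhasingProfile:
    """Successive-interval analysis of guide 5' ends along one feature.

    ``guides`` are (read, locus) pairs antisense to the feature.  The 5'
    position of an antisense guide is its genomic right edge for a
    plus-strand feature and its genomic left edge for a minus-strand
    feature; positions are reported ascending in template coordinates.
    A single guide yields an empty interval list and an undefined
    (None) in-band fraction.
    """
    positions = []
    for mr, (chrom, start, strand) in guides:
        if chrom != feature.chrom or strand == feature.strand:
            continue
        end = start + len(mr.sequence)
        five_prime = end - 1 if strand == "-" else start
        positions.append(template_coordinate(feature, five_prime))
    positions = sorted(set(positions))
    intervals = [b - a for a, b in zip(positions, positions[1:])]
    if intervals:
        lo, hi = band
        frac = sum(lo <= iv <= hi for iv in intervals) / len(intervals)
    else:
        frac = None
    return PhasingProfile(
        feature_id=feature.id,
        positions=positions,
        intervals=intervals,
        fraction_in_band=frac,
        band=band,
    )


def guides_for_feature(
    feature: Feature, library: MappedLibrary
) -> list[tuple[MappedRead, tuple[str, int, str]]]:
    """All 26-nt 5'G read loci antisense to and overlapping a feature."""
    out = []
    for mr in library.reads:
        if len(mr.sequence) != 26 or mr.sequence[0] != "G":
            continue
        for chrom, start, strand in mr.loci:
            if chrom != feature.chrom or strand == feature.strand:
                continue
            end = start + len(mr.sequence)
            if start < feature.end and end > feature.start:
                out.append((mr, (chrom, start, strand)))
    return out


def write_duplex_records(records: list[DuplexRecord], path) -> None:
    rows = []
    for r in records:
        chrom, start, strand = r.guide_locus
        rows.append(
            {
                "guide_sequence": r.guide_sequence,
                "chrom": chrom,
                "guide_start": start,
                "guide_strand": strand,
                "guide_rpm": r.guide_rpm,
                "passenger_sequence": r.passenger_sequence or "",
                "passenger_start": (
                    r.passenger_locus[1] if r.passenger_locus else -1
                ),
                "passenger_length": r.passenger_length or 0,
                "inset3": r.inset3 if r.inset3 is not None else "",
                "inset5": r.inset5 if r.inset5 is not None else "",
                "passenger_rpm": r.passenger_rpm,
                "ratio": r.ratio,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
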