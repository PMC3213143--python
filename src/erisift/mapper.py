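"""Exact-match placement of collapsed small-RNA reads on a genome.

Reads are placed wherever they match the genome exactly and at full
length, on either strand (a match of the reverse complement to the plus
strand is recorded as a minus-strand locus).  A sequence matching
``n_loci`` positions contributes ``count / n_loci`` fractional reads to
each locus, so per-locus weights sum to the read count and library
totals are conserved.  Library-size normalization is reads per million
mapped reads (RPM); unmapped reads do not enter the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import CollapsedRead

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MappedRead:
    """A collapsed sequence placed at one or more genomic loci."""

    sequence: str
    count: int
    loci: list[tuple[str, int, str]]  # (chrom, start, strand), sorted

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def weight_per_locus(self) -> float:
        return self.count / self.n_loci

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LibraryScale:
    """Normalization constant for one mapped library."""

    total_mapped_reads: int

    @property
    def rpm_factor(self) -> float:
        if self.total_mapped_reads <= 0:
            raise ValueError("cannot normalize an empty mapped library")
        return 1e6 / self.total_mapped_reads


@dataclass
class MappedLibrary:
    """All mapped reads of one library plus its scale and drop stats."""

    reads: list[MappedRead]
    scale: LibraryScale
    n_unmapped_sequences: int = 0
    n_unmapped_read_copies: int = 0

    def rpm(self, weighted_count: float) -> float:
        return rpm(weighted_count, self.scale)


def rpm(weighted_count: float, scale: LibraryScale) -> float:
    """Convert a (possibly fractional) read count to reads per million."""
    if weighted_count < 0:
        raise ValueError("weighted_count must be >= 0")
    return weighted_count * scale.rpm_factor


class GenomeIndex:
    """Exact-match index over both strands of a genome.

    Per read length L, a dict from every plus-strand L-mer to its start
    positions is built lazily on first use; minus-strand matches are
    found by looking up the read's reverse complement.
    """

    def __init__(self, chroms: dict[str, str]):
        self.chroms = {name: seq.upper() for name, seq in chroms.items()}
        self._by_length: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, length: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._by_length.get(length)
        if idx is None:
            idx = {}
            for name in sorted(self.chroms):
                seq = self.chroms[name]
                for start in range(0, len(seq) - length + 1):
                    idx.setdefault(seq[start : start + length], []).append(
                        (name, start)
                    )
            self._by_length[length] = idx
        return idx

    def find(self, sequence: str) -> list[tuple[str, int, str]]:
        """All exact full-length loci of ``sequence``, deterministic order."""
        idx = self._index_for(len(sequence))
        loci = [(c, s, "+") for c, s in idx.get(sequence, ())]
        rc = revcomp(sequence)
        loci += [(c, s, "-") for c, s in idx.get(rc, ())]
        # a palindromic read would list a locus once per strand; that is
        # intended (it genuinely matches both orientations)
        return sorted(loci)


def map_reads(
    reads: list[CollapsedRead],
    genome: dict[str, str] | GenomeIndex,
) -> MappedLibrary:
    """Place collapsed reads on the genome by exact full-length matching.

    Reads with zero loci are dropped and counted; the RPM denominator is
    the summed count of mapped read copies (sequencing depth), not the
    number of distinct sequences.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    mapped: list[MappedRead] = []
    n_unmapped_seq = 0
    n_unmapped_copies = 0
    total = 0
    for read in reads:
        loci = index.find(read.sequence)
        if not loci:
            n_unmapped_seq += 1
            n_unmapped_copies += read.count
            continue
        mapped.append(MappedRead(read.sequence, read.count, loci))
        total += read.count
    return MappedLibrary(
        reads=mapped,
        scale=LibraryScale(total_mapped_reads=total),
        n_unmapped_sequences=n_unmapped_seq,
        n_unmapped_read_copies=n_unmapped_copies,
    )


def scan_loci_bruteforce(
    sequence: str, chroms: dict[str, str]
) -> list[tuple[str, int, str]]:
    """Naive all-positions substring scan over both strands.

    Independent oracle for :meth:`GenomeIndex.find` on toy genomes.
    """
    hits = []
    rc = revcomp(sequence)
    for name in sorted(chroms):
        seq = chroms[name].upper()
        for query, strand in ((sequence, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                hits.append((name, start, strand))
                start = seq.find(query, start + 1)
    return sorted(hits)
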