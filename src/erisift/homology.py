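"""Sequence homology among siRNA target genes.

Recently duplicated genes are detected by pairwise comparison of gene
sequences (plus 0.5 kb of flanking sequence on each side): a pair
qualifies as homologous when the best local alignment shows more than
82% nucleotide identity *and* the two sequences share a perfect stretch
of at least 27 nt.  Qualifying pairs are clustered by single linkage
into homology groups, and the same criterion applied to random gene
samples of matched combined length provides the background rate.

Local alignment uses Biopython's PairwiseAligner (match +1, mismatch
-2; a gap of length L costs 5 + 2*(L-1)); the longest perfect stretch
is the exact longest common substring, computed with a suffix
automaton.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from Bio import Align

from .io import Feature
from .mapper import revcomp

PROXIMITY_GAP = 5000  #: nt; "close proximity" threshold between gene spans


@dataclass
class FlankedSequence:
    feature_id: str
    sequence: str
    clipped: bool


@dataclass
class HomologyEdge:
    """Pairwise homology measurement between two features."""

    a: str
    b: str
    percent_identity: float
    aligned_length: int
    longest_exact_stretch: int
    proximity_flag: bool = False


@dataclass
class HomologyGroup:
    members: frozenset[str]
    edges: list[HomologyEdge]


def flanked_sequence(
    feature: Feature, genome: dict[str, str], flank: int = 500
) -> FlankedSequence:
    """Gene span plus flanks, sense-strand orientation, clipped at edges."""
    chrom = genome[feature.chrom]
    lo = feature.start - flank
    hi = feature.end + flank
    clipped = lo < 0 or hi > len(chrom)
    lo, hi = max(lo, 0), min(hi, len(chrom))
    seq = chrom[lo:hi]
    if feature.strand == "-":
        seq = revcomp(seq)
    return FlankedSequence(feature.id, seq, clipped)


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = 1
    aln.mismatch_score = -2
    aln.open_gap_score = -5
    aln.extend_gap_score = -2
    return aln


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring, via a suffix automaton of ``a``."""
    if not a or not b:
        return 0
    # suffix automaton of a
    link = [-1]
    length = [0]
    trans: list[dict[str, int]] = [{}]
    last = 0
    for ch in a:
        cur = len(length)
        length.append(length[last] + 1)
        link.append(-1)
        trans.append({})
        p = last
        while p != -1 and ch not in trans[p]:
            trans[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = trans[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(length)
                length.append(length[p] + 1)
                link.append(link[q])
                trans.append(dict(trans[q]))
                while p != -1 and trans[p].get(ch) == q:
                    trans[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur
    # walk b through the automaton
    best = 0
    v, l = 0, 0
    for ch in b:
        while v != 0 and ch not in trans[v]:
            v = link[v]
            l = length[v]
        if ch in trans[v]:
            v = trans[v][ch]
            l += 1
            if l > best:
                best = l
    return best


def longest_common_substring_bruteforce(a: str, b: str) -> int:
    """O(n*m) dynamic-programming oracle for the longest common substring."""
    if not a or not b:
        return 0
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(bb), dtype=np.int32)
    best = 0
    for x in aa:
        eq = (bb == x).astype(np.int32)
        cur = eq.copy()
        cur[1:] += prev[:-1] * eq[1:]
        best = max(best, int(cur.max()))
        prev = cur
    return best


def pair_identity(
    seq_a: str, seq_b: str, a: str = "a", b: str = "b"
) -> HomologyEdge:
    """Percent identity of the best local alignment plus the exact stretch.

    Identity is matches over aligned columns (gap columns included), as
    a BLAST-style percentage; ``aligned_length`` is the number of
    columns of that alignment.  The longest exact stretch is computed
    exactly and independently of the alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner()
    alignments = aligner.align(seq_a, seq_b)
    stretch = longest_common_substring(seq_a, seq_b)
    if alignments.score <= 0:
        return HomologyEdge(a, b, 0.0, 0, stretch)
    best = alignments[0]
    counts = best.counts()
    aligned_cols = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    return HomologyEdge(a, b, identity, aligned_cols, stretch)


def proximity(f1: Feature, f2: Feature, max_gap: int = PROXIMITY_GAP) -> bool:
    """Same chromosome with a strict < ``max_gap`` nt gap between spans."""
    if f1.chrom != f2.chrom:
        return False
    gap = max(f1.start, f2.start) - min(f1.end, f2.end)
    return gap < max_gap


def build_edges(
    features: list[Feature],
    genome: dict[str, str],
    flank: int = 500,
    use_flanks: bool = True,
) -> list[HomologyEdge]:
    """All pairwise homology edges among ``features``."""
    seqs = {}
    for f in features:
        if use_flanks:
            seqs[f.id] = flanked_sequence(f, genome, flank).sequence
        else:
            chrom = genome[f.chrom]
            s = chrom[f.start : f.end]
            seqs[f.id] = revcomp(s) if f.strand == "-" else s
    by_id = {f.id: f for f in features}
    edges = []
    for fa, fb in itertools.combinations(sorted(seqs), 2):
        edge = pair_identity(seqs[fa], seqs[fb], fa, fb)
        edge.proximity_flag = proximity(by_id[fa], by_id[fb])
        edges.append(edge)
    return edges


def qualifying_edge(
    edge: HomologyEdge,
    identity_threshold: float = 82.0,
    stretch_threshold: int = 27,
    min_aligned: int = 100,
) -> bool:
    """True iff identity is strictly above threshold, the perfect stretch
    is at least ``stretch_threshold`` nt, and the alignment covers at
    least ``min_aligned`` columns."""
    return (
        edge.percent_identity > identity_threshold
        and edge.longest_exact_stretch >= stretch_threshold
        and edge.aligned_length >= min_aligned
    )


def cluster(
    feature_ids: list[str],
    edges: list[HomologyEdge],
    identity_threshold: float = 82.0,
    stretch_threshold: int = 27,
    min_aligned: int = 100,
) -> list[HomologyGroup]:
    """Single-linkage connected components under qualifying edges.

    Features without any qualifying edge remain singletons and are not
    reported as groups.
    """
    keep = [
        e
        for e in edges
        if qualifying_edge(e, identity_threshold, stretch_threshold, min_aligned)
        and e.a in set(feature_ids)
        and e.b in set(feature_ids)
    ]
    g = nx.Graph()
    for e in keep:
        g.add_edge(e.a, e.b)
    groups = []
    for comp in nx.connected_components(g):
        members = frozenset(comp)
        groups.append(
            HomologyGroup(
                members=members,
                edges=[e for e in keep if e.a in members and e.b in members],
            )
        )
    groups.sort(key=lambda gr: sorted(gr.members)[0])
    return groups


def background_fraction(
    features: list[Feature],
    genome: dict[str, str],
    target_ids: set[str],
    n_genes: int,
    n_draws: int,
    seed: int,
    flank: int = 500,
    length_tolerance: float = 0.10,
    exclude_ids: set[str] | None = None,
    **thresholds,
) -> float:
    """Fraction of randomly drawn genes with >= 1 qualifying edge.

    Each draw samples ``n_genes`` features from the non-target pool such
    that the combined flanked sequence length matches the target set's
    within ``length_tolerance``; the result is the mean over draws of
    the fraction of sampled genes having at least one qualifying edge
    within the sample.
    """
    rng = np.random.default_rng(seed)
    exclude = set(target_ids) | set(exclude_ids or ())
    pool = [
        f
        for f in features
        if f.id not in exclude and f.biotype in {"coding", "pseudogene", "transposon"}
    ]
    if len(pool) < n_genes:
        raise ValueError(
            f"need at least {n_genes} non-target genes, found {len(pool)}"
        )
    by_id = {f.id: f for f in features}
    target_len = sum(
        len(flanked_sequence(by_id[t], genome, flank).sequence)
        for t in target_ids
        if t in by_id
    )
    fractions = []
    for _ in range(n_draws):
        sample = None
        for _attempt in range(200):
            cand = list(rng.choice(len(pool), size=n_genes, replace=False))
            feats = [pool[i] for i in cand]
            combined = sum(
                len(flanked_sequence(f, genome, flank).sequence) for f in feats
            )
            if target_len == 0 or abs(combined - target_len) <= length_tolerance * target_len:
                sample = feats
                break
        if sample is None:
            # fall back to the closest-length sample seen last
            sample = feats
        edges = build_edges(sample, genome, flank=flank)
        with_edge = set()
        for e in edges:
            if qualifying_edge(e, **thresholds):
                with_edge.update((e.a, e.b))
        fractions.append(len(with_edge) / n_genes)
    return float(np.mean(fractions))


def gene_structure_stats(
    feature_ids: set[str] | list[str], features: list[Feature]
) -> dict[str, float]:
    """Median exon count and mean span length of a feature set,
    alongside the same summaries over the whole annotation."""
    by_id = {f.id: f for f in features}
    chosen = [by_id[i] for i in feature_ids if i in by_id]
    if not chosen:
        raise ValueError("empty feature set")
    genes = [f for f in features if f.biotype in {"coding", "pseudogene", "transposon"}]
    return {
        "set_median_exons": float(np.median([len(f.exons) for f in chosen])),
        "set_mean_length": float(np.mean([f.end - f.start for f in chosen])),
        "genome_median_exons": float(np.median([len(f.exons) for f in genes])),
        "genome_mean_length": float(np.mean([f.end - f.start for f in genes])),
    }
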