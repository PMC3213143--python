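"""Mutant-versus-wild-type comparisons of small-RNA abundance.

Implements the threshold-based calling scheme used throughout this kind
of analysis: a feature is an siRNA target of the pathway if it carries
>= 10 RPM of antisense siRNA reads in wild type and loses >= 67% of them
(ratio <= 1/3, ties passing) in every required mutant; individual guide
siRNAs are called the same way at a 1 RPM threshold.  Class- or
subset-level depletion is reported as a percentage of wild-type RPM.
No statistical test is applied: the method is deliberately a
thresholding scheme, not a differential-abundance model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import LibraryProfile


@dataclass
class TargetCall:
    """A feature-level depletion call."""

    feature_id: str
    wt_rpm: float
    mutant_rpm: dict[str, float]
    ratio: dict[str, float]
    passes_wt_threshold: bool
    depleted_in: set[str]


@dataclass
class SiRNACall:
    """A single-guide depletion call (26G sequence resolution)."""

    sequence: str
    wt_rpm: float
    ratio: dict[str, float]
    passed: bool


@dataclass
class WindowTrack:
    """Sliding-window log2 mutant/wild-type ratio along one chromosome."""

    chrom: str
    starts: np.ndarray
    widths: np.ndarray
    wt_rpm: np.ndarray
    mut_rpm: np.ndarray
    log2_ratio: np.ndarray
    dominant_length: np.ndarray


def _ratios(
    wt: LibraryProfile,
    mutants: dict[str, LibraryProfile],
    wt_values: pd.Series,
    getter,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    mut_vals = pd.DataFrame(
        {g: getter(p).reindex(wt_values.index).fillna(0.0) for g, p in mutants.items()}
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = mut_vals.div(wt_values, axis=0)
    return mut_vals, ratios


def call_targets(
    wt: LibraryProfile,
    mutants: dict[str, LibraryProfile],
    rpm_threshold: float = 10.0,
    depletion: float = 2 / 3,
    require: set[str] | None = None,
) -> list[TargetCall]:
    """Call features depleted of antisense siRNA reads in mutants.

    A feature is called iff its wild-type antisense RPM is >=
    ``rpm_threshold`` and mutant/wt <= 1 - ``depletion`` in *every*
    genotype in ``require``.  "Depleted by >= 67%" is read inclusively:
    the default ``depletion`` of 2/3 puts the cutoff at exactly 1/3 and
    a tie at 1/3 passes.  With ``require`` empty, the call set is
    the wild-type-threshold-passing set.  Output is sorted by wild-type
    RPM, descending.
    """
    require = set(require or ())
    missing = require - set(mutants)
    if missing:
        raise ValueError(f"required genotype(s) missing a profile: {sorted(missing)}")
    wt_vals = wt.feature_table["antisense_rpm"]
    mut_vals, ratios = _ratios(
        wt, mutants, wt_vals, lambda p: p.feature_table["antisense_rpm"]
    )
    calls = []
    cutoff = 1.0 - depletion
    for fid in wt_vals.index:
        w = float(wt_vals[fid])
        if w < rpm_threshold:
            continue
        rr = {g: float(ratios.loc[fid, g]) for g in mutants}
        depleted = {g for g, r in rr.items() if r <= cutoff + 1e-12}
        if require <= depleted:
            calls.append(
                TargetCall(
                    feature_id=fid,
                    wt_rpm=w,
                    mutant_rpm={g: float(mut_vals.loc[fid, g]) for g in mutants},
                    ratio=rr,
                    passes_wt_threshold=True,
                    depleted_in=depleted,
                )
            )
    calls.sort(key=lambda c: (-c.wt_rpm, c.feature_id))
    return calls


def call_sirnas(
    wt: LibraryProfile,
    mutants: dict[str, LibraryProfile],
    rpm_threshold: float = 1.0,
    depletion: float = 2 / 3,
    require: set[str] | None = None,
) -> list[SiRNACall]:
    """Call individual 26G guide sequences depleted in mutants."""
    require = set(require if require is not None else mutants)
    missing = require - set(mutants)
    if missing:
        raise ValueError(f"required genotype(s) missing a profile: {sorted(missing)}")
    wt_vals = wt.guide_table["rpm"]
    mut_vals, ratios = _ratios(
        wt, mutants, wt_vals, lambda p: p.guide_table["rpm"]
    )
    cutoff = 1.0 - depletion
    calls = []
    for seq in wt_vals.index:
        w = float(wt_vals[seq])
        if w < rpm_threshold:
            continue
        rr = {g: float(ratios.loc[seq, g]) for g in mutants}
        passed = all(rr[g] <= cutoff + 1e-12 for g in require)
        if passed:
            calls.append(SiRNACall(sequence=seq, wt_rpm=w, ratio=rr, passed=True))
    calls.sort(key=lambda c: (-c.wt_rpm, c.sequence))
    return calls


def class_depletion(
    wt: LibraryProfile,
    mutant: LibraryProfile,
    klass: str | None = None,
    subset: list[str] | set[str] | None = None,
) -> float:
    """Percent depletion of a class and/or feature subset in a mutant.

    Returns ``100 * (1 - sum(mutant RPM) / sum(wt RPM))`` over the
    selection; negative values indicate enrichment.  With ``klass``
    only, the selection is the library-wide class total; with ``subset``
    only, the total antisense RPM over those features; with both, the
    per-feature antisense RPM of that length class over the subset.
    """
    if klass is None and subset is None:
        raise ValueError("specify a class, a subset, or both")

    def total(p: LibraryProfile) -> float:
        if subset is None:
            return p.class_rpm[klass]
        ids = [i for i in subset if i in p.feature_table.index]
        if klass is None:
            return float(p.feature_table.loc[ids, "antisense_rpm"].sum())
        col = {"26G": "antisense_26g_rpm", "22G": "antisense_22g_rpm"}.get(klass)
        if col is None:
            raise ValueError(f"subset-restricted depletion undefined for {klass!r}")
        return float(p.feature_table.loc[ids, col].sum())

    wt_total = total(wt)
    if wt_total == 0:
        raise ValueError("wild-type RPM total is zero; depletion undefined")
    return 100.0 * (1.0 - total(mutant) / wt_total)


def window_starts(chrom_length: int, width: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Window starts/widths: full windows while start + width <= length,
    plus one truncated terminal window when the chromosome end is not
    flush with the last full window."""
    if chrom_length <= width:
        return np.array([0]), np.array([min(width, chrom_length)])
    last_full = (chrom_length - width) // step * step
    starts = list(range(0, last_full + 1, step))
    widths = [width] * len(starts)
    if last_full + width < chrom_length:
        starts.append(last_full + step)
        widths.append(chrom_length - starts[-1])
    return np.array(starts), np.array(widths)


def window_track(
    wt: LibraryProfile,
    mutant: LibraryProfile,
    chrom_lengths: dict[str, int],
    width: int = 5000,
    step: int = 1000,
    pseudocount: float = 1.0,
) -> dict[str, WindowTrack]:
    """5-kb / 1-kb sliding-window mutant-to-wild-type RPM ratio tracks.

    A read locus is assigned to every window containing its start
    position.  The log2 ratio uses ``pseudocount`` RPM on both sides;
    the dominant length class per window is taken over the summed wt and
    mutant RPM.
    """
    tracks = {}
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        starts, widths = window_starts(L, width, step)
        n = len(starts)
        wt_w = np.zeros(n)
        mut_w = np.zeros(n)
        len_w: dict[int, np.ndarray] = {}

        def accumulate(prof: LibraryProfile, acc: np.ndarray) -> None:
            factor = prof.library.scale.rpm_factor
            for mr in prof.library.reads:
                w_rpm = mr.weight_per_locus * factor
                for c, s, _strand in mr.loci:
                    if c != chrom:
                        continue
                    idx = np.nonzero((starts <= s) & (s < starts + widths))[0]
                    acc[idx] += w_rpm
                    lw = len_w.setdefault(len(mr.sequence), np.zeros(n))
                    lw[idx] += w_rpm

        accumulate(wt, wt_w)
        accumulate(mutant, mut_w)
        log2r = np.log2((mut_w + pseudocount) / (wt_w + pseudocount))
        if len_w:
            lengths = sorted(len_w)
            stack = np.vstack([len_w[l] for l in lengths])
            dominant = np.array(lengths)[np.argmax(stack, axis=0)]
            dominant[stack.sum(axis=0) == 0] = 0
        else:
            dominant = np.zeros(n, dtype=int)
        tracks[chrom] = WindowTrack(
            chrom=chrom,
            starts=starts,
            widths=widths,
            wt_rpm=wt_w,
            mut_rpm=mut_w,
            log2_ratio=log2r,
            dominant_length=dominant,
        )
    return tracks


def call_overlap(
    calls_a: list[TargetCall], calls_b: list[TargetCall]
) -> tuple[set[str], set[str], set[str]]:
    """Overlap between two call sets: (shared, only_a, only_b).

    Used e.g. to intersect embryo- and adult-stage target calls.
    """
    a = {c.feature_id for c in calls_a}
    b = {c.feature_id for c in calls_b}
    return a & b, a - b, b - a


def write_target_calls(calls: list[TargetCall], path) -> None:
    rows = []
    for c in calls:
        row = {"feature": c.feature_id, "wt_rpm": c.wt_rpm}
        for g in sorted(c.ratio):
            row[f"rpm_{g}"] = c.mutant_rpm[g]
            row[f"ratio_{g}"] = c.ratio[g]
        row["depleted_in"] = ",".join(sorted(c.depleted_in))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_window_tracks(tracks: dict[str, WindowTrack], path) -> None:
    rows = []
    for chrom in sorted(tracks):
        t = tracks[chrom]
        for i in range(len(t.starts)):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(t.starts[i]),
                    "end": int(t.starts[i] + t.widths[i]),
                    "wt_rpm": t.wt_rpm[i],
                    "mut_rpm": t.mut_rpm[i],
                    "log2_ratio": t.log2_ratio[i],
                    "dominant_length": int(t.dominant_length[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
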