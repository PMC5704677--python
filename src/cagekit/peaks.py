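"""Promoter (peak) identification from pooled CTSS signal.

Candidate regions of continuous composite signal are clustered per strand,
decomposed at smoothed-signal valleys into sub-peaks, and tiered:

* permissive — some sample has a single CTSS position with >= 3 tags inside;
* robust     — some sample has a single position with >= 10 tags whose
  per-sample TPM is also >= 1 (robust peaks are always permissive too).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .ctss import CtssProfile, SampleLibrary, tags_per_million
from .io import peak_name

DEFAULT_MAX_GAP = 20
DEFAULT_PERMISSIVE_MIN = 3
DEFAULT_ROBUST_MIN = 10
DEFAULT_ROBUST_TPM = 1.0


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty interval")


@dataclass
class Peak:
    """A called promoter region with per-sample expression."""

    chrom: str
    start: int
    end: int
    strand: str
    tier: str                       # 'permissive' | 'robust'
    counts: dict[str, int] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)
    pooled_count: int = 0
    summit: Optional[int] = None    # pooled-signal argmax position

    @property
    def name(self) -> str:
        return peak_name(self.chrom, self.start, self.end, self.strand)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def is_robust(self) -> bool:
        return self.tier == "robust"


def cluster_ctss(pooled: CtssProfile, max_gap: int = DEFAULT_MAX_GAP) -> list[Interval]:
    """Merge same-strand CTSS positions whose pairwise gap is <= max_gap.

    Interval bounds are [min position, max position + 1); '+' and '-'
    signal is never merged.
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for (chrom, pos, strand) in pooled.counts:
        by_key.setdefault((chrom, strand), []).append(pos)
    intervals: list[Interval] = []
    for (chrom, strand), positions in by_key.items():
        positions.sort()
        run_start = positions[0]
        prev = positions[0]
        for pos in positions[1:]:
            if pos - prev > max_gap:
                intervals.append(Interval(chrom, run_start, prev + 1, strand))
                run_start = pos
            prev = pos
        intervals.append(Interval(chrom, run_start, prev + 1, strand))
    intervals.sort()
    return intervals


def _local_maxima(arr: np.ndarray) -> list[int]:
    """Indices of local maxima (plateau-tolerant: first index of each plateau)."""
    maxima = []
    n = len(arr)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and arr[j + 1] == arr[i]:
            j += 1
        left_ok = i == 0 or arr[i - 1] < arr[i]
        right_ok = j == n - 1 or arr[j + 1] < arr[i]
        if left_ok and right_ok and arr[i] > 0:
            maxima.append(i)
        i = j + 1
    return maxima


def decompose_cluster(
    interval: Interval,
    pooled: CtssProfile,
    smooth_sd: float = 5.0,
    valley_fraction: float = 0.1,
    min_subpeak_gap: int = 10,
) -> list[Interval]:
    """Split a candidate interval at deep valleys of the smoothed pooled signal.

    The pooled per-position signal is Gaussian-smoothed (SD ``smooth_sd``);
    between every pair of adjacent local maxima at distance >=
    ``min_subpeak_gap`` the minimum is located, and the interval is split
    there when the smoothed minimum is < ``valley_fraction`` times the
    smaller flanking maximum. Sub-intervals are trimmed to their CTSS
    support; their positions partition the parent's exactly.
    """
    positions = sorted(
        pos
        for (chrom, pos, strand) in pooled.counts
        if chrom == interval.chrom
        and strand == interval.strand
        and interval.start <= pos < interval.end
    )
    if not positions:
        return []
    offset = interval.start
    arr = np.zeros(interval.end - interval.start, dtype=float)
    for pos in positions:
        arr[pos - offset] = pooled.get(interval.chrom, pos, interval.strand)
    smoothed = gaussian_filter1d(arr, smooth_sd, mode="constant")
    maxima = _local_maxima(smoothed)
    cuts: list[int] = []
    for m1, m2 in zip(maxima, maxima[1:]):
        if m2 - m1 < min_subpeak_gap:
            continue
        seg = smoothed[m1 : m2 + 1]
        v = int(np.argmin(seg)) + m1
        if smoothed[v] < valley_fraction * min(smoothed[m1], smoothed[m2]):
            cuts.append(v)
    if not cuts:
        return [Interval(interval.chrom, positions[0], positions[-1] + 1, interval.strand)]
    # positions <= a cut point belong to the left sub-interval
    out: list[Interval] = []
    bounds = [c + offset for c in cuts] + [interval.end]
    lo = interval.start - 1
    for hi in bounds:
        sub = [p for p in positions if lo < p <= hi] if hi != interval.end else [p for p in positions if lo < p]
        if sub:
            out.append(Interval(interval.chrom, sub[0], sub[-1] + 1, interval.strand))
        lo = hi
    return out


def call_peaks(
    sub_intervals: Iterable[Interval],
    libraries: list[SampleLibrary],
    permissive_min: int = DEFAULT_PERMISSIVE_MIN,
    robust_min: int = DEFAULT_ROBUST_MIN,
    robust_tpm: float = DEFAULT_ROBUST_TPM,
) -> list[Peak]:
    """Tier candidate sub-intervals into permissive/robust peaks.

    A sub-interval becomes a permissive peak iff some sample has a single
    CTSS position inside it with count >= ``permissive_min``; it is robust
    iff some sample has a position with count >= ``robust_min`` whose TPM
    in that same sample is >= ``robust_tpm``. Peaks are trimmed to the
    [min, max+1] span of surviving CTSS positions (pooled over samples).
    """
    import bisect

    totals = {lib.sample_id: lib.total_tags for lib in libraries}
    # per library, per (chrom, strand): parallel sorted arrays of positions/counts
    indexed: list[dict[tuple[str, str], tuple[list[int], list[int]]]] = []
    for lib in libraries:
        d: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        for (chrom, pos, strand), count in sorted(lib.profile.counts.items()):
            positions, cnts = d.setdefault((chrom, strand), ([], []))
            positions.append(pos)
            cnts.append(count)
        indexed.append(d)
    peaks: list[Peak] = []
    for iv in sub_intervals:
        permissive = False
        robust = False
        pooled_at: dict[int, int] = {}
        for lib, d in zip(libraries, indexed):
            lists = d.get((iv.chrom, iv.strand))
            if lists is None:
                continue
            positions, cnts = lists
            lo_i = bisect.bisect_left(positions, iv.start)
            hi_i = bisect.bisect_left(positions, iv.end)
            for k in range(lo_i, hi_i):
                pos, count = positions[k], cnts[k]
                pooled_at[pos] = pooled_at.get(pos, 0) + count
                if count >= permissive_min:
                    permissive = True
                if count >= robust_min and tags_per_million(count, totals[lib.sample_id]) >= robust_tpm:
                    robust = True
        if not permissive:
            continue
        summit_pos, summit_count = None, -1
        for pos in sorted(pooled_at):
            if pooled_at[pos] > summit_count:
                summit_pos, summit_count = pos, pooled_at[pos]
        lo, hi = min(pooled_at), max(pooled_at) + 1
        peaks.append(
            Peak(
                chrom=iv.chrom,
                start=lo,
                end=hi,
                strand=iv.strand,
                tier="robust" if robust else "permissive",
                pooled_count=sum(pooled_at.values()),
                summit=summit_pos,
            )
        )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.strand))
    return peaks


def identify_peaks(
    libraries: list[SampleLibrary],
    max_gap: int = DEFAULT_MAX_GAP,
    smooth_sd: float = 5.0,
    valley_fraction: float = 0.1,
    min_subpeak_gap: int = 10,
    permissive_min: int = DEFAULT_PERMISSIVE_MIN,
    robust_min: int = DEFAULT_ROBUST_MIN,
    robust_tpm: float = DEFAULT_ROBUST_TPM,
) -> list[Peak]:
    """Full peak identification: pool, cluster, decompose, tier, quantify."""
    from .ctss import pool_samples

    pooled = pool_samples(libraries)
    subs: list[Interval] = []
    for iv in cluster_ctss(pooled, max_gap=max_gap):
        subs.extend(
            decompose_cluster(
                iv, pooled, smooth_sd=smooth_sd,
                valley_fraction=valley_fraction, min_subpeak_gap=min_subpeak_gap,
            )
        )
    peaks = call_peaks(
        subs, libraries,
        permissive_min=permissive_min, robust_min=robust_min, robust_tpm=robust_tpm,
    )
    quantify_peak_expression(peaks, libraries)
    return peaks


def quantify_peak_expression(
    peaks: list[Peak], libraries: list[SampleLibrary]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak per-sample counts and TPM; also fills each Peak's maps.

    Returns (counts, tpm) DataFrames with peak names as the index.
    """
    sample_ids = [lib.sample_id for lib in libraries]
    counts = np.zeros((len(peaks), len(sample_ids)), dtype=int)
    index: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for i, p in enumerate(peaks):
        index.setdefault((p.chrom, p.strand), []).append((p.start, p.end, i))
    for key in index:
        index[key].sort()
    for j, lib in enumerate(libraries):
        for (chrom, pos, strand), count in lib.profile.counts.items():
            for (s, e, i) in index.get((chrom, strand), ()):
                if s <= pos < e:
                    counts[i, j] += count
                elif s > pos:
                    break
    totals = np.array([lib.total_tags for lib in libraries], dtype=float)
    tpm = counts / totals[None, :] * 1e6
    names = [p.name for p in peaks]
    counts_df = pd.DataFrame(counts, index=pd.Index(names, name="peak"), columns=sample_ids)
    tpm_df = pd.DataFrame(tpm, index=pd.Index(names, name="peak"), columns=sample_ids)
    for i, p in enumerate(peaks):
        p.counts = {s: int(counts[i, j]) for j, s in enumerate(sample_ids)}
        p.tpm = {s: float(tpm[i, j]) for j, s in enumerate(sample_ids)}
    return counts_df, tpm_df


def fraction_tags_in_peaks(
    libraries: list[SampleLibrary], peaks: list[Peak]
) -> dict[str, float]:
    """Per-sample fraction of mapped tags falling inside any called peak."""
    import bisect

    by_key: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
    for p in peaks:
        starts, ends = by_key.setdefault((p.chrom, p.strand), ([], []))
        starts.append(p.start)
        ends.append(p.end)
    for key, (starts, ends) in by_key.items():
        order = sorted(range(len(starts)), key=lambda i: starts[i])
        by_key[key] = ([starts[i] for i in order], [ends[i] for i in order])
    out: dict[str, float] = {}
    for lib in libraries:
        inside = 0
        for (chrom, pos, strand), count in lib.profile.counts.items():
            lists = by_key.get((chrom, strand))
            if lists is None:
                continue
            starts, ends = lists
            i = bisect.bisect_right(starts, pos) - 1
            # peaks on a strand may abut but never overlap; one probe suffices
            if i >= 0 and pos < ends[i]:
                inside += count
        total = lib.total_tags
        out[lib.sample_id] = inside / total if total else 0.0
    return out


def write_peaks_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.strand)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.pooled_count}\t{p.strand}\n")
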