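"""Interval projection through chain files and peak matching.

A stranded interval is projected base-by-base through the highest-scoring
chain whose aligned blocks carry at least ``min_match`` of its bases; the
projected interval is the [min, max+1) hull of the mapped bases, with the
strand composed from the chain orientation. Projected source peaks are then
matched to destination peaks when both boundaries agree within 50 bp.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import ChainMap, parse_interval_name
from .peaks import Peak

DEFAULT_MIN_MATCH = 0.95
DEFAULT_MAX_DIST = 50


@dataclass(frozen=True)
class ProjectionResult:
    """Outcome of projecting one interval; unmapped results carry a reason."""

    mapped: bool
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    reason: Optional[str] = None
    chain_id: Optional[int] = None
    fraction: float = 0.0


@dataclass(frozen=True)
class ProjectionMatch:
    source_name: str
    proj_chrom: str
    proj_start: int
    proj_end: int
    proj_strand: str
    dest_name: Optional[str]
    d_start: Optional[int]
    d_end: Optional[int]
    source_expressed: bool = True

    @property
    def matched(self) -> bool:
        return self.dest_name is not None


class _ChainIndex:
    """Bisect-ready view of one chain's aligned segments."""

    def __init__(self, chain: ChainMap) -> None:
        self.chain = chain
        segs = chain.segments()
        self.t_starts = [t for (t, _, _) in segs]
        self.segs = segs

    def map_base(self, pos: int) -> Optional[tuple[int, str]]:
        """Map a source base to (dest plus-strand position, dest strand)."""
        i = bisect.bisect_right(self.t_starts, pos) - 1
        if i < 0:
            return None
        t0, q0, size = self.segs[i]
        if not (t0 <= pos < t0 + size):
            return None
        q = q0 + (pos - t0)
        chain = self.chain
        if chain.q_strand == "+":
            return q, "+"
        return chain.q_size - 1 - q, "-"


def _compose_strand(interval_strand: str, q_strand: str) -> str:
    if q_strand == "+":
        return interval_strand
    return "-" if interval_strand == "+" else "+"


def project_interval(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    chains: Sequence[ChainMap],
    min_match: float = DEFAULT_MIN_MATCH,
) -> ProjectionResult:
    """Project [start, end) on ``strand`` through the best covering chain.

    The interval maps iff >= ``min_match`` of its bases land on a single
    chain's aligned blocks; among qualifying chains the highest-scoring one
    wins. Reasons for failure: "no chain" (no chain touches the interval's
    chromosome/span) or "partial" (best coverage below min_match).
    """
    if end <= start:
        raise ValueError("empty interval")
    candidates = [
        c for c in chains
        if c.t_name == chrom and c.t_start < end and start < c.t_end
    ]
    if not candidates:
        return ProjectionResult(mapped=False, reason="no chain")
    best: Optional[tuple[float, float, ChainMap, list[int], str]] = None
    n = end - start
    for chain in sorted(candidates, key=lambda c: -c.score):
        idx = _ChainIndex(chain)
        mapped_positions: list[int] = []
        dest_strand = None
        for pos in range(start, end):
            hit = idx.map_base(pos)
            if hit is None:
                continue
            qpos, qstrand = hit
            mapped_positions.append(qpos)
            dest_strand = qstrand
        frac = len(mapped_positions) / n
        if best is None or frac > best[0]:
            best = (frac, chain.score, chain, mapped_positions, dest_strand or chain.q_strand)
        if frac >= min_match:
            return ProjectionResult(
                mapped=True,
                chrom=chain.q_name,
                start=min(mapped_positions),
                end=max(mapped_positions) + 1,
                strand=_compose_strand(strand, chain.q_strand),
                chain_id=chain.chain_id,
                fraction=frac,
            )
    return ProjectionResult(mapped=False, reason="partial", fraction=best[0] if best else 0.0)


def project_peaks(
    peaks_or_names: Iterable,
    chains: Sequence[ChainMap],
    min_match: float = DEFAULT_MIN_MATCH,
) -> dict[str, ProjectionResult]:
    """Project many peaks (Peak objects or canonical name strings)."""
    out: dict[str, ProjectionResult] = {}
    for p in peaks_or_names:
        if isinstance(p, str):
            chrom, start, end, strand = parse_interval_name(p)
            name = p
        else:
            chrom, start, end, strand, name = p.chrom, p.start, p.end, p.strand, p.name
        out[name] = project_interval(chrom, start, end, strand, chains, min_match=min_match)
    return out


def filter_expressed(
    expression: pd.DataFrame,
    matching_samples: Sequence[str],
    min_tpm: float = 0.0,
) -> set[str]:
    """Peak names expressed (>= min_tpm, nonzero) in >= 1 matching sample."""
    unknown = [s for s in matching_samples if s not in expression.columns]
    if unknown:
        raise KeyError(f"unknown sample labels in expression matrix: {unknown}")
    sub = expression[list(matching_samples)]
    mask = ((sub >= min_tpm) & (sub > 0)).any(axis=1)
    return set(sub.index[mask])


def match_projected_peaks(
    projected: dict[str, ProjectionResult],
    dest_peaks: Sequence[Peak],
    max_dist: int = DEFAULT_MAX_DIST,
    expressed: Optional[set[str]] = None,
) -> list[ProjectionMatch]:
    """Match projected source peaks to destination peaks.

    A projected peak matches a dest peak iff same chrom and strand,
    |dStart| <= max_dist and |dEnd| <= max_dist. Among several candidates
    the one minimizing |dStart|+|dEnd| wins; ties go to the leftmost dest
    start. Unmapped projections are skipped.
    """
    by_key: dict[tuple[str, str], list[Peak]] = {}
    for p in dest_peaks:
        by_key.setdefault((p.chrom, p.strand), []).append(p)
    for key in by_key:
        by_key[key].sort(key=lambda p: p.start)
    out: list[ProjectionMatch] = []
    for name in sorted(projected):
        res = projected[name]
        if not res.mapped:
            continue
        cands = by_key.get((res.chrom, res.strand), ())
        best: Optional[tuple[int, int, Peak]] = None
        for dp in cands:
            ds = abs(res.start - dp.start)
            de = abs(res.end - dp.end)
            if ds > max_dist or de > max_dist:
                continue
            key = (ds + de, dp.start)
            if best is None or key < (best[0], best[1]):
                best = (ds + de, dp.start, dp)
        is_expr = True if expressed is None else (name in expressed)
        if best is None:
            out.append(
                ProjectionMatch(name, res.chrom, res.start, res.end, res.strand,
                                None, None, None, is_expr)
            )
        else:
            dp = best[2]
            out.append(
                ProjectionMatch(
                    name, res.chrom, res.start, res.end, res.strand,
                    dp.name, abs(res.start - dp.start), abs(res.end - dp.end), is_expr,
                )
            )
    return out


def write_match_table(matches: Sequence[ProjectionMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("source_peak\tproj_chrom\tproj_start\tproj_end\tproj_strand\t"
                 "dest_peak\td_start\td_end\texpressed\n")
        for m in matches:
            fh.write(
                f"{m.source_name}\t{m.proj_chrom}\t{m.proj_start}\t{m.proj_end}\t"
                f"{m.proj_strand}\t{m.dest_name or '.'}\t"
                f"{'.' if m.d_start is None else m.d_start}\t"
                f"{'.' if m.d_end is None else m.d_end}\t{int(m.source_expressed)}\n"
            )
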