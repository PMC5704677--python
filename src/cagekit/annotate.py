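"""Peak-to-gene association, genomic context and promoter architecture.

A peak is associated with a gene when it overlaps, on the same strand, a
1 kb window centred on the gene's 5' end. Architecture classes combine a
TATA position-weight-matrix scan (-500..+200 around the peak 5' boundary)
with CpG-island overlap.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import BedInterval, GeneModelRecord, gap_between
from .peaks import Peak

logger = logging.getLogger(__name__)

DEFAULT_ASSOC_WINDOW_HALF = 500
DEFAULT_TATA_WINDOW = (-500, 200)
DEFAULT_PROMOTER_WINDOW = (-1000, 500)
DEFAULT_TTS_WINDOW = 500

GENOMIC_CLASSES = (
    "promoter", "5UTR", "exon", "intron", "TTS", "CpG-island", "repeat", "intergenic",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Association:
    peak_name: str
    source_set: str
    gene_id: str
    transcript_id: str
    distance: int  # peak 5' boundary -> gene 5' end, in transcript orientation


@dataclass
class PeakAnnotation:
    peak_name: str
    associations: list[Association] = field(default_factory=list)
    genomic_class: str = "intergenic"
    has_tata: bool = False
    tata_offset: Optional[int] = None
    has_cpg: bool = False

    @property
    def n_sets_hit(self) -> int:
        return len({a.source_set for a in self.associations})

    @property
    def arch_class(self) -> str:
        if self.has_tata and self.has_cpg:
            return "both"
        if self.has_tata:
            return "TATA-only"
        if self.has_cpg:
            return "CpG-only"
        return "neither"


def _tss_window(gene: GeneModelRecord, half: int) -> tuple[int, int]:
    tss = gene.tss
    return tss - half, tss + half


def associate_peaks_to_genes(
    peaks: Sequence[Peak],
    gene_models: Sequence[GeneModelRecord],
    window_half: int = DEFAULT_ASSOC_WINDOW_HALF,
) -> list[Association]:
    """All (peak, gene) pairs where the peak overlaps [tss-half, tss+half)
    on the same strand; reported per source set."""
    by_key: dict[tuple[str, str], list[GeneModelRecord]] = defaultdict(list)
    for g in gene_models:
        by_key[(g.chrom, g.strand)].append(g)
    out: list[Association] = []
    for p in peaks:
        for g in by_key.get((p.chrom, p.strand), ()):
            lo, hi = _tss_window(g, window_half)
            if p.start < hi and lo < p.end:
                anchor = p.start if p.strand == "+" else p.end - 1
                dist = anchor - g.tss if g.strand == "+" else g.tss - anchor
                out.append(Association(p.name, g.source_set, g.gene_id, g.transcript_id, dist))
    return out


def build_annotations(
    peaks: Sequence[Peak], associations: Iterable[Association]
) -> dict[str, PeakAnnotation]:
    """Index associations into one PeakAnnotation per peak (all peaks present)."""
    ann = {p.name: PeakAnnotation(p.name) for p in peaks}
    for a in associations:
        if a.peak_name in ann:
            ann[a.peak_name].associations.append(a)
    return ann


def annotation_breakdown(
    annotations: dict[str, PeakAnnotation], n_sets: int
) -> list[int]:
    """Histogram of peaks by number of gene-model sets hit (bins 0..n_sets)."""
    bins = [0] * (n_sets + 1)
    for a in annotations.values():
        k = a.n_sets_hit
        if k > n_sets:
            raise ValueError(f"peak {a.peak_name} hits {k} sets but n_sets={n_sets}")
        bins[k] += 1
    return bins


def gene_coverage(
    gene_models: Sequence[GeneModelRecord], associations: Iterable[Association]
) -> dict[str, tuple[int, int]]:
    """Per source set: (genes with >=1 associated peak, total genes)."""
    assoc_genes: dict[str, set[str]] = defaultdict(set)
    for a in associations:
        assoc_genes[a.source_set].add(a.gene_id)
    totals: dict[str, set[str]] = defaultdict(set)
    for g in gene_models:
        totals[g.source_set].add(g.gene_id)
    return {
        s: (len(assoc_genes.get(s, set()) & genes), len(genes))
        for s, genes in totals.items()
    }


def classify_genomic_feature(
    peak: Peak,
    gene_models: Sequence[GeneModelRecord],
    cpg_islands: Sequence[BedInterval] = (),
    repeats: Sequence[BedInterval] = (),
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    tts_window: int = DEFAULT_TTS_WINDOW,
) -> str:
    """First matching class by fixed precedence:
    promoter > 5UTR > exon > intron > TTS > CpG-island > repeat > intergenic.

    Gene-relative windows are oriented by the gene's strand (upstream is
    negative); gene-feature checks ignore peak strand, matching common
    annotator behaviour.
    """
    p_lo, p_hi = peak.start, peak.end

    def overlaps(lo: int, hi: int) -> bool:
        return p_lo < hi and lo < p_hi

    genes = [g for g in gene_models if g.chrom == peak.chrom]
    up, down = promoter_window
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss + up, g.tss + down
        else:
            lo, hi = g.tss - down + 1, g.tss - up + 1
        if overlaps(lo, hi):
            return "promoter"
    for g in genes:
        if not g.coding:
            continue
        if g.strand == "+":
            lo, hi = g.tx_start, g.cds_start
        else:
            lo, hi = g.cds_end, g.tx_end
        if lo < hi and overlaps(lo, hi):
            return "5UTR"
    for g in genes:
        for rel, size in zip(g.exon_starts or (0,), g.exon_sizes or (g.tx_end - g.tx_start,)):
            if overlaps(g.tx_start + rel, g.tx_start + rel + size):
                return "exon"
    for g in genes:
        if overlaps(g.tx_start, g.tx_end):
            return "intron"
    for g in genes:
        tts = g.tx_end - 1 if g.strand == "+" else g.tx_start
        if overlaps(tts - tts_window, tts + tts_window + 1):
            return "TTS"
    for iv in cpg_islands:
        if iv.chrom == peak.chrom and overlaps(iv.start, iv.end):
            return "CpG-island"
    for iv in repeats:
        if iv.chrom == peak.chrom and overlaps(iv.start, iv.end):
            return "repeat"
    return "intergenic"


# ---------------------------------------------------------------------------
# TATA scan
# ---------------------------------------------------------------------------

def pwm_log_odds(pwm: np.ndarray, background: float = 0.25, pseudo: float = 1e-3) -> np.ndarray:
    """Convert a frequency PWM (rows A,C,G,T) to log2-odds scores."""
    freq = pwm + pseudo
    freq = freq / freq.sum(axis=0, keepdims=True)
    return np.log2(freq / background)


@dataclass(frozen=True)
class TataHit:
    offset: int          # motif start relative to the scan anchor, transcript orientation
    score: float
    genomic_start: int   # leftmost genomic base of the motif occurrence
    genomic_end: int


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def scan_tata_motif(
    peak: Peak,
    genome: dict[str, str],
    pwm: np.ndarray,
    window: tuple[int, int] = DEFAULT_TATA_WINDOW,
    log_odds_min: Optional[float] = None,
    anchor: Optional[int] = None,
) -> Optional[TataHit]:
    """Best above-threshold PWM hit in a strand-aware window around the peak.

    The window (negative = upstream) is anchored at the peak's 5' boundary
    unless ``anchor`` overrides it (e.g. the peak summit). Scanning is on
    the peak strand only. ``log_odds_min`` defaults to 60% of the maximal
    attainable log-odds score. Windows reaching past the chromosome are
    truncated with a warning.
    """
    lod = pwm_log_odds(pwm)
    motif_len = lod.shape[1]
    if log_odds_min is None:
        log_odds_min = 0.6 * float(lod.max(axis=0).sum())
    seq = genome[peak.chrom]
    if anchor is None:
        anchor = peak.start if peak.strand == "+" else peak.end - 1
    win_lo, win_hi = window
    if peak.strand == "+":
        g_lo, g_hi = anchor + win_lo, anchor + win_hi
    else:
        g_lo, g_hi = anchor - win_hi + 1, anchor - win_lo + 1
    if g_lo < 0 or g_hi > len(seq):
        logger.warning("TATA scan window for %s truncated at chromosome edge", peak.name)
        g_lo, g_hi = max(g_lo, 0), min(g_hi, len(seq))
    sub = seq[g_lo:g_hi]
    if peak.strand == "-":
        sub = revcomp(sub)
    best: Optional[TataHit] = None
    for j in range(0, len(sub) - motif_len + 1):
        score = 0.0
        ok = True
        for k in range(motif_len):
            idx = _BASE_INDEX.get(sub[j + k])
            if idx is None:
                ok = False
                break
            score += lod[idx, k]
        if not ok or score < log_odds_min:
            continue
        if peak.strand == "+":
            g_start = g_lo + j
            offset = g_start - anchor
        else:
            g_start = g_hi - j - motif_len
            offset = anchor - (g_start + motif_len - 1)
        if best is None or score > best.score:
            best = TataHit(offset=offset, score=score,
                           genomic_start=g_start, genomic_end=g_start + motif_len)
    return best


def detect_cpg_islands(
    genome: dict[str, str],
    min_len: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
) -> list[BedInterval]:
    """Gardiner-Garden CpG islands: merged >= min_len windows with
    GC >= min_gc and observed/expected CpG >= min_obs_exp.

    Sliding windows of ``min_len`` (step 1) that satisfy the criteria are
    merged into maximal intervals.
    """
    out: list[BedInterval] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        n = len(seq)
        if n < min_len:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = (arr == ord("C")).astype(np.int32)
        is_g = (arr == ord("G")).astype(np.int32)
        is_cg = np.zeros(n, dtype=np.int32)
        if n > 1:
            is_cg[:-1] = ((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int32)
        c_cum = np.concatenate([[0], np.cumsum(is_c)])
        g_cum = np.concatenate([[0], np.cumsum(is_g)])
        cg_cum = np.concatenate([[0], np.cumsum(is_cg)])
        starts = np.arange(0, n - min_len + 1)
        ends = starts + min_len
        n_c = c_cum[ends] - c_cum[starts]
        n_g = g_cum[ends] - g_cum[starts]
        # CpG dinucleotides fully inside the window
        n_cg = cg_cum[ends - 1] - cg_cum[starts]
        gc = (n_c + n_g) / min_len
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_exp = np.where(n_c * n_g > 0, n_cg * min_len / np.maximum(n_c * n_g, 1), 0.0)
        good = (gc >= min_gc) & (obs_exp >= min_obs_exp)
        idx = np.nonzero(good)[0]
        if idx.size == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i > prev + 1:
                out.append(BedInterval(chrom, int(run_start), int(prev + min_len), "CpG"))
                run_start = i
            prev = i
        out.append(BedInterval(chrom, int(run_start), int(prev + min_len), "CpG"))
    return out


def overlaps_any(peak: Peak, intervals: Sequence[BedInterval]) -> bool:
    return any(
        iv.chrom == peak.chrom and peak.start < iv.end and iv.start < peak.end
        for iv in intervals
    )


@dataclass
class ArchitectureSummary:
    classes: dict[str, str]            # peak name -> arch class
    widths: dict[str, list[int]]       # arch class -> width vector
    t_statistic: Optional[float]       # TATA-only vs CpG-only (Welch)
    p_value: Optional[float]


def classify_promoter_architecture(
    peaks: Sequence[Peak],
    tata_hits: dict[str, Optional[TataHit]],
    cpg_islands: Sequence[BedInterval],
) -> ArchitectureSummary:
    """Assign TATA-only / CpG-only / both / neither and compare widths.

    The width comparison is a Welch two-sample t statistic between the
    TATA-only and CpG-only width vectors (negative when TATA-only peaks
    are narrower on average).
    """
    from scipy import stats

    classes: dict[str, str] = {}
    widths: dict[str, list[int]] = {c: [] for c in ("TATA-only", "CpG-only", "both", "neither")}
    for p in peaks:
        has_tata = tata_hits.get(p.name) is not None
        has_cpg = overlaps_any(p, cpg_islands)
        if has_tata and has_cpg:
            cls = "both"
        elif has_tata:
            cls = "TATA-only"
        elif has_cpg:
            cls = "CpG-only"
        else:
            cls = "neither"
        classes[p.name] = cls
        widths[cls].append(p.width)
    t_stat = p_val = None
    if len(widths["TATA-only"]) >= 2 and len(widths["CpG-only"]) >= 2:
        t_stat, p_val = stats.ttest_ind(
            widths["TATA-only"], widths["CpG-only"], equal_var=False
        )
        t_stat, p_val = float(t_stat), float(p_val)
    return ArchitectureSummary(classes=classes, widths=widths, t_statistic=t_stat, p_value=p_val)
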