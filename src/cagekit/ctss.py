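"""Single-base TSS (CTSS) quantification from alignment records.

Each retained alignment contributes one tag to the genomic position of its
5' end: the leftmost aligned base on '+', the rightmost on '-'. Records are
filtered on mapping quality, SAM flag bits and (when available) sequence
identity before counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .io import CtssRecord, ctss_name

logger = logging.getLogger(__name__)

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10

DEFAULT_MIN_MAPQ = 20
DEFAULT_EXCLUDE_FLAGS = 768  # secondary (256) + QC fail (512)
DEFAULT_MIN_IDENTITY = 0.85


@dataclass(frozen=True)
class AlignmentRecord:
    """A minimal aligned-read record (subset of a SAM line)."""

    chrom: str
    start: int          # 0-based leftmost aligned reference base
    end: int            # half-open rightmost
    strand: str
    mapq: int
    flags: int = 0
    identity: Optional[float] = None  # 1 - edits/aligned_length; None if unknown


class CtssProfile:
    """Per-sample map (chrom, position, strand) -> tag count."""

    def __init__(self) -> None:
        self.counts: dict[tuple[str, int, str], int] = {}

    def add(self, chrom: str, pos: int, strand: str, n: int = 1) -> None:
        key = (chrom, pos, strand)
        self.counts[key] = self.counts.get(key, 0) + n

    def get(self, chrom: str, pos: int, strand: str) -> int:
        return self.counts.get((chrom, pos, strand), 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        return isinstance(other, CtssProfile) and self.counts == other.counts

    def to_records(self) -> list[CtssRecord]:
        return [
            CtssRecord.make(chrom, pos, count, strand)
            for (chrom, pos, strand), count in sorted(self.counts.items())
        ]

    @classmethod
    def from_records(cls, records: Iterable[CtssRecord]) -> "CtssProfile":
        prof = cls()
        for r in records:
            prof.add(r.chrom, r.start, r.strand, r.count)
        return prof

    def copy(self) -> "CtssProfile":
        out = CtssProfile()
        out.counts = dict(self.counts)
        return out


@dataclass
class SampleLibrary:
    """One sample's CTSS profile plus its library size."""

    sample_id: str
    profile: CtssProfile

    @property
    def total_tags(self) -> int:
        return self.profile.total()


def extract_ctss_from_alignments(
    records: Iterable[AlignmentRecord],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> CtssProfile:
    """Count 5'-ends of retained alignments into a CTSS profile.

    Retention mirrors ``samtools view -q <min_mapq> -F <exclude_flags>``
    followed by per-strand 5'-end counting: a record is kept iff it is
    mapped, mapq >= min_mapq, shares no bit with exclude_flags, and its
    identity (when known) is >= min_identity. Records without an identity
    annotation pass the identity filter; a warning is logged once.
    """
    profile = CtssProfile()
    warned_identity = False
    n_bad_strand = 0
    for rec in records:
        if rec.flags & FLAG_UNMAPPED:
            continue
        if rec.mapq < min_mapq:
            continue
        if rec.flags & exclude_flags:
            continue
        if rec.identity is None:
            if not warned_identity:
                logger.warning(
                    "alignment records carry no identity annotation; "
                    "identity filter (%.2f) not applied", min_identity
                )
                warned_identity = True
        elif rec.identity < min_identity:
            continue
        if rec.strand == "+":
            profile.add(rec.chrom, rec.start, "+")
        elif rec.strand == "-":
            profile.add(rec.chrom, rec.end - 1, "-")
        else:
            n_bad_strand += 1
            logger.warning("skipping record with unknown strand %r", rec.strand)
    if n_bad_strand:
        logger.warning("%d records skipped for unknown strand", n_bad_strand)
    return profile


def iter_sam(path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file.

    Identity is computed as 1 - NM / aligned_length when the NM tag is
    present, otherwise left absent.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name is None:
                yield AlignmentRecord(
                    chrom=aln.reference_name or "*",
                    start=aln.reference_start if aln.reference_start >= 0 else 0,
                    end=(aln.reference_end or 0),
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    flags=aln.flag,
                )
                continue
            identity: Optional[float] = None
            if aln.has_tag("NM"):
                alen = aln.query_alignment_length or (aln.reference_end - aln.reference_start)
                if alen:
                    identity = 1.0 - aln.get_tag("NM") / alen
            yield AlignmentRecord(
                chrom=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
                flags=aln.flag,
                identity=identity,
            )


def extract_ctss_from_sam(path, **kwargs) -> CtssProfile:
    """Convenience wrapper: :func:`extract_ctss_from_alignments` on a SAM/BAM file."""
    return extract_ctss_from_alignments(iter_sam(path), **kwargs)


def tags_per_million(count: float, total_tags: int) -> float:
    """Scale a tag count to tags-per-million of the library total."""
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")
    return count * 1e6 / total_tags


def pool_samples(libraries: list[SampleLibrary]) -> CtssProfile:
    """Position-wise sum of CTSS counts across samples, per strand."""
    if not libraries:
        raise ValueError("need at least one library to pool")
    pooled = CtssProfile()
    for lib in libraries:
        for (chrom, pos, strand), count in lib.profile.counts.items():
            pooled.add(chrom, pos, strand, count)
    return pooled
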