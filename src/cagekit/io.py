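"""Readers and writers for the on-disk formats the pipeline touches.

Coordinates are 0-based half-open (BED convention) throughout. CTSS and
peak names use the canonical ``chrom:start..end,strand`` string, which is
the external interoperability contract.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

STRANDS = ("+", "-")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# canonical names
# ---------------------------------------------------------------------------

def ctss_name(chrom: str, start: int, strand: str) -> str:
    """Canonical name of a 1-bp CTSS: ``chrom:start..start+1,strand``."""
    return f"{chrom}:{start}..{start + 1},{strand}"


def peak_name(chrom: str, start: int, end: int, strand: str) -> str:
    """Canonical name of a stranded interval: ``chrom:start..end,strand``."""
    return f"{chrom}:{start}..{end},{strand}"


def parse_interval_name(name: str) -> tuple[str, int, int, str]:
    """Parse a canonical ``chrom:start..end,strand`` name."""
    try:
        locus, strand = name.rsplit(",", 1)
        chrom, span = locus.rsplit(":", 1)
        s, e = span.split("..")
        start, end = int(s), int(e)
    except ValueError as exc:
        raise FormatError(f"malformed interval name {name!r}") from exc
    if strand not in STRANDS:
        raise FormatError(f"bad strand in interval name {name!r}")
    return chrom, start, end, strand


# ---------------------------------------------------------------------------
# CTSS BED6
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CtssRecord:
    """One transcription start site at single-base resolution."""

    chrom: str
    start: int
    end: int
    name: str
    count: int
    strand: str

    @classmethod
    def make(cls, chrom: str, start: int, count: int, strand: str) -> "CtssRecord":
        return cls(chrom, start, start + 1, ctss_name(chrom, start, strand), count, strand)

    def validate(self) -> None:
        if self.end != self.start + 1:
            raise FormatError(f"CTSS record must span 1 bp: {self.name}")
        if self.strand not in STRANDS:
            raise FormatError(f"bad strand {self.strand!r} in {self.name}")
        if self.count < 0:
            raise FormatError(f"negative count in {self.name}")
        if self.name != ctss_name(self.chrom, self.start, self.strand):
            raise FormatError(f"non-canonical CTSS name {self.name!r}")


def read_ctss_bed(path) -> list[CtssRecord]:
    """Read a CTSS BED6 file; records returned sorted by (chrom, start, strand).

    Column 5 must be an integer count and every record must span exactly
    one base.
    """
    records: list[CtssRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, s, e, name, score, strand = fields[:6]
            try:
                start, end, count = int(s), int(e), int(score)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate or count") from exc
            if end != start + 1:
                raise FormatError(f"{path}:{lineno}: CTSS interval must be 1 bp wide")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            records.append(CtssRecord(chrom, start, end, name, count, strand))
    records.sort(key=lambda r: (r.chrom, r.start, r.strand))
    return records


def write_ctss_bed(records: Iterable[CtssRecord], path) -> None:
    """Write CTSS records as canonical BED6 (sorted, counts >= 1)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.strand))
    with open(path, "w") as fh:
        for r in recs:
            if r.count < 1:
                raise FormatError(f"refusing to write zero-count CTSS {r.name}")
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{ctss_name(r.chrom, r.start, r.strand)}\t{r.count}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainBlock:
    """One aligned block followed by (optionally) gaps on either side.

    ``size`` aligned bases; ``dt`` gap on the source (target) side before
    the next block; ``dq`` gap on the destination (query) side.
    """

    size: int
    dt: int = 0
    dq: int = 0


@dataclass
class ChainMap:
    """A single UCSC chain: colinear alignment between two assemblies."""

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: list[ChainBlock] = field(default_factory=list)

    def validate(self) -> None:
        if self.t_strand != "+":
            raise FormatError(f"chain {self.chain_id}: source strand must be '+'")
        if self.q_strand not in STRANDS:
            raise FormatError(f"chain {self.chain_id}: unknown strand {self.q_strand!r}")
        aligned = sum(b.size for b in self.blocks)
        dt = sum(b.dt for b in self.blocks)
        dq = sum(b.dq for b in self.blocks)
        for b in self.blocks:
            if b.size < 0 or b.dt < 0 or b.dq < 0:
                raise FormatError(f"chain {self.chain_id}: negative block size or gap")
        if self.blocks and (self.blocks[-1].dt or self.blocks[-1].dq):
            raise FormatError(f"chain {self.chain_id}: terminal block must have no gaps")
        if aligned + dt != self.t_end - self.t_start:
            raise FormatError(
                f"chain {self.chain_id}: source span mismatch "
                f"({aligned}+{dt} != {self.t_end - self.t_start})"
            )
        if aligned + dq != self.q_end - self.q_start:
            raise FormatError(
                f"chain {self.chain_id}: dest span mismatch "
                f"({aligned}+{dq} != {self.q_end - self.q_start})"
            )

    def segments(self) -> list[tuple[int, int, int]]:
        """Absolute aligned segments as (t_start, q_start, size).

        q coordinates are in q-strand space (as stored in the chain line).
        """
        out = []
        t, q = self.t_start, self.q_start
        for b in self.blocks:
            out.append((t, q, b.size))
            t += b.size + b.dt
            q += b.size + b.dq
        return out

    def invert(self) -> "ChainMap":
        """Return the chain with source and destination swapped.

        The inverted chain always has a '+' source strand; a '-' original
        query strand becomes a '-' query strand on the inverted side.
        """
        segs = self.segments()
        if self.q_strand == "+":
            inv_segs = [(q, t, s) for (t, q, s) in segs]
            q_strand = "+"
            q_start, q_end = self.t_start, self.t_end
        else:
            # express the q side in plus-strand coords; order flips
            inv_segs = sorted(
                (self.q_size - (q + s), t, s) for (t, q, s) in segs
            )
            q_strand = "-"
            # original t side, now the query, read backwards: strand coords
            q_start = self.t_size - self.t_end
            q_end = self.t_size - self.t_start
            inv_segs = [
                (tp, self.t_size - (t + s), s) for (tp, t, s) in inv_segs
            ]
        blocks = []
        for i, (t0, q0, s) in enumerate(inv_segs):
            if i + 1 < len(inv_segs):
                t1, q1, _ = inv_segs[i + 1]
                blocks.append(ChainBlock(s, t1 - (t0 + s), q1 - (q0 + s)))
            else:
                blocks.append(ChainBlock(s))
        t_start = inv_segs[0][0]
        t_end = inv_segs[-1][0] + inv_segs[-1][2]
        if q_strand == "-":
            pass  # q_start/q_end computed above in strand coords
        inv = ChainMap(
            score=self.score,
            t_name=self.q_name,
            t_size=self.q_size,
            t_strand="+",
            t_start=t_start,
            t_end=t_end,
            q_name=self.t_name,
            q_size=self.t_size,
            q_strand=q_strand,
            q_start=q_start if q_strand == "-" else inv_segs[0][1],
            q_end=q_end if q_strand == "-" else inv_segs[-1][1] + inv_segs[-1][2],
            chain_id=self.chain_id,
            blocks=blocks,
        )
        inv.validate()
        return inv


def parse_chain_file(path) -> list[ChainMap]:
    """Parse a UCSC chain file (plain or gzipped).

    Every chain's block arithmetic is reconciled against its header spans;
    a mismatch raises :class:`FormatError`.
    """
    chains: list[ChainMap] = []
    current: Optional[ChainMap] = None
    closed = True
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if not closed:
                    raise FormatError(f"{path}:{lineno}: previous chain not terminated")
                toks = line.split()
                if len(toks) not in (12, 13):
                    raise FormatError(f"{path}:{lineno}: bad chain header")
                current = ChainMap(
                    score=float(toks[1]),
                    t_name=toks[2],
                    t_size=int(toks[3]),
                    t_strand=toks[4],
                    t_start=int(toks[5]),
                    t_end=int(toks[6]),
                    q_name=toks[7],
                    q_size=int(toks[8]),
                    q_strand=toks[9],
                    q_start=int(toks[10]),
                    q_end=int(toks[11]),
                    chain_id=int(toks[12]) if len(toks) == 13 else len(chains) + 1,
                )
                if current.t_strand != "+" or current.q_strand not in STRANDS:
                    raise FormatError(f"{path}:{lineno}: unknown strand symbol")
                chains.append(current)
                closed = False
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: block line before chain header")
            toks = line.split()
            if len(toks) == 3:
                current.blocks.append(ChainBlock(int(toks[0]), int(toks[1]), int(toks[2])))
            elif len(toks) == 1:
                current.blocks.append(ChainBlock(int(toks[0])))
                closed = True
            else:
                raise FormatError(f"{path}:{lineno}: bad block line")
    if not closed:
        raise FormatError(f"{path}: truncated final block")
    for c in chains:
        try:
            c.validate()
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return chains


def write_chain_file(chains: Iterable[ChainMap], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            c.validate()
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size}\t{b.dt}\t{b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


# ---------------------------------------------------------------------------
# gene models (BED12)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModelRecord:
    """A gene/transcript model with transcription and coding starts."""

    chrom: str
    tx_start: int
    tx_end: int
    strand: str
    gene_id: str
    transcript_id: str
    source_set: str
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    exon_starts: tuple[int, ...] = ()   # relative to tx_start
    exon_sizes: tuple[int, ...] = ()

    @property
    def tss(self) -> int:
        """0-based position of the 5' end: tx_start on '+', tx_end-1 on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    @property
    def orf_like(self) -> bool:
        """True when transcription and coding starts coincide (strand-aware)."""
        if not self.coding:
            return False
        if self.strand == "+":
            return self.tx_start == self.cds_start
        return self.tx_end == self.cds_end

    def span_distance(self, start: int, end: int) -> int:
        """Minimum gap between [start, end) and the transcript span; 0 if overlapping."""
        return gap_between(start, end, self.tx_start, self.tx_end)

    def name_field(self) -> str:
        return f"{self.gene_id}|{self.transcript_id}"


def gap_between(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap or touch."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def read_gene_models(path, source_set: str) -> list[GeneModelRecord]:
    """Read gene models from BED12; thickStart/thickEnd carry the coding span.

    The BED name column may be ``gene_id|transcript_id``; a bare name is
    used for both identifiers. thickStart == thickEnd marks a non-coding
    record (cds fields absent).
    """
    records: list[GeneModelRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected BED12, got {len(f)} columns")
            chrom = f[0]
            try:
                tx_start, tx_end = int(f[1]), int(f[2])
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = tuple(int(x) for x in f[10].rstrip(",").split(","))
                starts = tuple(int(x) for x in f[11].rstrip(",").split(","))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED12 field") from exc
            strand = f[5]
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount disagrees with block lists")
            if starts[0] != 0 or starts[-1] + sizes[-1] != tx_end - tx_start:
                raise FormatError(f"{path}:{lineno}: blockSizes/blockStarts inconsistent with span")
            for i in range(1, n_blocks):
                if starts[i] < starts[i - 1] + sizes[i - 1]:
                    raise FormatError(f"{path}:{lineno}: overlapping/unsorted blocks")
            name = f[3]
            gene_id, _, tx_id = name.partition("|")
            tx_id = tx_id or gene_id
            coding = thick_end > thick_start
            if coding and not (tx_start <= thick_start <= thick_end <= tx_end):
                raise FormatError(f"{path}:{lineno}: coding span outside transcript span")
            records.append(
                GeneModelRecord(
                    chrom=chrom,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    strand=strand,
                    gene_id=gene_id,
                    transcript_id=tx_id,
                    source_set=source_set,
                    cds_start=thick_start if coding else None,
                    cds_end=thick_end if coding else None,
                    exon_starts=starts,
                    exon_sizes=sizes,
                )
            )
    return records


def write_gene_models(records: Iterable[GeneModelRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            starts = r.exon_starts or (0,)
            sizes = r.exon_sizes or (r.tx_end - r.tx_start,)
            thick_s = r.cds_start if r.coding else r.tx_start
            thick_e = r.cds_end if r.coding else r.tx_start
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.tx_start),
                        str(r.tx_end),
                        r.name_field(),
                        "0",
                        r.strand,
                        str(thick_s),
                        str(thick_e),
                        "0",
                        str(len(sizes)),
                        ",".join(str(s) for s in sizes) + ",",
                        ",".join(str(s) for s in starts) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# simple BED intervals (CpG islands, repeats), FASTA, tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."


def read_bed_intervals(path) -> list[BedInterval]:
    """Read a BED3+ file of plain intervals."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "."
            out.append(BedInterval(f[0], start, end, name, strand))
    out.sort()
    return out


def write_bed_intervals(intervals: Iterable[BedInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA file fully into memory, upper-cased."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a tab-separated matrix: rows = peak names, columns = sample labels."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "peak"
    return df


def write_expression_matrix(df: pd.DataFrame, path, float_format: Optional[str] = None) -> None:
    df = df.sort_index()
    df.index.name = "peak"
    df.to_csv(path, sep="\t", float_format=float_format)


def read_orthology(path) -> dict[str, list[str]]:
    """Read a 2-column tab-separated orthology table source_gene -> dest genes."""
    mapping: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            mapping.setdefault(f[0], []).append(f[1])
    return mapping


def write_orthology(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


# TATA position-weight matrix: 4 rows (A, C, G, T) of tab-separated base
# frequencies per motif column.
PWM_ROWS = "ACGT"


def read_pwm(path):
    import numpy as np

    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            label = parts[0]
            if label in PWM_ROWS:
                parts = parts[1:]
            rows.append([float(x) for x in parts])
    if len(rows) != 4:
        raise FormatError(f"{path}: PWM must have 4 rows (A,C,G,T), got {len(rows)}")
    mat = np.asarray(rows, dtype=float)
    if mat.shape[1] < 2:
        raise FormatError(f"{path}: PWM too short")
    return mat


def write_pwm(mat, path) -> None:
    with open(path, "w") as fh:
        for base, row in zip(PWM_ROWS, mat):
            fh.write(base + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
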