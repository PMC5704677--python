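"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

Two related toy "species" genomes linked by an indel chain; gene models
with distinct transcription vs coding starts; sharp (TATA) and broad (CpG)
promoters; multi-sample replicate CTSS counts with negative-binomial
dispersion and uniform background; a source-side reference peak set with
an expression matrix; and a ground-truth record of everything planted.

All randomness flows through one ``numpy`` Generator seeded once, with
draws in a fixed order, so the same seed yields byte-identical output
files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as iof
from .annotate import revcomp
from .io import (
    BedInterval,
    ChainBlock,
    ChainMap,
    CtssRecord,
    GeneModelRecord,
    ctss_name,
    peak_name,
)

BASES = np.array(list("ACGT"))

TATA_CONSENSUS = "TATAAA"
# frequency PWM matching the planted consensus (rows A, C, G, T)
TATA_PWM = np.array(
    [
        [0.033, 0.900, 0.033, 0.900, 0.900, 0.900],  # A
        [0.033, 0.033, 0.033, 0.033, 0.033, 0.033],  # C
        [0.033, 0.033, 0.033, 0.033, 0.033, 0.033],  # G
        [0.900, 0.033, 0.900, 0.033, 0.033, 0.033],  # T
    ]
)

CPG_HALF = 150          # planted island half-width around broad TSSs
PROMOTER_MARGIN = 800   # promoter-centred zone kept free of chain edits


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic fixture generator."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 50_000
    n_promoters: int = 10
    fraction_sharp: float = 0.5
    n_samples: int = 4
    n_replicate_groups: int = 2
    mean_expression_log_mu: float = math.log(300.0)
    mean_expression_log_sigma: float = 0.4
    group_sigma: float = 1.0         # log-sd of per-group promoter mean shifts
    nb_size: float = 20.0            # negative-binomial size (larger = tighter replicates)
    background_rate: float = 1e-4    # background tags per bp per sample
    chain_edit_rate: float = 2e-4    # indels per bp between the two species
    max_indel: int = 10
    fraction_orf_like: float = 0.3   # genes with tx start == cds start
    fraction_unannotated: float = 0.2  # dest genes with displaced models (rescue candidates)
    fraction_source_unmatched_expression: float = 0.2
    read_length: int = 30
    sharp_sd: float = 2.0
    broad_sd: float = 25.0
    gc_content: float = 0.4
    junk_read_fraction: float = 0.01  # per filter class, reads that must be discarded
    emit_sam: bool = True  # skipping SAM text does not perturb the CTSS draws

    def validate(self) -> None:
        for name in ("fraction_sharp", "fraction_orf_like", "fraction_unannotated",
                     "fraction_source_unmatched_expression", "junk_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("background_rate", "chain_edit_rate", "group_sigma",
                     "mean_expression_log_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_samples < 1 or self.n_replicate_groups < 1:
            raise ConfigError("need at least one sample and one replicate group")
        if self.n_replicate_groups > self.n_samples:
            raise ConfigError("more replicate groups than samples")
        if self.nb_size <= 0:
            raise ConfigError("nb_size must be positive")
        per_chrom = math.ceil(self.n_promoters / self.n_chroms)
        spacing = self.chrom_length // (per_chrom + 1)
        if spacing < 1500:
            raise ConfigError(
                "promoters cannot be placed without overlap: "
                f"spacing {spacing} < 1500 bp (grow chrom_length or drop promoters)"
            )


@dataclass
class Promoter:
    idx: int
    chrom: str
    strand: str
    cls: str                 # 'sharp' | 'broad'
    tss_src: int
    tss_dest: int = -1
    gene_id_src: str = ""
    gene_id_dest: str = ""
    rescue_candidate: bool = False
    source_expr_matched: bool = True
    base_mean: float = 0.0
    tata_offset: Optional[int] = None  # upstream distance of planted motif (sharp only)


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream oracle tests."""

    promoters: list[dict]
    edits: dict[str, list[dict]]
    sample_groups: dict[str, str]
    retained_reads: dict[str, int]
    junk_reads: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def cpg_rich_sequence(rng: np.random.Generator, length: int) -> str:
    """CpG-dense sequence passing Gardiner-Garden criteria comfortably."""
    out: list[str] = []
    while len(out) < length:
        if rng.random() < 0.45:
            out.extend("CG")
        else:
            out.extend(BASES[rng.choice(4, size=2, p=[0.2, 0.3, 0.3, 0.2])])
    return "".join(out[:length])


def chain_from_edits(
    chrom: str, src_len: int, dest_len: int, edits: list[dict], chain_id: int = 1,
    score: Optional[float] = None,
) -> ChainMap:
    """Build the chain that exactly describes an edit list.

    Each edit is ``{"src_pos": p, "del_len": d, "ins_len": i}``: ``d``
    source bases absent from the destination and/or ``i`` destination
    bases inserted at that point. Edits must be sorted and disjoint.
    """
    blocks: list[ChainBlock] = []
    prev = 0
    for e in edits:
        size = e["src_pos"] - prev
        if size <= 0:
            raise ConfigError("edits too dense: zero-length aligned block")
        blocks.append(ChainBlock(size, e["del_len"], e["ins_len"]))
        prev = e["src_pos"] + e["del_len"]
    if src_len - prev <= 0:
        raise ConfigError("edit at chromosome end leaves no aligned block")
    blocks.append(ChainBlock(src_len - prev))
    aligned = sum(b.size for b in blocks)
    chain = ChainMap(
        score=score if score is not None else float(aligned),
        t_name=chrom, t_size=src_len, t_strand="+", t_start=0, t_end=src_len,
        q_name=chrom, q_size=dest_len, q_strand="+", q_start=0, q_end=dest_len,
        chain_id=chain_id, blocks=blocks,
    )
    chain.validate()
    return chain


def map_src_to_dest(pos: int, edits: list[dict]) -> int:
    """Map a source coordinate through an edit list (clamping inside deletions)."""
    delta = 0
    for e in edits:
        if e["src_pos"] + e["del_len"] <= pos:
            delta += e["ins_len"] - e["del_len"]
        elif e["src_pos"] <= pos:
            return e["src_pos"] + delta  # inside a deletion: clamp to its left edge
        else:
            break
    return pos + delta


def flip_chain_dest(
    chains: list[ChainMap], dest_genome: dict[str, str]
) -> tuple[list[ChainMap], dict[str, str]]:
    """Reverse-complement the destination assembly of '+'-strand chains.

    Returns equivalent chains with q_strand '-' plus the reverse-complemented
    destination sequences; useful for exercising strand-flip projection.
    """
    flipped = []
    for c in chains:
        if c.q_strand != "+":
            raise ValueError("flip_chain_dest expects '+' query strands")
        f = ChainMap(
            score=c.score, t_name=c.t_name, t_size=c.t_size, t_strand="+",
            t_start=c.t_start, t_end=c.t_end,
            q_name=c.q_name, q_size=c.q_size, q_strand="-",
            q_start=c.q_start, q_end=c.q_end, chain_id=c.chain_id,
            blocks=list(c.blocks),
        )
        f.validate()
        flipped.append(f)
    return flipped, {name: revcomp(seq) for name, seq in dest_genome.items()}


class FixtureGenerator:
    """Deterministic builder of the full fixture bundle.

    All layout planning (promoter placement, gene geometry, motif planting,
    chain edits) happens in ``__init__``; sequence and count generation are
    materialized lazily but in a fixed draw order.
    """

    def __init__(self, config: SimulationConfig) -> None:
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._plan()
        self._genomes_done = False
        self._models_done = False
        self._profiles_done = False

    # -- planning ----------------------------------------------------------

    def _plan(self) -> None:
        cfg = self.config
        rng = self.rng
        self.chrom_names = [f"chr{i+1}" for i in range(cfg.n_chroms)]
        per_chrom = math.ceil(cfg.n_promoters / cfg.n_chroms)
        spacing = cfg.chrom_length // (per_chrom + 1)
        self.promoters: list[Promoter] = []
        k = 0
        for ci, chrom in enumerate(self.chrom_names):
            for slot in range(per_chrom):
                if k >= cfg.n_promoters:
                    break
                tss = (slot + 1) * spacing + int(rng.integers(-100, 101))
                strand = "+" if rng.random() < 0.5 else "-"
                cls = "sharp" if rng.random() < cfg.fraction_sharp else "broad"
                self.promoters.append(
                    Promoter(
                        idx=k, chrom=chrom, strand=strand, cls=cls, tss_src=tss,
                        gene_id_src=f"g{k:04d}_src", gene_id_dest=f"g{k:04d}_dst",
                    )
                )
                k += 1
        n = len(self.promoters)
        n_rescue = int(round(cfg.fraction_unannotated * n))
        rescue_idx = {int(i) for i in rng.choice(n, size=n_rescue, replace=False)} if n_rescue else set()
        for p in self.promoters:
            p.rescue_candidate = p.idx in rescue_idx
        non_rescue = [p.idx for p in self.promoters if not p.rescue_candidate]
        n_unmatched = min(
            int(round(cfg.fraction_source_unmatched_expression * n)), len(non_rescue)
        )
        unmatched = {int(i) for i in rng.choice(non_rescue, size=n_unmatched, replace=False)} if n_unmatched else set()
        for p in self.promoters:
            p.source_expr_matched = p.idx not in unmatched
        for p in self.promoters:
            p.base_mean = float(rng.lognormal(cfg.mean_expression_log_mu, cfg.mean_expression_log_sigma))
            if p.cls == "sharp":
                p.tata_offset = int(rng.integers(30, 36))

        # gene geometry (source coordinates, transcript orientation)
        orf_like = rng.random(n) < cfg.fraction_orf_like
        self.gene_len = rng.integers(800, 2000, size=n)
        self.utr_len = np.where(orf_like, 0, rng.integers(80, 300, size=n))
        max_disp = min(4000, spacing - 1200)
        if max_disp >= 1500:
            self.rescue_disp = rng.integers(1500, max_disp + 1, size=n)
        else:
            if any(p.rescue_candidate for p in self.promoters):
                raise ConfigError("chromosomes too crowded to place rescue-candidate gene models")
            self.rescue_disp = np.zeros(n, dtype=int)

        # chain edits per chromosome, clear of promoter zones
        self.edits: dict[str, list[dict]] = {}
        forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chrom_names}
        for p in self.promoters:
            lo = p.tss_src - PROMOTER_MARGIN
            hi = p.tss_src + PROMOTER_MARGIN
            # keep gene bodies' far ends clear too so endpoints map exactly
            reach = int(self.gene_len[p.idx] + self.rescue_disp[p.idx]) + 50
            if p.strand == "+":
                hi = max(hi, p.tss_src + reach)
            else:
                lo = min(lo, p.tss_src - reach)
            forbidden[p.chrom].append((lo, hi))
        for chrom in self.chrom_names:
            n_edits = int(round(cfg.chain_edit_rate * cfg.chrom_length))
            chosen: list[dict] = []
            attempts = 0
            while len(chosen) < n_edits and attempts < 50 * (n_edits + 1):
                attempts += 1
                pos = int(rng.integers(200, cfg.chrom_length - 200))
                if any(lo - 50 <= pos <= hi + 50 for lo, hi in forbidden[chrom]):
                    continue
                if any(abs(pos - e["src_pos"]) < 60 for e in chosen):
                    continue
                size = int(rng.integers(1, cfg.max_indel + 1))
                if rng.random() < 0.5:
                    chosen.append({"src_pos": pos, "del_len": size, "ins_len": 0})
                else:
                    chosen.append({"src_pos": pos, "del_len": 0, "ins_len": size})
            chosen.sort(key=lambda e: e["src_pos"])
            self.edits[chrom] = chosen
        for p in self.promoters:
            p.tss_dest = map_src_to_dest(p.tss_src, self.edits[p.chrom])

    # -- genomes -----------------------------------------------------------

    def generate_genome_pair(self):
        """Source/dest genomes (with planted motifs), chains, orthology pairs."""
        if self._genomes_done:
            return self.source_genome, self.dest_genome, self.chains, self.orthology
        cfg = self.config
        rng = self.rng
        src: dict[str, str] = {}
        for chrom in self.chrom_names:
            seq = list(random_sequence(rng, cfg.chrom_length, cfg.gc_content))
            for p in self.promoters:
                if p.chrom != chrom:
                    continue
                if p.cls == "sharp":
                    u = p.tata_offset
                    if p.strand == "+":
                        s = p.tss_src - u
                        seq[s : s + len(TATA_CONSENSUS)] = TATA_CONSENSUS
                    else:
                        s = p.tss_src + u - len(TATA_CONSENSUS) + 1
                        seq[s : s + len(TATA_CONSENSUS)] = revcomp(TATA_CONSENSUS)
                else:
                    island = cpg_rich_sequence(rng, 2 * CPG_HALF)
                    s = p.tss_src - CPG_HALF
                    seq[s : s + 2 * CPG_HALF] = island
            src[chrom] = "".join(seq)
        dest: dict[str, str] = {}
        chains: list[ChainMap] = []
        for ci, chrom in enumerate(self.chrom_names):
            seq = src[chrom]
            pieces: list[str] = []
            prev = 0
            for e in self.edits[chrom]:
                pieces.append(seq[prev : e["src_pos"]])
                if e["ins_len"]:
                    pieces.append(random_sequence(rng, e["ins_len"], cfg.gc_content))
                prev = e["src_pos"] + e["del_len"]
            pieces.append(seq[prev:])
            dseq = "".join(pieces)
            dest[chrom] = dseq
            chains.append(
                chain_from_edits(chrom, len(seq), len(dseq), self.edits[chrom], chain_id=ci + 1)
            )
        self.source_genome, self.dest_genome, self.chains = src, dest, chains
        self.orthology = [(p.gene_id_src, p.gene_id_dest) for p in self.promoters]
        self._genomes_done = True
        return src, dest, chains, self.orthology

    # -- gene models, islands, PWM ----------------------------------------

    def generate_gene_models(self):
        """Per-species gene model sets, dest CpG island BED and the TATA PWM."""
        if self._models_done:
            return self.source_models, self.dest_models, self.cpg_islands, TATA_PWM
        self.generate_genome_pair()

        chrom_len = self.config.chrom_length

        def build_gene(chrom, strand, tss, gene_len, utr, gene_id, tx_id, source_set):
            if strand == "+":
                tx_s, tx_e = tss, min(tss + gene_len, chrom_len - 10)
                cds_s = tx_s + utr
                cds_e = max(cds_s + 3, tx_e - 100)
            else:
                tx_s, tx_e = max(tss + 1 - gene_len, 10), tss + 1
                cds_e = tx_e - utr
                cds_s = min(cds_e - 3, tx_s + 100)
            return GeneModelRecord(
                chrom=chrom, tx_start=tx_s, tx_end=tx_e, strand=strand,
                gene_id=gene_id, transcript_id=tx_id, source_set=source_set,
                cds_start=cds_s, cds_end=cds_e,
            )

        src_ens: list[GeneModelRecord] = []
        src_ref: list[GeneModelRecord] = []
        dst_ens: list[GeneModelRecord] = []
        dst_ref: list[GeneModelRecord] = []
        for p in self.promoters:
            glen = int(self.gene_len[p.idx])
            utr = int(self.utr_len[p.idx])
            src_ens.append(build_gene(p.chrom, p.strand, p.tss_src, glen, utr,
                                      p.gene_id_src, f"t{p.idx:04d}_src", "ensembl"))
            if p.idx % 2 == 0:
                src_ref.append(build_gene(p.chrom, p.strand, p.tss_src, glen, utr,
                                          p.gene_id_src, f"t{p.idx:04d}_src", "refseq"))
            if p.rescue_candidate:
                # displaced ORF-like model: present, but its 5' end is far
                # from the true promoter, so the dest peak stays un-annotated
                disp = int(self.rescue_disp[p.idx])
                tss_d = p.tss_dest + disp if p.strand == "+" else p.tss_dest - disp
                dst_ens.append(build_gene(p.chrom, p.strand, tss_d, glen, 0,
                                          p.gene_id_dest, f"t{p.idx:04d}_dst", "ensembl"))
            else:
                dst_ens.append(build_gene(p.chrom, p.strand, p.tss_dest, glen, utr,
                                          p.gene_id_dest, f"t{p.idx:04d}_dst", "ensembl"))
                if p.idx % 2 == 0:
                    dst_ref.append(build_gene(p.chrom, p.strand, p.tss_dest, glen, utr,
                                              p.gene_id_dest, f"t{p.idx:04d}_dst", "refseq"))
        islands = [
            BedInterval(
                p.chrom,
                map_src_to_dest(p.tss_src - CPG_HALF, self.edits[p.chrom]),
                map_src_to_dest(p.tss_src + CPG_HALF, self.edits[p.chrom]),
                f"cpg_{p.idx:04d}",
            )
            for p in self.promoters
            if p.cls == "broad"
        ]
        self.source_models = {"ensembl": src_ens, "refseq": src_ref}
        self.dest_models = {"ensembl": dst_ens, "refseq": dst_ref}
        self.cpg_islands = islands
        self._models_done = True
        return self.source_models, self.dest_models, self.cpg_islands, TATA_PWM

    # -- CTSS / SAM / source peak expression -------------------------------

    def sample_ids(self) -> list[str]:
        cfg = self.config
        ids = []
        for i in range(cfg.n_samples):
            group = i % cfg.n_replicate_groups
            rep = i // cfg.n_replicate_groups + 1
            ids.append(f"group{chr(ord('A') + group)}_rep{rep}")
        return sorted(ids)

    def simulate_ctss_profiles(self):
        """Per-sample CTSS records, SAM text, source peak set and ground truth."""
        if self._profiles_done:
            return self.ctss_by_sample, self.sam_by_sample, self.ground_truth
        self.generate_gene_models()
        cfg = self.config
        rng = self.rng
        samples = self.sample_ids()
        groups = {s: s.split("_")[0] for s in samples}
        n = len(self.promoters)
        # per-promoter per-group means (replicates share them)
        group_names = sorted(set(groups.values()))
        group_means = {
            g: np.array([p.base_mean for p in self.promoters])
            * rng.lognormal(0.0, cfg.group_sigma, size=n)
            for g in group_names
        }
        ctss_by_sample: dict[str, list[CtssRecord]] = {}
        counts_by_sample: dict[str, dict[tuple[str, int, str], int]] = {}
        for s in samples:
            means = group_means[groups[s]]
            counts: dict[tuple[str, int, str], int] = {}
            for p in self.promoters:
                mean = float(means[p.idx])
                size = cfg.nb_size
                c = int(rng.negative_binomial(size, size / (size + mean)))
                if c == 0:
                    continue
                sd = cfg.sharp_sd if p.cls == "sharp" else cfg.broad_sd
                span = int(math.ceil(3 * sd))
                offs = np.clip(np.rint(rng.normal(0.0, sd, size=c)), -span, span).astype(int)
                for off in offs:
                    key = (p.chrom, p.tss_dest + int(off), p.strand)
                    counts[key] = counts.get(key, 0) + 1
            n_noise = rng.poisson(cfg.background_rate * sum(len(v) for v in self.dest_genome.values()))
            for _ in range(int(n_noise)):
                chrom = self.chrom_names[int(rng.integers(0, cfg.n_chroms))]
                lo, hi = cfg.read_length + 5, len(self.dest_genome[chrom]) - cfg.read_length - 5
                pos = int(rng.integers(lo, hi))
                strand = "+" if rng.random() < 0.5 else "-"
                key = (chrom, pos, strand)
                counts[key] = counts.get(key, 0) + 1
            if not counts:
                raise ConfigError(f"sample {s}: zero library size (raise means or noise)")
            counts_by_sample[s] = counts
            ctss_by_sample[s] = [
                CtssRecord.make(chrom, pos, cnt, strand)
                for (chrom, pos, strand), cnt in sorted(counts.items())
            ]
        # SAM text mirrors the CTSS exactly, plus deliberately filtered junk
        sam_by_sample: dict[str, str] = {}
        retained: dict[str, int] = {}
        junk: dict[str, int] = {}
        header = ["@HD\tVN:1.6\tSO:unsorted"] + [
            f"@SQ\tSN:{c}\tLN:{len(self.dest_genome[c])}" for c in self.chrom_names
        ]
        for s in samples if cfg.emit_sam else []:
            lines = list(header)
            i = 0
            for (chrom, pos, strand), cnt in sorted(counts_by_sample[s].items()):
                for _ in range(cnt):
                    lines.append(self._sam_line(s, i, chrom, pos, strand, mapq=30, flag_extra=0, nm=0))
                    i += 1
            retained[s] = i
            n_junk_each = max(1, int(round(cfg.junk_read_fraction * i)))
            jk = 0
            for kind in ("lowq", "secondary", "lowid"):
                for _ in range(n_junk_each):
                    chrom = self.chrom_names[int(rng.integers(0, cfg.n_chroms))]
                    lo, hi = cfg.read_length + 5, len(self.dest_genome[chrom]) - cfg.read_length - 5
                    pos = int(rng.integers(lo, hi))
                    strand = "+" if rng.random() < 0.5 else "-"
                    if kind == "lowq":
                        lines.append(self._sam_line(s, i + jk, chrom, pos, strand, mapq=5, flag_extra=0, nm=0))
                    elif kind == "secondary":
                        lines.append(self._sam_line(s, i + jk, chrom, pos, strand, mapq=30, flag_extra=256, nm=0))
                    else:
                        lines.append(self._sam_line(s, i + jk, chrom, pos, strand, mapq=30, flag_extra=0, nm=6))
                    jk += 1
            junk[s] = jk
            sam_by_sample[s] = "\n".join(lines) + "\n"
        # source-side reference peak set + expression matrix
        src_peaks: list[BedInterval] = []
        expr_rows: dict[str, dict[str, float]] = {}
        unmatched_cols = ["other_1", "other_2"]
        for p in self.promoters:
            # widths chosen so projected boundaries sit within the 50 bp
            # match rule of the corresponding dest peak span (~3 SD)
            half = 3 if p.cls == "sharp" else 60
            name = peak_name(p.chrom, p.tss_src - half, p.tss_src + half + 1, p.strand)
            src_peaks.append(
                BedInterval(p.chrom, p.tss_src - half, p.tss_src + half + 1, name, p.strand)
            )
            row = {c: 0.0 for c in samples + unmatched_cols}
            level = round(float(p.base_mean) / 10.0, 3)
            if p.source_expr_matched:
                for c in samples:
                    row[c] = level
            else:
                for c in unmatched_cols:
                    row[c] = level
            expr_rows[name] = row
        import pandas as pd

        self.source_peaks = src_peaks
        self.source_expression = pd.DataFrame.from_dict(expr_rows, orient="index").sort_index()
        self.source_expression.index.name = "peak"
        self.ctss_by_sample = ctss_by_sample
        self.sam_by_sample = sam_by_sample
        self.ground_truth = GroundTruth(
            promoters=[
                {
                    "idx": p.idx, "chrom": p.chrom, "strand": p.strand, "class": p.cls,
                    "tss_src": p.tss_src, "tss_dest": p.tss_dest,
                    "gene_id_src": p.gene_id_src, "gene_id_dest": p.gene_id_dest,
                    "rescue_candidate": p.rescue_candidate,
                    "source_expr_matched": p.source_expr_matched,
                    "base_mean": round(p.base_mean, 4),
                    "tata_offset": p.tata_offset,
                }
                for p in self.promoters
            ],
            edits=self.edits,
            sample_groups=groups,
            retained_reads=retained,
            junk_reads=junk,
        )
        self._profiles_done = True
        return ctss_by_sample, sam_by_sample, self.ground_truth

    def _sam_line(self, sample, i, chrom, pos, strand, mapq, flag_extra, nm) -> str:
        L = self.config.read_length
        if strand == "+":
            left = pos
            flag = 0 | flag_extra
        else:
            left = pos - L + 1
            flag = 16 | flag_extra
        seq = self.dest_genome[chrom][left : left + L]
        if strand == "-":
            seq = revcomp(seq)
        return (
            f"{sample}_r{i:07d}\t{flag}\t{chrom}\t{left + 1}\t{mapq}\t{L}M\t*\t0\t0\t"
            f"{seq}\t*\tNM:i:{nm}"
        )


def generate_fixture_bundle(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write the complete fixture bundle; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = FixtureGenerator(config)
    src, dest, chains, orthology = gen.generate_genome_pair()
    source_models, dest_models, islands, pwm = gen.generate_gene_models()
    ctss, sam, truth = gen.simulate_ctss_profiles()

    paths: dict[str, Path] = {}

    def put(key, name):
        paths[key] = outdir / name
        return paths[key]

    iof.write_fasta(src, put("source_fasta", "source.fa"))
    iof.write_fasta(dest, put("dest_fasta", "dest.fa"))
    iof.write_chain_file(chains, put("chain", "src_to_dest.chain"))
    iof.write_orthology(orthology, put("orthology", "orthology.tsv"))
    for species, models in (("source", source_models), ("dest", dest_models)):
        for source_set, records in models.items():
            iof.write_gene_models(records, put(f"{species}_genes_{source_set}",
                                               f"genes_{species}_{source_set}.bed12"))
    iof.write_bed_intervals(islands, put("cpg", "cpg_islands_dest.bed"))
    iof.write_pwm(pwm, put("pwm", "tata.pwm"))
    for sample_id in sorted(ctss):
        iof.write_ctss_bed(ctss[sample_id], put(f"ctss_{sample_id}", f"ctss_{sample_id}.bed"))
    for sample_id in sorted(sam):
        put(f"sam_{sample_id}", f"reads_{sample_id}.sam").write_text(sam[sample_id])
    iof.write_bed_intervals(gen.source_peaks, put("source_peaks", "source_peaks.bed"))
    iof.write_expression_matrix(
        gen.source_expression, put("source_expression", "source_expression.tsv")
    )
    put("ground_truth", "ground_truth.json").write_text(truth.to_json() + "\n")
    return paths
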