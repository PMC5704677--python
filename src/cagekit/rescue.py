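"""Annotation rescue of un-annotated destination peaks.

A destination peak with no gene association in any model set is rescued
when its matched projected source peak is annotated with a gene whose
ortholog has a destination model within 10 kb of the peak; the peak is
then assigned that ortholog.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Optional, Sequence

from .annotate import PeakAnnotation
from .io import GeneModelRecord, gap_between, parse_interval_name
from .projection import ProjectionMatch

logger = logging.getLogger(__name__)

DEFAULT_MAX_GENE_DIST = 10_000


@dataclass(frozen=True)
class RescuedPeak:
    dest_peak: str
    source_peak: str
    source_gene: str
    dest_gene: str
    gene_distance: int          # min gap peak -> any model of the dest ortholog
    alt_genes: tuple[str, ...] = ()   # further ortholog routes, nearest first


def rescue_unannotated_peaks(
    dest_annotations: dict[str, PeakAnnotation],
    matches: Sequence[ProjectionMatch],
    source_annotations: dict[str, PeakAnnotation],
    orthology: dict[str, list[str]],
    dest_gene_models: Sequence[GeneModelRecord],
    max_gene_dist: int = DEFAULT_MAX_GENE_DIST,
    source_set: Optional[str] = None,
) -> list[RescuedPeak]:
    """Rescue un-annotated destination peaks via annotated projected matches.

    A dest peak P is rescued iff (a) P has zero associations in every
    model set, (b) a projected source peak S matched P, (c) S is annotated
    with gene g (optionally restricted to ``source_set``), (d) orthology
    maps g to a dest gene g', and (e) some model of g' lies within
    ``max_gene_dist`` bp of P (0 when overlapping). When several ortholog
    routes qualify, the nearest gene is assigned and the rest reported.
    Output ordering is deterministic (by dest peak name).
    """
    models_by_gene: dict[str, list[GeneModelRecord]] = defaultdict(list)
    for g in dest_gene_models:
        models_by_gene[g.gene_id].append(g)

    matches_by_dest: dict[str, list[ProjectionMatch]] = defaultdict(list)
    for m in matches:
        if m.matched:
            matches_by_dest[m.dest_name].append(m)

    rescued: list[RescuedPeak] = []
    for dest_name in sorted(matches_by_dest):
        ann = dest_annotations.get(dest_name)
        if ann is None or ann.n_sets_hit > 0:
            continue
        chrom, start, end, _strand = parse_interval_name(dest_name)
        routes: list[tuple[int, str, str, str]] = []  # (dist, dest_gene, src_gene, src_peak)
        for m in sorted(matches_by_dest[dest_name], key=lambda m: m.source_name):
            s_ann = source_annotations.get(m.source_name)
            if s_ann is None:
                continue
            src_genes = sorted({
                a.gene_id for a in s_ann.associations
                if source_set is None or a.source_set == source_set
            })
            for g in src_genes:
                dest_genes = orthology.get(g)
                if not dest_genes:
                    continue
                for g2 in dest_genes:
                    models = models_by_gene.get(g2)
                    if not models:
                        logger.warning(
                            "orthology maps %s -> %s but no dest model exists; skipped", g, g2
                        )
                        continue
                    dist = min(
                        gap_between(start, end, mdl.tx_start, mdl.tx_end)
                        for mdl in models
                        if mdl.chrom == chrom
                    ) if any(mdl.chrom == chrom for mdl in models) else None
                    if dist is None or dist > max_gene_dist:
                        continue
                    routes.append((dist, g2, g, m.source_name))
        if not routes:
            continue
        routes.sort()
        dist, g2, g, src_peak = routes[0]
        alt = tuple(dict.fromkeys(r[1] for r in routes[1:] if r[1] != g2))
        rescued.append(
            RescuedPeak(
                dest_peak=dest_name,
                source_peak=src_peak,
                source_gene=g,
                dest_gene=g2,
                gene_distance=dist,
                alt_genes=alt,
            )
        )
    return rescued


def rcp_summary_stats(
    rescued: Sequence[RescuedPeak],
    dest_gene_models: Sequence[GeneModelRecord],
    tf_list: Optional[Iterable[str]] = None,
) -> dict:
    """Summary statistics of the rescued-peak set.

    Reports median peak width, median rescued-gene length, the fraction of
    rescued genes whose transcription and coding starts coincide
    (ORF-like), rescued-peak counts per gene, and overlap with an optional
    TF id list. Empty input yields an empty summary.
    """
    if not rescued:
        return {
            "n_rescued": 0,
            "median_width": None,
            "median_gene_length": None,
            "orf_like_fraction": None,
            "rcp_per_gene": {},
            "tf_overlap": [],
        }
    models_by_gene: dict[str, list[GeneModelRecord]] = defaultdict(list)
    for g in dest_gene_models:
        models_by_gene[g.gene_id].append(g)

    widths = []
    for r in rescued:
        _, start, end, _ = parse_interval_name(r.dest_peak)
        widths.append(end - start)
    genes = sorted({r.dest_gene for r in rescued})
    gene_lengths = [
        max(m.tx_end - m.tx_start for m in models_by_gene[g]) for g in genes if g in models_by_gene
    ]
    orf_like = [
        any(m.orf_like for m in models_by_gene[g]) for g in genes if g in models_by_gene
    ]
    per_gene: dict[str, int] = defaultdict(int)
    for r in rescued:
        per_gene[r.dest_gene] += 1
    tf_overlap = sorted(set(genes) & set(tf_list)) if tf_list is not None else []
    return {
        "n_rescued": len(rescued),
        "median_width": median(widths),
        "median_gene_length": median(gene_lengths) if gene_lengths else None,
        "orf_like_fraction": (sum(orf_like) / len(orf_like)) if orf_like else None,
        "rcp_per_gene": dict(sorted(per_gene.items())),
        "tf_overlap": tf_overlap,
    }


def write_rescue_table(rescued: Sequence[RescuedPeak], path) -> None:
    with open(path, "w") as fh:
        fh.write("dest_peak\tsource_peak\tsource_gene\tdest_gene\tgene_distance\talt_genes\n")
        for r in rescued:
            fh.write(
                f"{r.dest_peak}\t{r.source_peak}\t{r.source_gene}\t{r.dest_gene}\t"
                f"{r.gene_distance}\t{','.join(r.alt_genes) or '.'}\n"
            )


def write_rescue_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
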