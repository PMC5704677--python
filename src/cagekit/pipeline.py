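"""End-to-end orchestration: ctss -> peaks -> annotate -> project -> match
-> rescue -> qc, driven by a serializable config, with a machine-readable
run report. Reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__, annotate, ctss as ctss_mod, io as iof, peaks as peaks_mod
from . import projection as proj_mod, qc as qc_mod, rescue as rescue_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run (defaults are the
    analysis defaults: -q 20 -F 768, identity 0.85, permissive 3,
    robust 10 & 1 TPM, 1 kb association window, -500..+200 TATA scan,
    50 bp match distance, 10 kb rescue distance)."""

    # inputs
    sam_files: dict[str, str] = field(default_factory=dict)   # sample_id -> path
    ctss_files: dict[str, str] = field(default_factory=dict)  # alternative to sam_files
    dest_gene_models: dict[str, str] = field(default_factory=dict)  # set name -> BED12
    source_gene_models: dict[str, str] = field(default_factory=dict)
    dest_genome: Optional[str] = None
    cpg_islands: Optional[str] = None
    repeats: Optional[str] = None
    tata_pwm: Optional[str] = None
    chain: Optional[str] = None
    orthology: Optional[str] = None
    source_peaks: Optional[str] = None
    source_expression: Optional[str] = None
    matching_samples: list[str] = field(default_factory=list)
    # thresholds
    min_mapq: int = 20
    exclude_flags: int = 768
    min_identity: float = 0.85
    max_gap: int = 20
    smooth_sd: float = 5.0
    valley_fraction: float = 0.1
    min_subpeak_gap: int = 10
    permissive_min: int = 3
    robust_min: int = 10
    robust_tpm: float = 1.0
    assoc_window: int = 500
    tata_window: tuple[int, int] = (-500, 200)
    promoter_window: tuple[int, int] = (-1000, 500)
    min_match: float = 0.95
    match_dist: int = 50
    min_source_tpm: float = 0.0
    rescue_dist: int = 10000
    rescue_source_set: Optional[str] = "ensembl"
    mds_top_n: int = 500
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tata_window"] = list(self.tata_window)
        d["promoter_window"] = list(self.promoter_window)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("tata_window", "promoter_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _resolve(base: Path, p: Optional[str]) -> Optional[Path]:
    if p is None:
        return None
    path = Path(p)
    return path if path.is_absolute() else base / path


def run_pipeline(config: PipelineConfig, outdir, config_dir: Optional[Path] = None) -> dict:
    """Run every stage in order and write the result bundle to ``outdir``.

    Relative input paths are resolved against ``config_dir`` (defaults to
    the current directory). Returns the run report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(config_dir) if config_dir is not None else Path(".")
    report: dict = {"tool": "cagekit", "version": __version__, "parameters": asdict(config),
                    "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    # ---- ctss -------------------------------------------------------------
    try:
        rec = stage("ctss")
        libraries: list[ctss_mod.SampleLibrary] = []
        if config.sam_files:
            for sample_id in sorted(config.sam_files):
                prof = ctss_mod.extract_ctss_from_sam(
                    _resolve(base, config.sam_files[sample_id]),
                    min_mapq=config.min_mapq,
                    exclude_flags=config.exclude_flags,
                    min_identity=config.min_identity,
                )
                libraries.append(ctss_mod.SampleLibrary(sample_id, prof))
        elif config.ctss_files:
            for sample_id in sorted(config.ctss_files):
                records = iof.read_ctss_bed(_resolve(base, config.ctss_files[sample_id]))
                libraries.append(
                    ctss_mod.SampleLibrary(sample_id, ctss_mod.CtssProfile.from_records(records))
                )
        else:
            raise ValueError("config provides neither sam_files nor ctss_files")
        for lib in libraries:
            iof.write_ctss_bed(lib.profile.to_records(), outdir / f"ctss_{lib.sample_id}.bed")
        rec["libraries"] = {lib.sample_id: lib.total_tags for lib in libraries}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ctss", exc) from exc

    # ---- peaks ------------------------------------------------------------
    try:
        rec = stage("peaks")
        all_peaks = peaks_mod.identify_peaks(
            libraries,
            max_gap=config.max_gap,
            smooth_sd=config.smooth_sd,
            valley_fraction=config.valley_fraction,
            min_subpeak_gap=config.min_subpeak_gap,
            permissive_min=config.permissive_min,
            robust_min=config.robust_min,
            robust_tpm=config.robust_tpm,
        )
        robust = [p for p in all_peaks if p.is_robust]
        counts_df, tpm_df = peaks_mod.quantify_peak_expression(all_peaks, libraries)
        peaks_mod.write_peaks_bed(all_peaks, outdir / "peaks_permissive.bed")
        peaks_mod.write_peaks_bed(robust, outdir / "peaks_robust.bed")
        iof.write_expression_matrix(counts_df, outdir / "peak_counts.tsv")
        iof.write_expression_matrix(tpm_df, outdir / "peak_tpm.tsv", float_format="%.6g")
        frac = peaks_mod.fraction_tags_in_peaks(libraries, all_peaks)
        rec["n_permissive"] = len(all_peaks)
        rec["n_robust"] = len(robust)
        rec["fraction_tags_in_peaks"] = {k: round(v, 6) for k, v in sorted(frac.items())}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("peaks", exc) from exc

    # ---- annotate ---------------------------------------------------------
    try:
        rec = stage("annotate")
        dest_models: list[iof.GeneModelRecord] = []
        for set_name in sorted(config.dest_gene_models):
            dest_models.extend(
                iof.read_gene_models(_resolve(base, config.dest_gene_models[set_name]), set_name)
            )
        n_sets = len(config.dest_gene_models)
        associations = annotate.associate_peaks_to_genes(
            robust, dest_models, window_half=config.assoc_window
        )
        annotations = annotate.build_annotations(robust, associations)
        bins = annotate.annotation_breakdown(annotations, n_sets) if n_sets else []
        cpg = iof.read_bed_intervals(_resolve(base, config.cpg_islands)) if config.cpg_islands else []
        repeats = iof.read_bed_intervals(_resolve(base, config.repeats)) if config.repeats else []
        arch = None
        if config.dest_genome and config.tata_pwm:
            genome = iof.read_fasta(_resolve(base, config.dest_genome))
            pwm = iof.read_pwm(_resolve(base, config.tata_pwm))
            tata_hits = {
                p.name: annotate.scan_tata_motif(
                    p, genome, pwm, window=config.tata_window, anchor=p.summit
                )
                for p in robust
            }
            for p in robust:
                hit = tata_hits[p.name]
                annotations[p.name].has_tata = hit is not None
                annotations[p.name].tata_offset = hit.offset if hit else None
                annotations[p.name].has_cpg = annotate.overlaps_any(p, cpg)
            arch = annotate.classify_promoter_architecture(robust, tata_hits, cpg)
        with open(outdir / "associations.tsv", "w") as fh:
            fh.write("peak\tsource_set\tgene_id\ttranscript_id\tdistance\n")
            for a in sorted(associations, key=lambda a: (a.peak_name, a.source_set, a.gene_id)):
                fh.write(f"{a.peak_name}\t{a.source_set}\t{a.gene_id}\t{a.transcript_id}\t{a.distance}\n")
        with open(outdir / "peak_annotation.tsv", "w") as fh:
            fh.write("peak\tn_sets_hit\tgenomic_class\thas_tata\ttata_offset\thas_cpg\tarch_class\n")
            for p in robust:
                a = annotations[p.name]
                gcls = annotate.classify_genomic_feature(
                    p, dest_models, cpg, repeats, promoter_window=config.promoter_window
                )
                a.genomic_class = gcls
                fh.write(
                    f"{p.name}\t{a.n_sets_hit}\t{gcls}\t{int(a.has_tata)}\t"
                    f"{'.' if a.tata_offset is None else a.tata_offset}\t{int(a.has_cpg)}\t{a.arch_class}\n"
                )
        rec["breakdown_by_n_sets"] = bins
        rec["gene_coverage"] = {
            s: {"covered": c, "total": t}
            for s, (c, t) in sorted(annotate.gene_coverage(dest_models, associations).items())
        }
        if arch is not None:
            rec["architecture"] = {
                "n_by_class": {k: len(v) for k, v in sorted(arch.widths.items())},
                "t_statistic": arch.t_statistic,
                "p_value": arch.p_value,
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotate", exc) from exc

    # ---- project + match --------------------------------------------------
    matches = []
    try:
        rec = stage("project")
        if config.chain and config.source_peaks:
            chains = iof.parse_chain_file(_resolve(base, config.chain))
            src_peaks = iof.read_bed_intervals(_resolve(base, config.source_peaks))
            names = [p.name for p in src_peaks]
            expressed = None
            if config.source_expression and config.matching_samples:
                expr = iof.read_expression_matrix(_resolve(base, config.source_expression))
                expressed = proj_mod.filter_expressed(
                    expr, config.matching_samples, min_tpm=config.min_source_tpm
                )
                names = [n for n in names if n in expressed]
            projected = proj_mod.project_peaks(names, chains, min_match=config.min_match)
            matches = proj_mod.match_projected_peaks(
                projected, robust, max_dist=config.match_dist, expressed=expressed
            )
            proj_mod.write_match_table(matches, outdir / "projection_matches.tsv")
            rec["n_source_peaks"] = len(src_peaks)
            rec["n_expressed"] = len(names)
            rec["n_projected"] = sum(1 for r in projected.values() if r.mapped)
            rec["n_matched"] = sum(1 for m in matches if m.matched)
        else:
            rec["skipped"] = True
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("project", exc) from exc

    # ---- rescue -----------------------------------------------------------
    try:
        rec = stage("rescue")
        if matches and config.orthology and config.source_gene_models:
            src_models: list[iof.GeneModelRecord] = []
            for set_name in sorted(config.source_gene_models):
                src_models.extend(
                    iof.read_gene_models(_resolve(base, config.source_gene_models[set_name]), set_name)
                )
            src_peaks = iof.read_bed_intervals(_resolve(base, config.source_peaks))
            src_peak_objs = [
                peaks_mod.Peak(p.chrom, p.start, p.end, p.strand, tier="robust")
                for p in src_peaks
            ]
            src_assoc = annotate.associate_peaks_to_genes(
                src_peak_objs, src_models, window_half=config.assoc_window
            )
            src_annotations = annotate.build_annotations(src_peak_objs, src_assoc)
            orthology = iof.read_orthology(_resolve(base, config.orthology))
            rescued = rescue_mod.rescue_unannotated_peaks(
                annotations, matches, src_annotations, orthology,
                dest_models, max_gene_dist=config.rescue_dist,
                source_set=config.rescue_source_set,
            )
            summary = rescue_mod.rcp_summary_stats(rescued, dest_models)
            rescue_mod.write_rescue_table(rescued, outdir / "rescued_peaks.tsv")
            rescue_mod.write_rescue_summary(summary, outdir / "rescue_summary.json")
            rec["n_rescued"] = len(rescued)
            rec["summary"] = summary
        else:
            rec["skipped"] = True
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("rescue", exc) from exc

    # ---- qc ---------------------------------------------------------------
    try:
        rec = stage("qc")
        if counts_df.shape[1] >= 2 and len(counts_df) >= 2:
            norm = qc_mod.NormalizedMatrix.from_counts(counts_df)
            rho = qc_mod.spearman_matrix(counts_df)
            rho.to_csv(outdir / "spearman.tsv", sep="\t", float_format="%.6g")
            norm.factors.to_frame().to_csv(outdir / "tmm_factors.tsv", sep="\t", float_format="%.9g")
            rec["tmm_factors"] = {k: round(float(v), 9) for k, v in norm.factors.items()}
            if counts_df.shape[1] >= 3:
                coords = qc_mod.mds_coordinates(
                    norm.normalized, top_n=config.mds_top_n, dims=2
                )
                coords.to_csv(outdir / "mds.tsv", sep="\t", float_format="%.6g")
        else:
            rec["skipped"] = True
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", exc) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
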