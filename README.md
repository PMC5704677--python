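# cagekit

Analysis toolkit for CAGE (Cap Analysis of Gene Expression) transcription
initiation data: single-base TSS quantification, promoter peak calling,
gene-model association, promoter architecture classification, cross-species
promoter projection, annotation rescue, and replicate QC. A seeded synthetic
fixture generator makes the whole pipeline testable end-to-end without any
external downloads.

## What it does

| module | role |
| --- | --- |
| `cagekit.io` | BED6 CTSS, BED12 gene models, UCSC chain, FASTA, PWM, expression/orthology tables |
| `cagekit.ctss` | alignment filtering (`mapq >= 20`, flag mask `768`, identity >= 0.85) and per-strand 5'-end counting into CTSS profiles; TPM |
| `cagekit.peaks` | clustering of pooled CTSS signal (gap <= 20 bp), smoothed-valley decomposition, permissive (>= 3 tags at one position) / robust (>= 10 tags and >= 1 TPM) tiers, per-sample peak expression |
| `cagekit.annotate` | peak-gene association (1 kb window centred on the gene 5' end, same strand), multi-set annotation breakdown, genomic-feature class, TATA PWM scan (-500..+200), Gardiner-Garden CpG islands, TATA/CpG architecture classes |
| `cagekit.projection` | liftOver-style interval projection through chain files (min 95% of bases on one chain), expression filtering, 50 bp two-boundary peak matching |
| `cagekit.rescue` | annotation rescue: un-annotated destination peaks gain a gene when their matched projected source peak is annotated and the ortholog lies within 10 kb |
| `cagekit.qc` | TMM scaling factors (edgeR-compatible), Spearman correlation matrices, classical MDS on leading-logFC distances |
| `cagekit.simulate` | deterministic two-species fixture bundles (genomes, chain, gene models, CTSS/SAM, source peak set, ground truth) |
| `cagekit.pipeline` / `cagekit.cli` | YAML-configured end-to-end orchestration with a machine-readable run report |

## CLI

```bash
# generate a synthetic fixture bundle + ready-to-run config.yaml
cage-pipeline make-fixtures --seed 7 --out fixtures/

# run the full pipeline: ctss -> peaks -> annotate -> project -> match -> rescue -> qc
cage-pipeline run --config fixtures/config.yaml --out results/

# stand-alone CTSS extraction from SAM/BAM
cage-pipeline ctss-extract aligned.sam ctss.bed --min-mapq 20 --exclude-flags 768
```

Pipeline outputs include permissive/robust peak BEDs, raw-count and TPM
expression tables, association and per-peak annotation tables, the
projection match table, the rescued-peak table plus summary JSON, Spearman
/ TMM / MDS QC tables, and `report.json` with stage-by-stage counts and
all parameters. Reruns with the same seed and config are byte-identical.

## Conventions

All coordinates are 0-based half-open (BED). CTSS and peak names follow
the `chrom:start..end,strand` canonical form. Strands are never merged at
any stage. Peak decomposition uses a documented smoothed-valley splitting
of the pooled signal (the original decomposition-based peak identification
is approximated, not reproduced).
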