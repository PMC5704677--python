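import numpy as np
import pytest

from cagekit.annotate import (
    associate_peaks_to_genes,
    annotation_breakdown,
    build_annotations,
    classify_genomic_feature,
    classify_promoter_architecture,
    detect_cpg_islands,
    gene_coverage,
    revcomp,
    scan_tata_motif,
)
from cagekit.io import BedInterval, GeneModelRecord
from cagekit.peaks import Peak
from cagekit.simulate import TATA_CONSENSUS, TATA_PWM, random_sequence


def gene(chrom="chr1", tx=(1000, 5000), strand="+", gene_id="G", source_set="ensembl",
         cds=None, exons=None):
    cds_s, cds_e = cds if cds else (None, None)
    kwargs = {}
    if exons:
        kwargs["exon_starts"] = tuple(s for s, _ in exons)
        kwargs["exon_sizes"] = tuple(e for _, e in exons)
    return GeneModelRecord(
        chrom=chrom, tx_start=tx[0], tx_end=tx[1], strand=strand, gene_id=gene_id,
        transcript_id=gene_id + "_t", source_set=source_set,
        cds_start=cds_s, cds_end=cds_e, **kwargs,
    )


def peak(chrom="chr1", start=990, end=1010, strand="+", tier="robust"):
    return Peak(chrom=chrom, start=start, end=end, strand=strand, tier=tier)


class TestAssociation:
    def test_window_edge_left(self):
        # '+' gene tss=1000: window [500, 1500); peak [490,510) overlaps
        assoc = associate_peaks_to_genes([peak(start=490, end=510)], [gene()])
        assert len(assoc) == 1

    def test_window_edge_right_half_open(self):
        assert associate_peaks_to_genes([peak(start=1500, end=1520)], [gene()]) == []
        assert associate_peaks_to_genes([peak(start=1499, end=1520)], [gene()]) != []

    def test_strand_mismatch(self):
        assert associate_peaks_to_genes([peak(strand="-")], [gene(strand="+")]) == []

    def test_minus_gene_window(self):
        g = gene(strand="-", tx=(1000, 5000))  # tss = 4999
        assert associate_peaks_to_genes([peak(start=4499, end=4500, strand="-")], [g]) != []
        assert associate_peaks_to_genes([peak(start=4498, end=4499, strand="-")], [g]) == []

    def test_brute_force_oracle_random(self):
        rng = np.random.default_rng(5)
        genes = [
            gene(chrom="chr1", tx=(int(t), int(t) + 500),
                 strand="+" if rng.random() < 0.5 else "-",
                 gene_id=f"g{i}")
            for i, t in enumerate(rng.integers(600, 20_000, size=60))
        ]
        peaks = [
            peak(chrom="chr1", start=int(s), end=int(s) + int(w),
                 strand="+" if rng.random() < 0.5 else "-")
            for s, w in zip(rng.integers(0, 21_000, size=60), rng.integers(1, 200, size=60))
        ]
        got = {(a.peak_name, a.gene_id) for a in associate_peaks_to_genes(peaks, genes)}
        expected = set()
        for p in peaks:
            for g in genes:
                if p.strand != g.strand:
                    continue
                lo, hi = g.tss - 500, g.tss + 500
                if p.start < hi and lo < p.end:
                    expected.add((p.name, g.gene_id))
        assert got == expected


class TestBreakdown:
    def test_bins(self):
        genes = [gene(gene_id="A", source_set="ensembl"), gene(gene_id="A", source_set="refseq")]
        peaks = [peak(), peak(chrom="chr9")]
        assoc = associate_peaks_to_genes(peaks, genes)
        ann = build_annotations(peaks, assoc)
        bins = annotation_breakdown(ann, n_sets=6)
        assert bins[2] == 1 and bins[0] == 1
        assert sum(bins) == len(peaks)

    def test_gene_coverage_same_pair_set(self):
        genes = [gene(gene_id="A"), gene(gene_id="B", tx=(8000, 9000))]
        peaks = [peak()]
        assoc = associate_peaks_to_genes(peaks, genes)
        cov = gene_coverage(genes, assoc)
        assert cov["ensembl"] == (1, 2)


class TestGenomicClass:
    CPG = [BedInterval("chr1", 990, 1200, "cpg")]

    def test_promoter_head_of_precedence(self):
        g = gene(cds=(1200, 4800))
        assert classify_genomic_feature(peak(), [g], self.CPG) == "promoter"

    def test_cpg_only(self):
        assert classify_genomic_feature(peak(), [], self.CPG) == "CpG-island"

    def test_intergenic(self):
        assert classify_genomic_feature(peak(chrom="chrX"), [], self.CPG) == "intergenic"

    def test_five_utr(self):
        g = gene(cds=(2500, 4800))
        p = peak(start=2000, end=2010)
        assert classify_genomic_feature(p, [g], []) == "5UTR"

    def test_exon_intron(self):
        g = gene(cds=(1000, 5000), exons=[(0, 100), (3000, 1000)])
        # exon blocks are relative to tx_start=1000: genomic [1000,1100) and [4000,5000)
        assert classify_genomic_feature(peak(start=4500, end=4510), [g], []) == "exon"
        assert classify_genomic_feature(peak(start=2000, end=2010), [g], []) == "intron"

    def test_tts(self):
        g = gene()
        assert classify_genomic_feature(peak(start=5100, end=5110), [g], []) == "TTS"


class TestTataScan:
    def _genome_with_motif(self, strand, upstream=30, length=2000, tss=1000, seed=0):
        rng = np.random.default_rng(seed)
        seq = list(random_sequence(rng, length, 0.5))
        if strand == "+":
            s = tss - upstream
            seq[s : s + len(TATA_CONSENSUS)] = TATA_CONSENSUS
        else:
            s = tss + upstream - len(TATA_CONSENSUS) + 1
            seq[s : s + len(TATA_CONSENSUS)] = revcomp(TATA_CONSENSUS)
        return {"chr1": "".join(seq)}

    def test_planted_plus(self):
        genome = self._genome_with_motif("+", upstream=30)
        p = peak(start=1000, end=1010, strand="+")
        hit = scan_tata_motif(p, genome, TATA_PWM)
        assert hit is not None and hit.offset == -30

    def test_planted_minus_symmetric(self):
        genome = self._genome_with_motif("-", upstream=30)
        p = peak(start=991, end=1001, strand="-")  # 5' boundary at 1000
        hit = scan_tata_motif(p, genome, TATA_PWM)
        assert hit is not None and hit.offset == -30

    def test_gc_rich_no_hit(self):
        genome = {"chr1": "GC" * 1000}
        p = peak(start=1000, end=1010)
        assert scan_tata_motif(p, genome, TATA_PWM) is None

    def test_exhaustive_oracle(self):
        # threshold at 60% of max requires a perfect TATAAA match for this PWM
        genome = self._genome_with_motif("+", upstream=42, seed=3)
        seq = genome["chr1"]
        p = peak(start=1000, end=1010, strand="+")
        hit = scan_tata_motif(p, genome, TATA_PWM)
        matches = [
            i for i in range(500, 1200 - 6)
            if seq[i : i + 6] == TATA_CONSENSUS
        ]
        if hit is None:
            assert not matches
        else:
            assert hit.genomic_start in matches

    def test_truncated_window_warns(self, caplog):
        genome = {"chr1": "A" * 300}
        p = peak(start=100, end=110)
        with caplog.at_level("WARNING"):
            scan_tata_motif(p, genome, TATA_PWM)
        assert "truncated" in caplog.text


class TestCpgIslands:
    def test_alternating_cg(self):
        islands = detect_cpg_islands({"chr1": "CG" * 100})
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (0, 200)

    def test_at_only_none(self):
        assert detect_cpg_islands({"chr1": "AT" * 100}) == []

    def test_gc_boundary_inclusive(self):
        # GC exactly 0.5 with high obs/exp: "CGAT" repeated
        seq = "CGAT" * 50
        n_c = seq.count("C")
        n_g = seq.count("G")
        n_cg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        assert (n_c + n_g) / len(seq) == 0.5
        assert n_cg * len(seq) / (n_c * n_g) >= 0.6
        islands = detect_cpg_islands({"chr1": seq})
        assert len(islands) == 1

    def test_brute_force_window_oracle(self):
        rng = np.random.default_rng(11)
        seq = random_sequence(rng, 600, 0.55) + "CG" * 150 + random_sequence(rng, 600, 0.3)
        islands = detect_cpg_islands({"chr1": seq}, min_len=200)
        good = []
        for s in range(len(seq) - 200 + 1):
            w = seq[s : s + 200]
            n_c, n_g = w.count("C"), w.count("G")
            n_cg = sum(1 for i in range(199) if w[i : i + 2] == "CG")
            if (n_c + n_g) / 200 >= 0.5 and n_c * n_g > 0 and n_cg * 200 / (n_c * n_g) >= 0.6:
                good.append(s)
        covered = set()
        for s in good:
            covered.update(range(s, s + 200))
        island_cover = set()
        for iv in islands:
            island_cover.update(range(iv.start, iv.end))
        assert island_cover == covered


class TestArchitecture:
    def test_classes_and_t_sign(self):
        peaks = [peak(start=i * 1000, end=i * 1000 + w, strand="+")
                 for i, w in enumerate([8, 10, 12, 100, 120, 140, 50, 30])]
        hits = {p.name: None for p in peaks}
        from cagekit.annotate import TataHit

        for p in peaks[:3] + [peaks[6]]:
            hits[p.name] = TataHit(offset=-30, score=10.0, genomic_start=0, genomic_end=6)
        cpg = [BedInterval("chr1", p.start, p.end, "c") for p in peaks[3:7]]
        summary = classify_promoter_architecture(peaks, hits, cpg)
        assert summary.classes[peaks[0].name] == "TATA-only"
        assert summary.classes[peaks[3].name] == "CpG-only"
        assert summary.classes[peaks[6].name] == "both"
        assert summary.classes[peaks[7].name] == "neither"
        assert summary.t_statistic < 0
        # hand-computed Welch t on the same vectors
        a = np.array(summary.widths["TATA-only"], dtype=float)
        b = np.array(summary.widths["CpG-only"], dtype=float)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert summary.t_statistic == pytest.approx((a.mean() - b.mean()) / se)
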