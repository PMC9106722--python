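"""Gene models, regions, coverage, densities, metagene profiles, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pausekit.genome import (
    CoverageTrack,
    GeneModel,
    GenomeFormatError,
    GenomicInterval,
    coverage_from_fragments,
    gene_regions,
    genes_near_peaks,
    load_gene_models,
    metagene_profile,
    read_bedgraph,
    read_chrom_sizes,
    region_density,
    write_bed12,
    write_bedgraph,
    write_chrom_sizes,
)


class TestLoadGeneModels:
    def test_gtf_converts_one_based_inclusive(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "g1";\n')
        (g,) = load_gene_models(gtf)
        assert (g.start, g.end, g.strand) == (1000, 2000, "+")

    def test_bed_keeps_half_open_and_minus_tss(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t999\t2000\tg1\t0\t-\n")
        (g,) = load_gene_models(bed)
        assert (g.start, g.end) == (999, 2000)
        assert g.tss == 1999

    def test_dot_strand_rejected_naming_gene(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\tsrc\tgene\t100\t200\t.\t.\t.\tgene_id "gX";\n')
        with pytest.raises(GenomeFormatError, match="gX"):
            load_gene_models(gtf)

    def test_malformed_line_reports_line_number(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t0\t100\tg1\t0\t+\nchr1\t5\n")
        with pytest.raises(GenomeFormatError, match="line 2"):
            load_gene_models(bed)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t0\t100\tg1\t0\t+\nchr1\t200\t300\tg1\t0\t+\n")
        with pytest.raises(GenomeFormatError, match="duplicate"):
            load_gene_models(bed)

    def test_gtf_transcript_union_fallback(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\ts\ttranscript\t101\t500\t.\t+\t.\tgene_id "g1";\n'
            'chr1\ts\ttranscript\t301\t900\t.\t+\t.\tgene_id "g1";\n'
        )
        (g,) = load_gene_models(gtf)
        assert (g.start, g.end) == (100, 900)

    def test_bed12_round_trip(self, tmp_path):
        genes = [
            GeneModel("a", "chr1", 100, 900, "+"),
            GeneModel("b", "chr2", 50, 1400, "-"),
        ]
        write_bed12(genes, tmp_path / "g.bed")
        assert load_gene_models(tmp_path / "g.bed") == genes


class TestGeneRegions:
    def test_plus_strand_windows(self):
        rp = gene_regions(GeneModel("g", "chr1", 1000, 5000, "+"), chrom_length=10**6)
        assert (rp.promoter.start, rp.promoter.end) == (970, 1300)
        assert (rp.body.start, rp.body.end) == (1300, 5000)

    def test_minus_strand_mirror(self):
        rp = gene_regions(GeneModel("g", "chr1", 5000, 8000, "-"), chrom_length=10**6)
        assert (rp.promoter.start, rp.promoter.end) == (7700, 8030)
        assert (rp.body.start, rp.body.end) == (5000, 7700)

    def test_short_gene_flagged_ineligible(self):
        rp = gene_regions(GeneModel("g", "chr1", 1000, 1250, "+"), chrom_length=10**6)
        assert not rp.eligible
        assert rp.body.empty

    def test_promoter_clipped_at_chromosome_edges(self):
        rp = gene_regions(GeneModel("g", "chr1", 10, 2000, "+"), chrom_length=10**6)
        assert rp.promoter.start == 0
        rp2 = gene_regions(GeneModel("g", "chr1", 0, 990, "-"), chrom_length=1000)
        assert rp2.promoter.end == 1000

    @settings(derandomize=True, max_examples=100)
    @given(
        start=st.integers(min_value=500, max_value=10_000),
        length=st.integers(min_value=331, max_value=50_000),
        strand=st.sampled_from(["+", "-"]),
    )
    def test_partition_covers_extended_gene_without_overlap(self, start, length, strand):
        gene = GeneModel("g", "chr1", start, start + length, strand)
        rp = gene_regions(gene, chrom_length=10**6)
        assert rp.eligible
        # promoter and body are adjacent, disjoint, and jointly span the
        # extended gene (gene plus the 30 bp upstream of the TSS)
        if strand == "+":
            assert rp.promoter.end == rp.body.start
            assert (rp.promoter.start, rp.body.end) == (gene.tss - 30, gene.end)
        else:
            assert rp.body.end == rp.promoter.start
            assert (rp.body.start, rp.promoter.end) == (gene.start, gene.tss + 31)
        assert len(rp.promoter) == 330
        assert len(rp.promoter) + len(rp.body) == length + 30


class TestCoverage:
    def test_single_fragment_pileup(self):
        track = coverage_from_fragments([("chr1", 100, 300)], {"chr1": 1000})
        cov = track.coverage["chr1"]
        assert cov[100] == 1 and cov[299] == 1
        assert cov[99] == 0 and cov[300] == 0
        assert track.total_fragments == 1

    def test_duplicate_fragments_add(self):
        track = coverage_from_fragments(
            [("chr1", 100, 300), ("chr1", 100, 300)], {"chr1": 1000}
        )
        assert track.coverage["chr1"][150] == 2

    def test_unknown_chromosome_named_in_error(self):
        with pytest.raises(ValueError, match="chrZ"):
            coverage_from_fragments([("chrZ", 0, 10)], {"chr1": 1000})

    def test_empty_input_gives_zero_track_and_density_errors(self):
        track = coverage_from_fragments([], {"chr1": 1000})
        assert track.total_fragments == 0
        with pytest.raises(ValueError, match="library"):
            region_density(track, GenomicInterval("chr1", 0, 100))

    def test_bed_path_input_matches_in_memory(self, tmp_path):
        frags = [("chr1", 10, 60), ("chr1", 40, 90), ("chr1", 500, 700)]
        bed = tmp_path / "f.bed"
        bed.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in frags))
        t_mem = coverage_from_fragments(frags, {"chr1": 1000})
        t_file = coverage_from_fragments(bed, {"chr1": 1000})
        np.testing.assert_array_equal(t_mem.coverage["chr1"], t_file.coverage["chr1"])


class TestRegionDensity:
    def test_per_million_scaling_identity(self, uniform_track):
        region = GenomicInterval("chr1", 1000, 2000)
        assert region_density(uniform_track, region) == pytest.approx(2.0)
        half_library = CoverageTrack(
            coverage=uniform_track.coverage, total_fragments=2_000_000
        )
        assert region_density(half_library, region) == pytest.approx(1.0)

    def test_zero_coverage_zero_density(self):
        track = CoverageTrack(
            coverage={"chr1": np.zeros(1000)}, total_fragments=1_000_000
        )
        assert region_density(track, GenomicInterval("chr1", 0, 100)) == 0.0

    def test_empty_region_rejected(self, uniform_track):
        with pytest.raises(ValueError, match="empty"):
            region_density(uniform_track, GenomicInterval("chr1", 5, 5))

    def test_split_recombine_by_length_weighted_mean(self, uniform_track):
        rng = np.random.default_rng(0)
        cov = rng.poisson(5.0, 100_000).astype(float)
        track = CoverageTrack(coverage={"chr1": cov}, total_fragments=10**6)
        whole = region_density(track, GenomicInterval("chr1", 100, 9100))
        left = region_density(track, GenomicInterval("chr1", 100, 4000))
        right = region_density(track, GenomicInterval("chr1", 4000, 9100))
        recombined = (left * 3900 + right * 5100) / 9000
        assert whole == pytest.approx(recombined, rel=1e-12)

    def test_doubling_fragments_leaves_density_unchanged(self):
        frags = [("chr1", 10, 210), ("chr1", 400, 600)]
        t1 = coverage_from_fragments(frags, {"chr1": 1000})
        t2 = coverage_from_fragments(frags * 2, {"chr1": 1000})
        region = GenomicInterval("chr1", 0, 1000)
        assert region_density(t1, region) == pytest.approx(region_density(t2, region))


class TestMetageneProfile:
    def test_uniform_track_gives_flat_profile(self, uniform_track):
        genes = [GeneModel("a", "chr1", 20_000, 24_000, "+")]
        prof = metagene_profile(uniform_track, genes, flank=3000, body_bins=20, flank_bin=100)
        np.testing.assert_allclose(prof.matrix, 2.0)
        assert prof.matrix.shape == (1, 30 + 20 + 30)

    def test_promoter_coverage_peaks_at_tss(self):
        cov = np.zeros(100_000)
        gene = GeneModel("a", "chr1", 50_000, 54_000, "+")
        cov[49_970:50_300] = 5.0
        track = CoverageTrack(coverage={"chr1": cov}, total_fragments=10**6)
        prof = metagene_profile(track, [gene], flank=3000, body_bins=40, flank_bin=100)
        row = prof.matrix[0]
        tss_bin = 30  # first body bin
        assert row[tss_bin] > 0
        assert np.all(row[tss_bin + 5 :] == 0)  # late body has no signal
        assert np.all(row[:25] == 0)  # distal upstream flank empty

    def test_minus_strand_row_matches_manual_reversal(self):
        cov = np.zeros(100_000)
        gene = GeneModel("a", "chr1", 40_000, 44_000, "-")  # TSS at 43_999
        cov[43_000:44_000] = 3.0  # TSS-proximal on the minus strand
        track = CoverageTrack(coverage={"chr1": cov}, total_fragments=10**6)
        prof = metagene_profile(track, [gene], flank=1000, body_bins=40, flank_bin=100)
        row = prof.matrix[0]
        n_flank = 10
        # TSS-proximal peak appears on the left of the row
        assert row[n_flank] > 0 and row[-(n_flank + 1)] == 0
        # manual oracle: orient 5'->3' by reversing, then bin the body
        oriented = cov[39_000:45_000][::-1]
        body = oriented[1000:5000].reshape(40, 100).mean(axis=1)
        np.testing.assert_allclose(row[n_flank : n_flank + 40], body, rtol=1e-12)

    def test_invalid_bins_rejected(self, uniform_track):
        gene = [GeneModel("a", "chr1", 20_000, 24_000, "+")]
        with pytest.raises(ValueError):
            metagene_profile(uniform_track, gene, flank=0)
        with pytest.raises(ValueError):
            metagene_profile(uniform_track, gene, body_bins=0)


class TestGenesNearPeaks:
    def test_distance_arithmetic(self):
        peaks = [GenomicInterval("chr1", 50_000, 50_500)]
        genes = [GeneModel("near", "chr1", 120_000, 125_000, "+")]
        sel = genes_near_peaks(peaks, genes, window=100_000)
        assert sel == {"near": 69_500}

    @pytest.mark.parametrize(
        "gene_start,expected",
        [(200_500, False), (150_500, True)],  # distance 150 kb vs exactly 100 kb
    )
    def test_window_bound_is_closed(self, gene_start, expected):
        peaks = [GenomicInterval("chr1", 50_000, 50_500)]
        genes = [GeneModel("g", "chr1", gene_start, gene_start + 1000, "+")]
        sel = genes_near_peaks(peaks, genes, window=100_000)
        assert ("g" in sel) is expected
        if expected:
            assert sel["g"] == 100_000

    def test_empty_peak_list_selects_nothing(self):
        genes = [GeneModel("g", "chr1", 0, 1000, "+")]
        assert genes_near_peaks([], genes) == {}

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(7)
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(
                rng.integers(0, 5_000_000, 300), rng.integers(200, 2000, 300)
            )
        ]
        genes = [
            GeneModel(f"g{i}", "chr1", int(s), int(s) + int(w), "+")
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 5_000_000, 200), rng.integers(500, 20_000, 200))
            )
        ]
        window = 50_000
        got = genes_near_peaks(peaks, genes, window=window)
        for g in genes:
            dists = []
            for p in peaks:
                if p.start < g.end and g.start < p.end:
                    dists.append(0)
                elif p.start >= g.end:
                    dists.append(p.start - g.end)
                else:
                    dists.append(g.start - p.end)
            best = min(dists)
            assert (g.gene_id in got) == (best <= window)
            if best <= window:
                assert got[g.gene_id] == best


class TestTrackIO:
    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        cov = rng.poisson(1.2, 5000).astype(float)
        track = CoverageTrack(coverage={"chr1": cov}, total_fragments=4321)
        write_bedgraph(track, tmp_path / "t.bedgraph")
        back = read_bedgraph(tmp_path / "t.bedgraph", {"chr1": 5000})
        np.testing.assert_array_equal(back.coverage["chr1"], cov)
        assert back.total_fragments == 4321

    def test_chrom_sizes_round_trip(self, tmp_path):
        sizes = {"chr1": 1000, "chr2": 2500}
        write_chrom_sizes(sizes, tmp_path / "c.sizes")
        assert read_chrom_sizes(tmp_path / "c.sizes") == sizes
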