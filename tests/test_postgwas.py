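import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypwas.postgwas import (
    GeneAnnotation,
    QTLRegion,
    allelic_effect,
    bh_fdr,
    flanking_region,
    ld_decay,
    overlap_genes,
    read_gff3_genes,
    regions_from_result,
    write_regions_bed,
)
from hypwas.simulate import SimConfig, simulate_genotypes
from tests.conftest import make_genotype_matrix


class TestBhFdr:
    def test_step_up_arithmetic(self):
        flags, q = bh_fdr([0.001, 0.02, 0.9], q=0.05)
        assert flags.tolist() == [True, True, False]

    def test_all_ones_none_significant(self):
        flags, _ = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not flags.any()

    def test_all_tiny_all_significant(self):
        flags, _ = bh_fdr([1e-10] * 5, q=0.05)
        assert flags.all()

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            bh_fdr([], 0.05)

    def test_nan_propagates_unflagged(self):
        flags, q = bh_fdr([0.001, np.nan, 0.9], q=0.05)
        assert not flags[1] and np.isnan(q[1])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=50))
    def test_flag_monotonicity(self, pvals):
        flags, _ = bh_fdr(pvals, 0.05)
        p = np.asarray(pvals)
        if flags.any():
            thresh = p[flags].max()
            assert flags[p <= thresh].all()


class TestFlankingRegion:
    def test_peak_window_worked_example(self):
        r = flanking_region("Chr2", 858458, window_bp=150_000)
        assert (r.start, r.end) == (708458, 1008458)

    def test_clipped_at_chromosome_start(self):
        r = flanking_region("Chr1", 100_000, window_bp=150_000)
        assert (r.start, r.end) == (1, 250_000)

    def test_zero_window(self):
        r = flanking_region("Chr1", 500, window_bp=0)
        assert (r.start, r.end) == (500, 500)

    def test_width_when_unclipped(self):
        r = flanking_region("Chr5", 10_000_000, window_bp=150_000)
        assert r.width == 2 * 150_000 + 1

    def test_chrom_length_clip_and_unknown(self):
        r = flanking_region("Chr1", 900, window_bp=500, chrom_length=1000)
        assert r.end == 1000
        with pytest.raises(ValueError, match="beyond"):
            flanking_region("Chr1", 2000, window_bp=10, chrom_length=1000)


class TestRegionsFromResult:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["marker", "chrom", "pos", "p", "significant"]
        )

    def test_merge_overlapping_windows(self):
        tbl = self._table([
            ("m1", "Chr1", 100_000, 1e-8, True),
            ("m2", "Chr1", 150_000, 1e-6, True),
            ("m3", "Chr2", 100_000, 1e-7, True),
        ])
        regions = regions_from_result(tbl, window_bp=100_000)
        assert len(regions) == 2
        assert regions[0].peak_marker == "m1"  # stronger peak kept
        assert regions[0].start == 1 and regions[0].end == 250_000

    def test_no_significant_no_regions(self):
        tbl = self._table([("m1", "Chr1", 100, 0.9, False)])
        assert regions_from_result(tbl) == []

    def test_unknown_chromosome_length_errors(self):
        tbl = self._table([("m1", "ChrX", 100, 1e-9, True)])
        with pytest.raises(ValueError, match="length"):
            regions_from_result(tbl, chrom_lengths={"Chr1": 1000})


class TestLdDecay:
    def test_duplicate_marker_r2_one_in_zero_bin(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 50)
        d = np.column_stack([col, col])
        G = make_genotype_matrix(d, pos=[100, 100])
        decay, _ = ld_decay(G, max_dist_bp=10_000, bin_bp=1_000)
        assert decay["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_markers_flat_no_halfmax(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, (300, 80))
        G = make_genotype_matrix(d, pos=[1000 * (i + 1) for i in range(80)])
        decay, summary = ld_decay(G, max_dist_bp=80_000, bin_bp=8_000)
        assert not summary["half_max_reached"] or np.isnan(summary["half_max_distance_bp"]) is False
        # background r2 ~ 1/n everywhere: smooth curve never drops below half max
        assert decay["mean_r2"].max() < 0.05

    def test_decay_distance_monotone_in_rho(self):
        def half_dist(rho, seed):
            cfg = SimConfig(n_genotypes=300, n_markers=200, n_chromosomes=2,
                            ld_decay_rho=rho, seed=seed)
            G = simulate_genotypes(cfg)
            _, s = ld_decay(G, max_dist_bp=400_000, bin_bp=10_000)
            return s["half_max_distance_bp"] if s["half_max_reached"] else np.inf
        d_hi = half_dist(0.95, 5)
        d_lo = half_dist(0.5, 5)
        assert d_hi > d_lo

    def test_monomorphic_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        d = np.column_stack([rng.integers(0, 3, 40), np.zeros(40, int),
                             rng.integers(0, 3, 40)])
        G = make_genotype_matrix(d, pos=[100, 200, 300])
        with pytest.warns(UserWarning, match="monomorphic"):
            decay, _ = ld_decay(G, max_dist_bp=1000, bin_bp=100)

    def test_all_monomorphic_errors(self):
        G = make_genotype_matrix(np.zeros((10, 3), int), pos=[1, 2, 3])
        with pytest.raises(ValueError):
            ld_decay(G)


class TestAllelicEffect:
    def test_direct_means(self):
        G = make_genotype_matrix(np.array([[0], [0], [2], [2]]))
        out = allelic_effect(np.array([1.0, 1, 3, 3]), G, "Chr1_1")
        assert out["mean_ref"] == 1.0
        assert out["mean_alt"] == 3.0
        assert out["difference"] == 2.0

    def test_constant_trait_zero_difference(self):
        G = make_genotype_matrix(np.array([[0], [1], [2], [2]]))
        out = allelic_effect(np.full(4, 7.0), G, "Chr1_1")
        assert out["difference"] == 0.0

    def test_missing_class_warns(self):
        G = make_genotype_matrix(np.array([[0], [0], [1], [1]]))
        with pytest.warns(UserWarning, match="dosage-2"):
            out = allelic_effect(np.arange(4.0), G, "Chr1_1")
        assert np.isnan(out["mean_alt"]) and np.isnan(out["difference"])

    def test_unknown_marker(self):
        G = make_genotype_matrix(np.array([[0], [2]]))
        with pytest.raises(ValueError, match="not found"):
            allelic_effect(np.arange(2.0), G, "nope")


class TestOverlapGenes:
    def _region(self):
        return QTLRegion("Chr2", 708458, 1008458, "Chr2_858458", 858458)

    def test_interval_arithmetic(self):
        genes = [GeneAnnotation("g1", "Chr2", 720_000, 730_000)]
        out = overlap_genes([self._region()], genes)
        assert len(out) == 1
        assert out["overlap_bp"].iloc[0] == 10_001

    def test_adjacent_gene_not_reported(self):
        genes = [GeneAnnotation("g1", "Chr2", 700_000, 708_457)]
        assert overlap_genes([self._region()], genes).empty

    def test_straddling_gene_reported(self):
        genes = [GeneAnnotation("g1", "Chr2", 1_008_000, 1_020_000)]
        assert len(overlap_genes([self._region()], genes)) == 1

    def test_chromosome_mismatch_errors(self):
        genes = [GeneAnnotation("g1", "2", 1, 10)]
        with pytest.raises(ValueError, match="rename"):
            overlap_genes([self._region()], genes)

    def test_symmetric_predicate(self):
        a = QTLRegion("Chr1", 100, 200, "m", 150)
        g = GeneAnnotation("g1", "Chr1", 180, 300)
        swapped_region = QTLRegion("Chr1", 180, 300, "m2", 200)
        swapped_gene = GeneAnnotation("g2", "Chr1", 100, 200)
        assert overlap_genes([a], [g])["overlap_bp"].iloc[0] == \
            overlap_genes([swapped_region], [swapped_gene])["overlap_bp"].iloc[0]


class TestGff3:
    def test_read_genes(self, tmp_path):
        gff = tmp_path / "x.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "Chr2\ttest\tgene\t720000\t730000\t.\t+\t.\tID=GeneA;Name=A\n"
            "Chr2\ttest\tmRNA\t720000\t730000\t.\t+\t.\tID=mA;Parent=GeneA\n"
            "Chr3\ttest\tgene\t100\t500\t.\t-\t.\tID=GeneB\n"
        )
        genes = read_gff3_genes(gff)
        assert [g.gene_id for g in genes] == ["GeneA", "GeneB"]
        assert genes[0].start == 720000 and genes[1].strand == "-"


def test_write_regions_bed_is_zero_based_half_open(tmp_path):
    r = QTLRegion("Chr1", 100, 200, "m", 150)
    path = tmp_path / "r.bed"
    write_regions_bed([r], path)
    assert path.read_text() == "Chr1\t99\t200\tm\n"
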