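import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import crossfsv as cf
from crossfsv import qcio
from crossfsv.containers import GenomicInterval


class TestKosambi:
    def test_zero_distance(self):
        assert cf.kosambi_recombination(0.0) == 0.0

    def test_ten_cm(self):
        # independently: r = tanh(0.2)/2
        assert cf.kosambi_recombination(10.0) == pytest.approx(
            np.tanh(0.2) / 2.0, abs=1e-12
        )
        assert cf.kosambi_recombination(10.0) == pytest.approx(0.09869, abs=5e-6)

    def test_asymptote(self):
        assert cf.kosambi_recombination(1000.0) == pytest.approx(0.5, abs=1e-9)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            cf.kosambi_recombination(-1.0)

    @given(st.floats(min_value=0.0, max_value=500.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_half_open(self, d):
        r = cf.kosambi_recombination(d)
        assert 0.0 <= r < 0.5


class TestGeneticMap:
    def test_two_marker_construction(self):
        g = cf.build_genetic_map(1, 2, 10.0, seed=1)
        assert g.n_markers == 2
        assert g.cm[1] - g.cm[0] == pytest.approx(10.0)

    def test_monotone_everywhere(self):
        g = cf.build_genetic_map(18, 50, 2.0, seed=7)
        assert g.n_markers == 900
        for c in g.chromosomes:
            sl = g.chrom_slice(c)
            assert np.all(np.diff(g.cm[sl]) > 0)
            assert np.all(np.diff(g.bp[sl]) > 0)

    def test_deterministic(self):
        a = cf.build_genetic_map(3, 20, 1.5, seed=42)
        b = cf.build_genetic_map(3, 20, 1.5, seed=42)
        assert a == b

    @pytest.mark.parametrize("bad", [(0, 5, 1.0), (1, 0, 1.0), (1, 5, 0.0)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            cf.build_genetic_map(*bad, seed=0)


class TestSimulateCross:
    def test_f1_all_heterozygous_when_q_fixed(self, gmap):
        cfg = cf.lk_config(gmap, seed=4, n_f2=50, n_f1=10, n_f0_sires=4, n_f0_dams=4)
        cross = cf.simulate_cross(cfg, gmap)
        f1 = (cross.pedigree["generation"] == 1).to_numpy()
        assert np.all(cross.qtl_genotypes()[f1] == 1)

    def test_f2_segregation_1_2_1(self, gmap):
        cfg = cf.lk_config(gmap, seed=5, n_f2=1000, n_f1=20, n_f0_sires=5, n_f0_dams=5)
        cross = cf.simulate_cross(cfg, gmap)
        g = cross.qtl_genotypes()[cross.f2_mask]
        n_het = int((g == 1).sum())
        # binomial check: heterozygote count ~ Bin(1000, 1/2)
        assert abs(n_het - 500) < 3 * np.sqrt(1000 * 0.25)

    def test_no_recombination_on_null_map(self):
        g = cf.build_genetic_map(1, 10, 1.0, seed=2)
        g.cm[:] = np.arange(10) * 1e-7     # effectively zero genetic length
        cfg = cf.lk_config(g, seed=3, n_f2=40, n_f1=6, n_f0_sires=3, n_f0_dams=3)
        cross = cf.simulate_cross(cfg, g)
        for r in np.flatnonzero(cross.f2_mask)[:20]:
            sire = cross.row(cross.pedigree.loc[r, "sire"])
            pat = cross.haplotypes[r, 0]
            assert np.array_equal(pat, cross.haplotypes[sire, 0]) or np.array_equal(
                pat, cross.haplotypes[sire, 1]
            )

    def test_deterministic_given_seed(self, gmap):
        cfg = cf.lk_config(gmap, seed=8, n_f2=60, n_f1=8, n_f0_sires=4, n_f0_dams=4)
        a = cf.simulate_cross(cfg, gmap)
        b = cf.simulate_cross(cfg, gmap)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.pedigree.equals(b.pedigree)

    def test_mendelian_consistent(self, cross_medium):
        cross, _ = cross_medium
        rates, informative = qcio.check_mendelian(cross.genotypes(), cross.pedigree)
        assert informative.min() > 0
        assert np.all(rates == 0.0)

    def test_qtl_off_map_raises(self, gmap):
        cfg = cf.lk_config(gmap, seed=1, n_f2=10, n_f1=4, n_f0_sires=2, n_f0_dams=2)
        import dataclasses

        cfg.qtl = dataclasses.replace(cfg.qtl, bp=12345)
        with pytest.raises(ValueError):
            cf.simulate_cross(cfg, gmap)

    def test_segregation_chi2_across_seeds(self, gmap):
        fails = 0
        for seed in range(20):
            cfg = cf.lk_config(gmap, seed=100 + seed, n_f2=300, n_f1=10,
                               n_f0_sires=4, n_f0_dams=4)
            g = cf.simulate_cross(cfg, gmap).qtl_genotypes()
            g = g[-300:]
            obs = np.bincount(g, minlength=3)
            chi2 = (((obs - 300 * np.array([0.25, 0.5, 0.25])) ** 2)
                    / (300 * np.array([0.25, 0.5, 0.25]))).sum()
            if stats.chi2.sf(chi2, 2) <= 0.001:
                fails += 1
        assert fails <= 1


class TestSimulatePhenotypes:
    def test_pure_residual_variance(self, gmap):
        cfg = cf.lk_config(gmap, seed=6, n_f2=1000, n_f1=20, n_f0_sires=5,
                           n_f0_dams=5, sigma_g2=(0.0, 0.0), sigma_e2=(1.0, 1.0),
                           sex_effects=(0.0, 0.0), batch_amplitudes=(0.0, 0.0),
                           carcass_slopes=(0.0, 0.0))
        import dataclasses

        cfg.qtl = dataclasses.replace(cfg.qtl, add_effects=(0.0, 0.0))
        cross = cf.simulate_cross(cfg, gmap)
        tab = cf.simulate_phenotypes(cross, cfg, seed=1)
        assert tab["trait1"].var() == pytest.approx(1.0, rel=0.10)

    def test_additivity_of_genotype_means(self, cross_medium):
        cross, cfg = cross_medium
        g = cross.qtl_genotypes()[cross.f2_mask]
        y = cross.phenotypes["trait1"].to_numpy()
        m = [y[g == k].mean() for k in (0, 1, 2)]
        se = np.sqrt(sum(y[g == k].var() / (g == k).sum() for k in (0, 2)) / 4
                     + y[g == 1].var() / (g == 1).sum())
        assert abs(m[1] - (m[0] + m[2]) / 2) < 3 * se

    def test_residual_correlation_recovered(self, gmap):
        cfg = cf.lk_config(gmap, seed=7, n_f2=1000, n_f1=20, n_f0_sires=5,
                           n_f0_dams=5, sigma_g2=(0.0, 0.0),
                           residual_corr=0.5)
        import dataclasses

        cfg.qtl = dataclasses.replace(cfg.qtl, add_effects=(0.0, 0.0))
        cross = cf.simulate_cross(cfg, gmap)
        tab = cf.simulate_phenotypes(cross, cfg, seed=2)
        r = np.corrcoef(tab["trait1"], tab["trait2"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.1)

    def test_requires_truth(self, gmap):
        cfg = cf.lk_config(gmap, seed=1, n_f2=20, n_f1=4, n_f0_sires=2, n_f0_dams=2)
        cross = cf.simulate_cross(cfg, gmap)
        cross.truth = {}
        with pytest.raises(ValueError):
            cf.simulate_phenotypes(cross, cfg, seed=0)


@pytest.fixture
def region(cross_medium):
    cross, _ = cross_medium
    bp = cross.truth["qtl_bp"]
    return GenomicInterval("1", bp - 150_000, bp + 150_000)


class TestVariantPanels:
    def test_empty_panel(self, cross_medium, region):
        cross, _ = cross_medium
        panels, motifs = cf.simulate_variant_panels(
            [cross], region, n_variants=0, n_pattern_consistent=0, seed=1
        )
        assert panels[0].n_variants == 0

    def test_all_multiallelic(self, cross_medium, region):
        from crossfsv import masa

        cross, _ = cross_medium
        panels, _ = cf.simulate_variant_panels(
            [cross], region, n_variants=30, n_pattern_consistent=0,
            multiallelic_frac=1.0, include_causal=False, seed=2,
        )
        assert masa.filter_biallelic(panels[0]).n == 0

    def test_multiallelic_fraction(self, cross_medium, region):
        from crossfsv import masa

        cross, _ = cross_medium
        panels, _ = cf.simulate_variant_panels(
            [cross], region, n_variants=100, n_pattern_consistent=9,
            multiallelic_frac=0.1, seed=3,
        )
        s1 = masa.filter_biallelic(panels[0])
        assert s1.stage_counts["biallelic"] == 100 - round(0.1 * 90)

    def test_causal_recorded_and_in_motif(self, cross_medium, region):
        cross, _ = cross_medium
        panels, motifs = cf.simulate_variant_panels(
            [cross], region, n_variants=50, n_pattern_consistent=5, seed=4
        )
        pos = cross.truth["causal_variant_pos"]
        i = int(np.flatnonzero(panels[0].positions == pos)[0])
        assert len(panels[0].ref[i]) == 7 and panels[0].alt[i] == [panels[0].ref[i][0]]
        assert motifs.overlaps(panels[0].variant_span(i))

    def test_region_too_small(self, cross_medium):
        cross, _ = cross_medium
        bp = cross.truth["qtl_bp"]
        tiny = GenomicInterval("1", bp - 300, bp + 300)
        with pytest.raises(ValueError):
            cf.simulate_variant_panels([cross], tiny, n_variants=500,
                                       n_pattern_consistent=10, seed=1)


class TestPersistence:
    def test_save_load_round_trip(self, cross_medium, tmp_path):
        from crossfsv.simcross import load_cross, save_cross

        cross, cfg = cross_medium
        save_cross(cross, tmp_path / "c", cfg)
        back = load_cross(tmp_path / "c")
        assert np.array_equal(back.haplotypes, cross.haplotypes)
        assert np.array_equal(back.origins, cross.origins)
        assert back.truth["qtl_bp"] == cross.truth["qtl_bp"]
        assert np.allclose(
            back.phenotypes["trait1"], cross.phenotypes["trait1"]
        )
        assert list(back.f1_sire_ids) == list(cross.f1_sire_ids)
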