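import numpy as np
import pytest

import crossfsv as cf
from crossfsv import linkage, masa
from crossfsv.containers import GenomicInterval, MotifTrack, VariantPanel


def make_panel(genotypes, positions=None, ref=None, alt=None, samples=None,
               cross_id="X"):
    """Hand-built panel; genotypes: list of per-variant lists of (a, b)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_var, n_s, _ = g.shape
    return VariantPanel(
        chrom="12",
        positions=np.asarray(positions if positions is not None
                             else 100 + 10 * np.arange(n_var)),
        ref=ref if ref is not None else ["A"] * n_var,
        alt=alt if alt is not None else [["C"]] * n_var,
        sample_ids=samples if samples is not None
        else [f"s{i}" for i in range(n_s)],
        genotypes=g,
        cross_id=cross_id,
    )


def calls(het=(), hom=()):
    return [masa.SireQTLCall(s, 3.0, "heterozygous", 40) for s in het] + [
        masa.SireQTLCall(s, -3.0, "homozygous", 40) for s in hom
    ]


class TestCallRule:
    @pytest.mark.parametrize(
        "lr,expected",
        [(3.0, "heterozygous"), (2.01, "heterozygous"), (0.0, "undetermined"),
         (1.99, "undetermined"), (-1.99, "undetermined"), (-2.01, "homozygous"),
         (-5.0, "homozygous")],
    )
    def test_thresholds(self, lr, expected):
        assert masa._call_from_lr(lr) == expected


class TestMasaCalls:
    def test_recovery_with_prescribed_sires(self, cross_masa):
        cross, cfg = cross_masa
        truth = cross.truth["sire_qtl"]
        prof = linkage.line_cross_scan(cross, "trait1", step_cm=2.0)
        out = masa.masa_genotype_sires(
            cross, "trait1", prof.peak_cm, prof.peak_add_effect
        )
        wrong = sum(
            (truth[c.sire_id] == "het" and c.call == "homozygous")
            or (truth[c.sire_id] == "hom" and c.call == "heterozygous")
            for c in out
        )
        correct = sum(
            (truth[c.sire_id] == "het" and c.call == "heterozygous")
            or (truth[c.sire_id] == "hom" and c.call == "homozygous")
            for c in out
        )
        assert wrong == 0
        assert correct + sum(c.call == "undetermined" for c in out) == 12
        assert correct >= 8

    def test_small_family_rejected(self, cross_medium):
        cross, _ = cross_medium
        with pytest.raises(ValueError):
            masa.masa_genotype_sires(cross, "trait1", 60.0, 1.0,
                                     min_offspring=100)


class TestBiallelicFilter:
    def test_triallelic_removed_biallelic_kept(self):
        panel = make_panel(
            [
                [(0, 1), (1, 2)],      # three observed alleles -> removed
                [(0, 1), (1, 1)],      # two observed -> kept
                [(0, 0), (0, 0)],      # monomorphic in samples -> removed
            ],
            alt=[["C", "T"], ["C"], ["C"]],
        )
        s1 = masa.filter_biallelic(panel)
        assert list(s1.positions) == [110]
        assert s1.stage_counts == {"input": 3, "biallelic": 1}

    def test_empty_panel_raises(self):
        panel = make_panel(np.zeros((0, 2, 2)), positions=[], ref=[], alt=[],
                           samples=["a", "b"])
        with pytest.raises(ValueError):
            masa.filter_biallelic(panel)


class TestSegregationPattern:
    def _panel(self):
        # samples: het-called sires h1, h2; hom-called sire m1
        return make_panel(
            [
                [(0, 1), (0, 1), (1, 1)],   # het in hets, hom in hom -> keep
                [(0, 0), (0, 1), (1, 1)],   # hom in one het sire -> drop
                [(0, 1), (0, 1), (0, 1)],   # het in hom sire -> drop
                [(-1, -1), (0, 1), (0, 0)], # missing in a called sire -> drop
            ],
            samples=["h1", "h2", "m1"],
        )

    def test_pattern_rule(self):
        s1 = masa.filter_biallelic(self._panel())
        s2 = masa.filter_segregation_pattern(s1, calls(het=("h1", "h2"), hom=("m1",)))
        assert list(s2.positions) == [100]

    def test_undetermined_sires_unconstrained(self):
        s1 = masa.filter_biallelic(self._panel())
        und = [masa.SireQTLCall("h2", 0.5, "undetermined", 40)]
        s2 = masa.filter_segregation_pattern(
            s1, calls(het=("h1",)) + und
        )
        # only h1 constrains now: variants 0 and 2 are het in h1; variant 3 is
        # missing in h1... wait variant 3 is missing in h1 -> dropped
        assert set(s2.positions) == {100, 120}

    def test_no_called_sires(self):
        s1 = masa.filter_biallelic(self._panel())
        with pytest.raises(ValueError):
            masa.filter_segregation_pattern(
                s1, [masa.SireQTLCall("h1", 0.0, "undetermined", 40)]
            )

    def test_order_stability_stage1_stage2(self):
        """Applying the pattern filter before the biallelic filter gives the
        same final variant set (commuting filters)."""
        panel = self._panel()
        c = calls(het=("h1", "h2"), hom=("m1",))
        ab = masa.filter_segregation_pattern(masa.filter_biallelic(panel), c)
        # reversed order: seed the candidate set with everything
        all_idx = masa.FSVCandidateSet(
            panel.cross_id, panel, np.arange(panel.n_variants),
            {"input": panel.n_variants},
        )
        ba = masa.filter_biallelic(
            masa.filter_segregation_pattern(all_idx, c).panel.subset(
                masa.filter_segregation_pattern(all_idx, c).index
            )
        )
        assert set(ab.positions) == set(ba.panel.positions[ba.index])


class TestIntersection:
    def test_disjoint_empty(self):
        a = masa.filter_biallelic(make_panel([[(0, 1), (0, 1)]], positions=[100]))
        b = masa.filter_biallelic(make_panel([[(0, 1), (0, 1)]], positions=[200]))
        assert masa.intersect_crosses(a, b).n == 0

    def test_subset_returns_subset(self):
        g = [[(0, 1), (0, 1)], [(1, 1), (0, 1)]]
        a = masa.filter_biallelic(make_panel(g[:1], positions=[100]))
        b = masa.filter_biallelic(make_panel(g, positions=[100, 110]))
        out = masa.intersect_crosses(a, b)
        assert list(out.positions) == [100]

    def test_same_position_different_alleles_not_shared(self):
        a = masa.filter_biallelic(make_panel([[(0, 1), (0, 1)]], alt=[["C"]]))
        b = masa.filter_biallelic(make_panel([[(0, 1), (0, 1)]], alt=[["T"]]))
        assert masa.intersect_crosses(a, b).n == 0


class TestMotifOverlap:
    def _candidates(self, positions, ref=None):
        n = len(positions)
        panel = make_panel(
            [[(0, 1), (0, 1)]] * n, positions=positions,
            ref=ref if ref else ["A"] * n,
        )
        return masa.filter_biallelic(panel)

    def test_interior_and_boundary(self):
        track = MotifTrack("12", np.array([99]), np.array([200]))
        c = self._candidates([150, 100, 250])
        out = masa.filter_motif_overlap(c, track)
        # BED 99-200 covers 1-based 100..200: both 150 and 100 kept
        assert set(out.positions) == {150, 100}

    def test_deletion_overlaps_by_deleted_span(self):
        # deletion at POS 95 removes bases 96..101; motif starts at 1-based 100
        track = MotifTrack("12", np.array([99]), np.array([200]))
        c = self._candidates([95], ref=["GTTTTTT"])
        out = masa.filter_motif_overlap(c, track)
        assert list(out.positions) == [95]

    def test_empty_track(self):
        track = MotifTrack("12", np.empty(0, dtype=int), np.empty(0, dtype=int))
        out = masa.filter_motif_overlap(self._candidates([150]), track)
        assert out.n == 0


@pytest.fixture(scope="module")
def cascade_run(cross_masa, gmap):
    cross_a, _ = cross_masa
    cfg_b = cf.dk_config(
        gmap, seed=22, n_f2=400, n_f1=10, n_f0_sires=5, n_f0_dams=5,
        qtl_var_share=0.4, sire_qtl_pattern=("het", "het", "het", "hom", "hom"),
    )
    cross_b = cf.simulate(cfg_b, gmap)
    out = {}
    for tag, cross in (("a", cross_a), ("b", cross_b)):
        prof = linkage.line_cross_scan(cross, "trait1", step_cm=2.0)
        out[tag] = (cross, masa.masa_genotype_sires(
            cross, "trait1", prof.peak_cm, prof.peak_add_effect
        ))
    bp = cross_a.truth["qtl_bp"]
    region = GenomicInterval("1", bp - 250_000, bp + 250_000)
    panels, motifs = cf.simulate_variant_panels(
        [cross_a, cross_b], region, n_variants=200, n_pattern_consistent=25,
        seed=33,
    )
    final = masa.run_cascade(panels[0], out["a"][1], panels[1], out["b"][1], motifs)
    return final, cross_a


class TestCascadeEndToEnd:
    def test_only_planted_causal_survives(self, cascade_run):
        final, cross = cascade_run
        assert list(final.positions) == [cross.truth["causal_variant_pos"]]

    def test_stage_counts_monotone(self, cascade_run):
        final, _ = cascade_run
        counts = list(final.stage_counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_pattern_stage_counts_planted_variants(self, cascade_run):
        final, _ = cascade_run
        assert final.stage_counts["pattern"] == 25 + 1
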