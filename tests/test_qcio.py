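from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import crossfsv as cf
from crossfsv import qcio
from crossfsv.containers import MotifTrack, VariantPanel


def _hwe_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct enumeration of genotype tables with the same
    allele counts, in exact rational arithmetic."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - het) // 2
        bb = n - aa - het
        if bb < 0:
            continue
        # P(table | allele counts): multinomial x 2^het / C(2n, n_a)
        num = Fraction(
            comb(n, aa) * comb(n - aa, het) * 2**het, comb(2 * n, n_a)
        )
        probs[het] = num
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWEExact:
    @pytest.mark.parametrize(
        "table",
        [(5, 10, 5), (0, 20, 0), (10, 0, 10), (3, 4, 13), (1, 1, 18), (7, 6, 7),
         (0, 1, 19), (2, 16, 2)],
    )
    def test_matches_enumeration_oracle(self, table):
        assert qcio.hwe_exact_test(*table) == pytest.approx(
            _hwe_oracle(*table), abs=1e-10
        )

    def test_balanced_marker_retained(self):
        # 1:2:1 at n=1000 is the HWE ideal; p must be far above 1e-6
        assert qcio.hwe_exact_test(250, 500, 250) > 0.5


class TestPedMap:
    @pytest.fixture
    def tiny(self):
        ped = pd.DataFrame(
            {"id": ["a", "b"], "sire": ["0", "0"], "dam": ["0", "0"],
             "sex": ["M", "F"]}
        )
        G = np.array([[0, 1], [2, -1]], dtype=np.int8)
        gmap = cf.build_genetic_map(1, 2, 5.0, seed=1)
        return ped, G, gmap

    def test_round_trip(self, tiny, tmp_path):
        ped, G, gmap = tiny
        qcio.write_ped_map(tmp_path / "x.ped", tmp_path / "x.map", ped, G, gmap)
        ped2, G2, gmap2 = qcio.read_ped_map(tmp_path / "x.ped", tmp_path / "x.map")
        assert np.array_equal(G, G2)
        assert gmap2 == gmap
        assert list(ped2["id"]) == ["a", "b"]

    def test_missing_code_round_trip(self, tiny, tmp_path):
        ped, G, gmap = tiny
        qcio.write_ped_map(tmp_path / "x.ped", tmp_path / "x.map", ped, G, gmap)
        text = (tmp_path / "x.ped").read_text()
        assert "0 0" in text          # missing genotype encoding
        _, G2, _ = qcio.read_ped_map(tmp_path / "x.ped", tmp_path / "x.map")
        assert G2[1, 1] == qcio.MISSING

    def test_unsorted_map_rejected(self, tmp_path):
        (tmp_path / "bad.map").write_text("1\tm1\t5.0\t500\n1\tm2\t1.0\t100\n")
        with pytest.raises(ValueError):
            qcio.read_map(tmp_path / "bad.map")

    def test_field_count_mismatch(self, tiny, tmp_path):
        ped, G, gmap = tiny
        qcio.write_ped_map(tmp_path / "x.ped", tmp_path / "x.map", ped, G, gmap)
        with open(tmp_path / "x.ped", "a") as fh:
            fh.write("0 c 0 0 1 -9 1 1\n")   # one marker short
        with pytest.raises(ValueError):
            qcio.read_ped_map(tmp_path / "x.ped", tmp_path / "x.map")


class TestVcfBed:
    @pytest.fixture
    def panel(self):
        return VariantPanel(
            chrom="12",
            positions=np.array([100, 250, 300]),
            ref=["A", "C", "GTTTTTT"],
            alt=[["G"], ["A", "T"], ["G"]],
            sample_ids=["s1", "s2"],
            genotypes=np.array(
                [[[0, 1], [1, 1]], [[0, 2], [-1, -1]], [[0, 0], [0, 1]]],
                dtype=np.int8,
            ),
        )

    def test_vcf_round_trip(self, panel, tmp_path):
        qcio.write_vcf_minimal(panel, tmp_path / "p.vcf")
        back = qcio.read_vcf_minimal(tmp_path / "p.vcf")
        assert np.array_equal(back.positions, panel.positions)
        assert back.ref == panel.ref and back.alt == panel.alt
        assert np.array_equal(back.genotypes, panel.genotypes)

    def test_multiallelic_flag(self, panel):
        assert panel.n_alt(1) == 2          # ALT "A,T" is not biallelic
        assert panel.n_alt(0) == 1

    def test_empty_vcf(self, tmp_path):
        (tmp_path / "e.vcf").write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        back = qcio.read_vcf_minimal(tmp_path / "e.vcf")
        assert back.n_variants == 0

    def test_bed_convention(self, tmp_path):
        (tmp_path / "m.bed").write_text("12\t99\t200\tsite\n")
        track = qcio.read_bed(tmp_path / "m.bed")
        iv = track.to_intervals()[0]
        assert (iv.start, iv.end) == (100, 200)

    def test_bed_round_trip(self, tmp_path):
        t = MotifTrack("5", np.array([10, 50]), np.array([20, 80]), ["a", "b"])
        qcio.write_bed(t, tmp_path / "t.bed")
        back = qcio.read_bed(tmp_path / "t.bed")
        assert np.array_equal(back.starts, t.starts)
        assert np.array_equal(back.ends, t.ends)

    def test_bed_bad_coordinates(self, tmp_path):
        (tmp_path / "b.bed").write_text("12\tfoo\t200\n")
        with pytest.raises(ValueError):
            qcio.read_bed(tmp_path / "b.bed")

    def test_empty_bed(self, tmp_path):
        (tmp_path / "e.bed").write_text("")
        assert len(qcio.read_bed(tmp_path / "e.bed")) == 0


class TestMarkerQC:
    def test_rules_and_idempotence(self):
        rng = np.random.default_rng(5)
        good = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(1000, 1))
        mono = np.zeros((1000, 1), dtype=int)
        low_call = good.copy()
        low_call[rng.random(1000) < 0.15] = -1       # 85% call rate
        G = np.hstack([good, mono, low_call]).astype(np.int8)
        keep, report = qcio.qc_filter_markers(G, qcio.MarkerQCRule())
        assert keep.tolist() == [True, False, False]
        assert report.loc[1, "fail_maf"] and report.loc[2, "fail_call_rate"]
        # idempotent: filtering the retained set keeps it unchanged
        keep2, _ = qcio.qc_filter_markers(G[:, keep], qcio.MarkerQCRule())
        assert keep2.all()

    def test_hwe_rule_uses_f2_subset(self):
        # F0/F1 rows wildly out of HWE; F2 rows balanced -> retained
        f2 = np.repeat([False, True], [50, 1000])
        rng = np.random.default_rng(6)
        col = np.concatenate(
            [np.zeros(50, int),
             rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=1000)]
        )[:, None].astype(np.int8)
        keep, _ = qcio.qc_filter_markers(col, qcio.MarkerQCRule(), f2_mask=f2)
        assert keep[0]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            qcio.qc_filter_markers(np.empty((0, 0)), qcio.MarkerQCRule())

    def test_rule_bounds(self):
        with pytest.raises(ValueError):
            qcio.MarkerQCRule(maf_min=1.5)


class TestMendelian:
    @pytest.fixture
    def trio(self):
        return pd.DataFrame(
            {"id": ["s", "d", "c"], "sire": ["0", "0", "s"],
             "dam": ["0", "0", "d"]}
        )

    def test_impossible_child(self, trio):
        G = np.array([[0], [0], [1]], dtype=np.int8)    # AA x AA -> AB
        rates, informative = qcio.check_mendelian(G, trio)
        assert rates[0] == 1.0 and informative[0] == 1

    def test_het_parents_never_error(self, trio):
        for child in (0, 1, 2):
            G = np.array([[1], [1], [child]], dtype=np.int8)
            rates, _ = qcio.check_mendelian(G, trio)
            assert rates[0] == 0.0

    def test_missing_parent_skipped(self):
        ped = pd.DataFrame(
            {"id": ["c"], "sire": ["nope"], "dam": ["nada"]}
        )
        rates, informative = qcio.check_mendelian(
            np.array([[2]], dtype=np.int8), ped
        )
        assert informative[0] == 0 and rates[0] == 0.0


class TestTrioPhase:
    def test_resolves_when_parent_homozygous(self):
        ped = pd.DataFrame(
            {"id": ["s", "d", "c"], "sire": ["0", "0", "s"],
             "dam": ["0", "0", "d"]}
        )
        #           marker: sire hom alt, dam hom ref, child het -> paternal allele 1
        G = np.array([[2, 1], [0, 1], [1, 1]], dtype=np.int8)
        haps = qcio.trio_phase(G, ped)
        assert haps[2, 0, 0] == 1 and haps[2, 1, 0] == 0
        # both parents heterozygous: unresolved
        assert haps[2, 0, 1] == qcio.MISSING

    def test_homozygous_child_trivially_phased(self):
        ped = pd.DataFrame({"id": ["x"], "sire": ["0"], "dam": ["0"]})
        haps = qcio.trio_phase(np.array([[0, 2]], dtype=np.int8), ped)
        assert haps[0].tolist() == [[0, 1], [0, 1]]
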