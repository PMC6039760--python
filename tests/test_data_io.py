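import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeblup.data_io import (MISSING, GenotypeMatrix, PhenotypeTable, SnpRecord,
                              adjust_phenotypes, qc_filter, read_genotypes,
                              read_phenotypes, read_snp_map, write_genotypes,
                              write_phenotypes, write_snp_map)

from conftest import make_matrix, make_pheno


class TestReadGenotypes:
    def test_vcf_het_call_is_one(self, tmp_path):
        g = make_matrix([[1]])
        path = write_genotypes(g, tmp_path / "one.vcf", "vcf")
        back = read_genotypes(path)
        assert back.dosage.tolist() == [[1]]
        assert back.animal_ids == ["a1"]

    def test_vcf_gt_coding(self, tmp_path):
        g = make_matrix([[0], [1], [2], [MISSING]])
        back = read_genotypes(write_genotypes(g, tmp_path / "x.vcf", "vcf"))
        assert back.dosage[:, 0].tolist() == [0, 1, 2, MISSING]

    def test_multiallelic_vcf_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\tbad1\tA\tC,G\t.\t.\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="bad1"):
            read_genotypes(path)

    def test_plink_raw_row(self, tmp_path):
        path = tmp_path / "g.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE s1_A s2_A s3_A\n"
            "F1 A1 0 0 1 -9 0 2 NA\n")
        g = read_genotypes(path)
        assert g.animal_ids == ["A1"]
        assert g.dosage[0].tolist() == [0, 2, MISSING]
        assert g.snp_ids == ["s1", "s2", "s3"]

    def test_plink_malformed_value_names_line(self, tmp_path):
        path = tmp_path / "g.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE s1_A\nF1 A1 0 0 1 -9 7\n")
        with pytest.raises(ValueError, match="line 2"):
            read_genotypes(path)

    def test_unknown_format(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("animal_id\ts1\na1\t0\n")
        with pytest.raises(ValueError, match="unknown genotype format"):
            read_genotypes(p, format="bed")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_genotypes("/nonexistent/geno.tsv")

    @pytest.mark.parametrize("fmt", ["vcf", "plink_raw", "tsv"])
    def test_round_trip_identity(self, tmp_path, rng, fmt):
        dosage = rng.integers(0, 3, size=(10, 50))
        dosage[rng.random((10, 50)) < 0.05] = MISSING
        g = make_matrix(dosage, chroms=rng.integers(1, 4, 50),
                        positions=np.cumsum(rng.integers(1, 1000, 50)))
        g.snps.sort(key=lambda s: (s.chrom, s.pos_bp))
        path = write_genotypes(g, tmp_path / f"g.{fmt}", fmt)
        back = read_genotypes(path, fmt, snp_map=g.snps)
        np.testing.assert_array_equal(back.dosage, g.dosage)
        assert back.animal_ids == g.animal_ids
        assert [s.snp_id for s in back.snps] == g.snp_ids

    def test_snp_map_round_trip(self, tmp_path):
        snps = [SnpRecord("rs1", "1", 100, "A", "C"), SnpRecord("rs2", "X", 5, "G", "T")]
        back = read_snp_map(write_snp_map(snps, tmp_path / "map.tsv"))
        assert back == snps

    def test_phenotype_round_trip(self, tmp_path):
        p = make_pheno([1.0, 2.5], groups=["G1", "G2"], ages=[400, 410])
        back = read_phenotypes(write_phenotypes(p, tmp_path / "p.tsv"))
        pd.testing.assert_frame_equal(back.data, p.data, check_dtype=False)


class TestGenotypeMatrixValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate animal ids"):
            GenotypeMatrix(["a", "a"], [SnpRecord("s1", "1", 1)],
                           np.zeros((2, 1), dtype=np.int8))

    def test_bad_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosage values"):
            make_matrix([[5]])

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError, match="pos_bp"):
            SnpRecord("s1", "1", 0)


class TestQcFilter:
    def test_low_maf_removed(self):
        # MAFs: 0.30, 0.005, 0.30 over 100 animals
        n = 100
        dosage = np.zeros((n, 3), dtype=np.int8)
        dosage[:60, 0] = 1
        dosage[0, 1] = 1  # freq 0.005
        dosage[40:, 2] = 1
        g = make_matrix(dosage)
        g2, removed = qc_filter(g, maf_min=0.01)
        assert removed == ["s2"]
        assert g2.snp_ids == ["s1", "s3"]
        assert g2.animal_ids == g.animal_ids

    def test_missing_call_removes_despite_maf(self):
        dosage = np.tile([0, 1, 2, 1, 0], (4, 1)).T.astype(np.int8)  # 5x4, MAF .4
        dosage[0, 1] = MISSING
        g = make_matrix(dosage)
        g2, reasons = qc_filter(g, maf_min=0.01, return_reasons=True)
        assert "s2" in reasons and "missing_call" in reasons["s2"]
        assert g2.m_snps == 3

    def test_tie_at_threshold_retained(self):
        # exactly MAF = 0.10 with 10 animals: 2 het of 20 alleles
        dosage = np.zeros((10, 1), dtype=np.int8)
        dosage[:2, 0] = 1
        g2, removed = qc_filter(make_matrix(dosage), maf_min=0.10)
        assert removed == []
        assert g2.m_snps == 1

    def test_all_removed_errors(self):
        g = make_matrix(np.zeros((10, 2), dtype=np.int8))  # monomorphic
        with pytest.raises(ValueError, match="every SNP"):
            qc_filter(g, maf_min=0.01)

    def test_idempotent(self, rng):
        dosage = rng.integers(0, 3, size=(40, 30))
        dosage[rng.random((40, 30)) < 0.01] = MISSING
        g = make_matrix(dosage)
        once, _ = qc_filter(g, 0.05)
        twice, removed2 = qc_filter(once, 0.05)
        assert removed2 == []
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_bad_maf_min(self):
        with pytest.raises(ValueError):
            qc_filter(make_matrix([[1]]), maf_min=0.7)


class TestAdjustPhenotypes:
    def test_single_group_constant_age_identity(self, rng):
        y = rng.normal(100, 10, 30)
        adj = adjust_phenotypes(make_pheno(y))
        np.testing.assert_allclose(adj.data["y_adjusted"], y, atol=1e-9)
        np.testing.assert_allclose(adj.data["y_corrected"], y - y.mean(), atol=1e-9)

    def test_perfect_age_fit(self):
        ages = np.arange(300, 330)
        adj = adjust_phenotypes(make_pheno(2.0 * ages, ages=ages))
        np.testing.assert_allclose(adj.data["y_corrected"], 0.0, atol=1e-8)
        assert adj.fit["age_slope"] == pytest.approx(2.0)

    def test_known_group_effects_recovered(self, rng):
        n = 200
        groups = np.where(np.arange(n) % 2 == 0, "A", "B")
        truth = {"A": 10.0, "B": -10.0}
        y = 50 + np.array([truth[g] for g in groups]) + rng.normal(0, 2, n)
        adj = adjust_phenotypes(make_pheno(y, groups=groups))
        # contrast B - A should be about -20, within a few OLS standard errors
        se = 2.0 * np.sqrt(4.0 / n)
        assert adj.fit["group_effects"]["B"] == pytest.approx(-20.0, abs=4 * se)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 150
        groups = rng.choice(["A", "B", "C"], n)
        ages = rng.integers(300, 500, n)
        y = rng.normal(100, 15, n)
        adj = adjust_phenotypes(make_pheno(y, groups=groups, ages=ages))
        r = adj.data["y_corrected"].to_numpy()
        assert abs(r.sum()) < 1e-6
        assert abs(r @ ages) < 1e-5 * np.abs(r @ ages + 1)
        for gname in ["A", "B", "C"]:
            assert abs(r[groups == gname].sum()) < 1e-6

    def test_reference_group_invariance(self, rng):
        n = 90
        groups = rng.choice(["A", "B", "C"], n)
        y = rng.normal(0, 1, n)
        p = make_pheno(y, groups=groups)
        r1 = adjust_phenotypes(p, reference_group="A").data["y_corrected"]
        r2 = adjust_phenotypes(p, reference_group="C").data["y_corrected"]
        np.testing.assert_allclose(r1, r2, atol=1e-9)

    def test_singleton_group_warns(self):
        p = make_pheno([1, 2, 3, 4], groups=["A", "A", "A", "B"])
        with pytest.warns(UserWarning, match="single record"):
            adjust_phenotypes(p)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            PhenotypeTable(pd.DataFrame({"animal_id": ["a"], "y_raw": [1.0]}))


@settings(max_examples=20, deadline=None)
@given(st.integers(2, 12), st.integers(1, 8), st.integers(0, 2**32 - 1))
def test_tsv_round_trip_property(n, m, seed):
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(n, m))
    dosage[rng.random((n, m)) < 0.2] = MISSING
    g = make_matrix(dosage)
    import os
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "g.tsv")
        write_genotypes(g, path, "tsv")
        back = read_genotypes(path, "tsv")
    np.testing.assert_array_equal(back.dosage, g.dosage)
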