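"""Panel loading, genotype ingestion from VCF/matrix, and feature encoding."""

import numpy as np
import pandas as pd
import pytest

from t1dprs import encode, load_panel, read_genotypes
from t1dprs.panel import (
    AlleleMismatchError,
    PanelValidationError,
    SNPPanel,
    SNPRecord,
    write_dosage_matrix,
)

from conftest import make_genotypes, write_vcf


class TestLoadPanel:
    def test_packaged_panel_has_67_unique_variants(self, panel):
        assert len(panel) == 67
        assert len(set(panel.rsids)) == 67

    def test_known_record_values(self, panel):
        rec = panel.record("rs2476601")
        assert rec.risk_allele == "A"
        assert rec.beta == pytest.approx(0.64)
        assert rec.chromosome == "1"
        assert rec.position == 114377568

    def test_betas_are_signed_and_finite(self, panel):
        betas = panel.betas
        assert np.all(np.isfinite(betas))
        assert betas.max() > 0 > betas.min()  # panel mixes risk and protective weights

    def test_duplicate_rsid_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "rsid\trisk_allele\tbeta\tchromosome\tposition\n"
            "rs1\tA\t0.5\t1\t100\nrs1\tC\t0.2\t1\t200\n"
        )
        with pytest.raises(PanelValidationError, match="duplicate"):
            load_panel(p)

    def test_non_finite_beta_rejected(self):
        with pytest.raises(PanelValidationError, match="finite"):
            SNPRecord("rs1", "A", float("nan"), "1", 100)

    def test_custom_panel_roundtrip(self, tmp_path, mini_panel):
        p = tmp_path / "mini.tsv"
        rows = ["rsid\trisk_allele\tbeta\tchromosome\tposition"]
        for r in mini_panel:
            rows.append(f"{r.rsid}\t{r.risk_allele}\t{r.beta}\t{r.chromosome}\t{r.position}")
        p.write_text("\n".join(rows))
        loaded = load_panel(p)
        assert loaded.rsids == mini_panel.rsids
        assert np.allclose(loaded.betas, mini_panel.betas)


class TestReadVCF:
    def test_alt_is_risk_allele_counts_alt(self, tmp_path, mini_panel):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            ["s1", "s2", "s3"],
            [("1", 114377568, "rs2476601", "G", ["A"], ["0/1", "1/1", "0/0"])],
        )
        gm = read_genotypes(vcf, mini_panel)
        j = mini_panel.index_of("rs2476601")
        assert list(gm.dosages[:, j]) == [1, 2, 0]
        assert not gm.missing_mask[:, j].any()

    @pytest.mark.parametrize("a", [0, 1])
    @pytest.mark.parametrize("b", [0, 1])
    def test_ref_is_risk_allele_counts_complement(self, tmp_path, mini_panel, a, b):
        # oracle: dosage = 2 - ALT count, enumerated over diploid genotypes
        vcf = write_vcf(
            tmp_path / "b.vcf",
            ["s1"],
            [("1", 114377568, "rs2476601", "A", ["G"], [f"{a}/{b}"])],
        )
        gm = read_genotypes(vcf, mini_panel)
        assert gm.dosages[0, mini_panel.index_of("rs2476601")] == 2 - (a + b)

    @pytest.mark.parametrize("gt", ["0/0", "0/1", "1/1"])
    def test_orientation_consistency(self, tmp_path, mini_panel, gt):
        """Swapping REF/ALT roles (and flipping the genotype) leaves dosage unchanged."""
        a, b = (int(x) for x in gt.split("/"))
        flipped = f"{1 - a}/{1 - b}"
        v1 = write_vcf(tmp_path / "fwd.vcf", ["s1"],
                       [("1", 114377568, "rs2476601", "G", ["A"], [gt])])
        v2 = write_vcf(tmp_path / "rev.vcf", ["s1"],
                       [("1", 114377568, "rs2476601", "A", ["G"], [flipped])])
        j = mini_panel.index_of("rs2476601")
        d1 = read_genotypes(v1, mini_panel).dosages[0, j]
        d2 = read_genotypes(v2, mini_panel).dosages[0, j]
        assert d1 == d2 == a + b

    def test_indel_orientation_by_length(self, tmp_path, mini_panel):
        # I risk allele = longer allele; here ALT is the insertion
        # D risk allele = shorter allele; here REF is longer so ALT carries D
        vcf = write_vcf(
            tmp_path / "indel.vcf",
            ["s1"],
            [
                ("6", 31274794, "rs540653847", "T", ["TAC"], ["0/1"]),
                ("6", 31324737, "rs371250843", "CTT", ["C"], ["1/1"]),
            ],
        )
        gm = read_genotypes(vcf, mini_panel)
        assert gm.dosages[0, mini_panel.index_of("rs540653847")] == 1
        assert gm.dosages[0, mini_panel.index_of("rs371250843")] == 2

    def test_position_fallback_when_id_missing(self, tmp_path, mini_panel):
        vcf = write_vcf(
            tmp_path / "noid.vcf", ["s1"],
            [("1", 114377568, ".", "G", ["A"], ["1/1"])],
        )
        gm = read_genotypes(vcf, mini_panel)
        assert gm.dosages[0, mini_panel.index_of("rs2476601")] == 2

    def test_absent_panel_snp_becomes_missing_column(self, tmp_path, mini_panel):
        vcf = write_vcf(
            tmp_path / "sparse.vcf", ["s1", "s2"],
            [("1", 114377568, "rs2476601", "G", ["A"], ["0/1", "0/0"])],
        )
        gm = read_genotypes(vcf, mini_panel)
        assert gm.n_missing_columns == 3  # the other panel SNPs
        assert gm.missing_mask[:, mini_panel.index_of("rs61839660")].all()

    def test_allele_mismatch_names_rsid(self, tmp_path, mini_panel):
        vcf = write_vcf(
            tmp_path / "bad.vcf", ["s1"],
            [("1", 114377568, "rs2476601", "G", ["C"], ["0/1"])],
        )
        with pytest.raises(AlleleMismatchError, match="rs2476601"):
            read_genotypes(vcf, mini_panel)

    def test_missing_gt_masked(self, tmp_path, mini_panel):
        vcf = write_vcf(
            tmp_path / "mis.vcf", ["s1", "s2"],
            [("1", 114377568, "rs2476601", "G", ["A"], ["./.", "0/1"])],
        )
        gm = read_genotypes(vcf, mini_panel)
        j = mini_panel.index_of("rs2476601")
        assert gm.missing_mask[0, j] and not gm.missing_mask[1, j]


class TestDosageMatrix:
    def test_roundtrip_with_missing(self, tmp_path, mini_panel):
        dosages = [[0, 1, 2, 1], [2, 0, 1, 0]]
        missing = [[False, True, False, False], [False, False, False, True]]
        gm = make_genotypes(mini_panel, dosages, missing)
        path = tmp_path / "geno.tsv"
        write_dosage_matrix(gm, path)
        back = read_genotypes(path, mini_panel)
        assert np.array_equal(back.missing_mask, gm.missing_mask)
        assert np.array_equal(
            back.dosages[~back.missing_mask], gm.dosages[~gm.missing_mask]
        )

    def test_column_order_follows_panel_not_file(self, tmp_path, mini_panel):
        path = tmp_path / "shuffled.tsv"
        path.write_text(
            "subject_id\trs371250843\trs2476601\trs61839660\trs540653847\n"
            "s1\t1\t2\t0\t1\n"
        )
        gm = read_genotypes(path, mini_panel)
        assert gm.dosages[0, mini_panel.index_of("rs2476601")] == 2
        assert gm.dosages[0, mini_panel.index_of("rs371250843")] == 1


class TestEncode:
    def test_count_is_identity(self, mini_panel):
        rng = np.random.default_rng(0)
        dosages = rng.integers(0, 3, size=(5, 4))
        fm = encode(make_genotypes(mini_panel, dosages), "count")
        assert np.array_equal(fm.values, dosages)
        assert fm.feature_names == mini_panel.rsids

    def test_beta_weighted_scales_columns(self, mini_panel):
        rng = np.random.default_rng(1)
        dosages = rng.integers(0, 3, size=(6, 4))
        gm = make_genotypes(mini_panel, dosages)
        counts = encode(gm, "count").values
        weighted = encode(gm, "beta_weighted").values
        assert np.allclose(weighted, counts * mini_panel.betas)

    def test_beta_weighted_known_value(self, panel):
        dosages = np.zeros((1, 67))
        j = panel.index_of("rs2476601")
        dosages[0, j] = 2
        fm = encode(make_genotypes(panel, dosages), "beta_weighted")
        assert fm.values[0, j] == pytest.approx(1.28)
        assert np.count_nonzero(fm.values) == 1  # zero dosage annihilates both schemes

    def test_missing_entries_rejected(self, mini_panel):
        gm = make_genotypes(
            mini_panel, [[0, 1, 2, 1]], [[True, False, False, False]]
        )
        with pytest.raises(ValueError, match="impute"):
            encode(gm, "count")

    def test_unknown_scheme_rejected(self, mini_panel):
        gm = make_genotypes(mini_panel, [[0, 1, 2, 1]])
        with pytest.raises(ValueError, match="encoding"):
            encode(gm, "one_hot")
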