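import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latentgxe.scan import (
    GenotypeMatrix,
    ScanFilters,
    attenuation_analysis,
    gc_lambda,
    hwe_test_pvalue,
    interaction_followup,
    read_genotypes,
    run_scan,
)
from latentgxe.simulate import make_fixture_panel


class TestReadTsvMatrix:
    def test_round_trip(self, tmp_path):
        gm = GenotypeMatrix(
            counts=np.array([[0.0, 1.0], [1.0, np.nan], [2.0, 0.0]]),
            snp_ids=["rs1", "rs2"],
            sample_ids=["a", "b", "c"],
        )
        path = tmp_path / "g.tsv"
        gm.write_tsv(path)
        back = read_genotypes(path)
        assert np.array_equal(back.counts, gm.counts, equal_nan=True)
        assert back.snp_ids == gm.snp_ids
        assert back.sample_ids == gm.sample_ids

    def test_malformed_cell_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("iid\trs1\nind1\t0\nind2\t3\n")
        with pytest.raises(ValueError, match="line 3"):
            read_genotypes(path)


class TestReadPlinkRaw:
    def test_parses_dialect(self, tmp_path):
        path = tmp_path / "export.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_T\n"
            "f1 i1 0 0 1 2 0 2\n"
            "f2 i2 0 0 2 1 1 NA\n"
        )
        gm = read_genotypes(path, format="plink_raw")
        assert gm.snp_ids == ["rs1", "rs2"]
        assert gm.counted_allele == ["A", "T"]
        assert gm.sample_ids == ["i1", "i2"]
        assert np.array_equal(
            gm.counts, np.array([[0.0, 2.0], [1.0, np.nan]]), equal_nan=True
        )

    def test_missing_fixed_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.raw"
        path.write_text("IID rs1_A\ni1 0\n")
        with pytest.raises(ValueError, match="PLINK"):
            read_genotypes(path, format="plink_raw")


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
1\t300\trs3\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0
"""


class TestReadVcf:
    def test_gt_conversion_and_skips(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_TEXT)
        gm = read_genotypes(path, format="vcf")
        # multi-allelic rs3 skipped
        assert gm.snp_ids == ["rs1", "rs2"]
        assert gm.counts[:, 0] == pytest.approx([0.0, 1.0, 2.0])
        assert np.isnan(gm.counts[0, 1])
        assert gm.counts[1:, 1] == pytest.approx([1.0, 0.0])
        assert gm.counted_allele == ["G", "T"]


class TestHweFilter:
    def test_hwe_data_passes(self, rng):
        g = rng.binomial(2, 0.3, 5000)
        assert hwe_test_pvalue(g) > 1e-4

    def test_distorted_data_fails(self):
        # gross heterozygote excess
        g = np.r_[np.zeros(500), np.ones(4000), np.full(500, 2.0)]
        assert hwe_test_pvalue(g) < 1e-50


class TestGcLambda:
    def test_exact_uniform_quantiles_give_one(self):
        p = (np.arange(1, 10_000) - 0.5) / 10_000
        assert gc_lambda(p, df=1) == pytest.approx(1.0, abs=5e-3)
        assert gc_lambda(p, df=2) == pytest.approx(1.0, abs=5e-3)

    def test_halving_p_inflates(self):
        p = (np.arange(1, 1000) - 0.5) / 1000
        assert gc_lambda(p / 2, df=1) > gc_lambda(p, df=1)

    def test_uniform_draws_near_one(self, rng):
        p = rng.random(100_000)
        assert 0.99 < gc_lambda(p, df=1) < 1.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_lambda([], df=1)


@pytest.fixture(scope="module")
def panel():
    return make_fixture_panel(
        n=4_000, M=40, seed=13, maf_range=(0.2, 0.5),
        planted=[{"snp": 7, "kind": "additive", "beta": 0.8}],
    )


@pytest.fixture(scope="module")
def gxg_panel():
    return make_fixture_panel(
        n=8_000, M=12, seed=31,
        planted=[{"snp": 3, "kind": "latent_gxg", "beta": 0.5, "index": 0}],
    )


class TestRunScan:

    def test_planted_additive_snp_tops_joint(self, panel):
        table = run_scan(panel.y, panel.genotypes,
                         covariates=panel.covariates)
        ok = table[table["status"] == "ok"]
        assert ok.loc[ok["p_joint"].idxmin(), "snp"] == "snp00007"

    def test_monomorphic_excluded_with_status_row(self, panel):
        g = panel.genotypes.copy()
        g["snp_mono"] = 0.0
        table = run_scan(panel.y, g)
        row = table[table["snp"] == "snp_mono"].iloc[0]
        assert row["status"] == "filtered:monomorphic"
        assert np.isnan(row["p_joint"])

    def test_low_call_rate_filtered(self, panel):
        g = panel.genotypes.copy()
        col = g["snp00001"].to_numpy().copy()
        col[: int(0.5 * len(col))] = np.nan
        g["snp00001"] = col
        table = run_scan(panel.y, g)
        assert (
            table.loc[table["snp"] == "snp00001", "status"].iloc[0]
            == "filtered:call_rate"
        )

    def test_filter_accounting(self, panel):
        g = panel.genotypes.copy()
        g["snp_mono"] = 0.0
        table = run_scan(panel.y, g)
        assert len(table) == g.shape[1]
        assert set(table["status"]) <= {
            "ok", "filtered:monomorphic", "filtered:maf",
            "filtered:call_rate", "filtered:hwe",
        } | {s for s in table["status"] if s.startswith("failed")}

    def test_deterministic(self, panel):
        t1 = run_scan(panel.y, panel.genotypes)
        t2 = run_scan(panel.y, panel.genotypes)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_panel_size(self):
        null = make_fixture_panel(n=2_000, M=300, seed=21)
        table = run_scan(null.y, null.genotypes)
        ok = table[table["status"] == "ok"]
        frac = (ok["p_joint"] < 0.05).mean()
        # ~ Binomial(300, .05): 3 SE band
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(ok))

    def test_phenotype_mismatch_rejected(self, panel):
        with pytest.raises(ValueError, match="match"):
            run_scan(panel.y[:-1], panel.genotypes)


class TestInteractionFollowup:
    def test_planted_pair_flagged(self, gxg_panel):
        cands = [f"snp{j:05d}" for j in range(1, 12)]
        table = interaction_followup(
            gxg_panel.y, gxg_panel.genotypes, "snp00000", cands,
            covariates=gxg_panel.covariates,
        )
        assert set(table.columns) >= {
            "p_indirect", "p_interaction", "beta_D", "beta_GE"}
        flagged = table[table["significant_interaction"]]
        assert "snp00003" in set(flagged["snp"])

    def test_index_against_itself_rejected(self, gxg_panel):
        with pytest.raises(ValueError, match="itself"):
            interaction_followup(
                gxg_panel.y, gxg_panel.genotypes, "snp00000", ["snp00000"])


class TestAttenuation:
    def test_interaction_induced_dominance_shrinks(self):
        panel = make_fixture_panel(
            n=10_000, M=8, seed=41,
            planted=[
                {"snp": j, "kind": "latent_gxg", "beta": 0.5, "index": 0}
                for j in range(1, 6)
            ],
        )
        cands = [f"snp{j:05d}" for j in range(1, 6)]
        table = attenuation_analysis(
            panel.y, panel.genotypes, "snp00000", cands)
        assert {"abs_beta_D_before", "abs_beta_D_after",
                "se_beta_D_before", "se_beta_D_after"} <= set(table.columns)
        ratio = table["abs_beta_D_after"] / table["abs_beta_D_before"]
        assert ratio.median() < 1.0
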