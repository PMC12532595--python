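"""GWAS regression, IVW meta-analysis, conditional selection and clumping."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import bagwas as bw
from bagwas.syndata import GenotypePanel


def _panel_from_matrix(dos, pos=None, chrom="1"):
    m = dos.shape[1]
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos, "id": [f"rs{i + 1}" for i in range(m)],
        "a1": "A", "a2": "G",
        "maf": np.minimum(dos.mean(0) / 2, 1 - dos.mean(0) / 2),
        "ploidy_class": "diploid", "info": 1.0,
    })
    return GenotypePanel(variants=variants, dosages=dos.astype(float),
                         block_index=np.zeros(m, dtype=int))


class TestGwasLinear:
    def test_matches_statsmodels_ols(self):
        """Per-variant beta/se/p equal the full OLS fit to 1e-10."""
        rng = np.random.default_rng(0)
        n, m = 40, 5
        dos = rng.integers(0, 3, (n, m)).astype(float)
        panel = _panel_from_matrix(dos)
        cov = rng.standard_normal((n, 2))
        y = 0.4 * dos[:, 1] + cov @ [0.5, -0.2] + rng.standard_normal(n)
        res = bw.gwas_linear(panel, y, cov)
        for j in range(m):
            X = sm.add_constant(np.column_stack([dos[:, j], cov]))
            fit = sm.OLS(y, X).fit()
            assert res["beta"].iloc[j] == pytest.approx(fit.params[1], abs=1e-10)
            assert res["se"].iloc[j] == pytest.approx(fit.bse[1], abs=1e-10)
            assert res["p"].iloc[j] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_six_individual_toy_closed_form(self):
        """Tiny closed-form case: one covariate, six individuals."""
        dos = np.array([[0.0], [1], [2], [0], [1], [2]])
        cov = np.array([[1.0], [0], [1], [0], [1], [0]])
        y = np.array([0.1, 0.9, 2.2, -0.1, 1.3, 1.8])
        panel = _panel_from_matrix(dos)
        res = bw.gwas_linear(panel, y, cov)
        X = sm.add_constant(np.column_stack([dos[:, 0], cov]))
        fit = sm.OLS(y, X).fit()
        assert res["beta"].iloc[0] == pytest.approx(fit.params[1], abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_monomorphic_flagged_not_dropped(self):
        dos = np.column_stack([np.ones(30), np.random.default_rng(1).integers(0, 3, 30)])
        panel = _panel_from_matrix(dos)
        y = np.random.default_rng(2).standard_normal(30)
        res = bw.gwas_linear(panel, y)
        assert len(res) == 2
        assert np.isnan(res["beta"].iloc[0]) and res["reason"].iloc[0] == "monomorphic"

    def test_rank_deficient_covariates(self):
        dos = np.random.default_rng(3).integers(0, 3, (30, 2)).astype(float)
        panel = _panel_from_matrix(dos)
        cov = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError):
            bw.gwas_linear(panel, np.zeros(30), cov)

    def test_frisch_waugh_identity(self, small_study):
        """GWAS on adjusted BAG equals GWAS on raw BAG with the covariates
        in the model (same t-statistics to 1e-6) up to the df bookkeeping of
        pre-residualized covariates."""
        panel, cohort, _ = small_study
        cov = cohort.covariates()
        pred = cohort.age + cohort.bag_true
        bag = bw.compute_bag(pred, cohort.age, cov)
        res_model = bw.gwas_linear(panel, bag["bag_raw"].to_numpy(), cov)
        res_adj = bw.gwas_linear(panel, bag["bag_adj"].to_numpy(), cov)
        np.testing.assert_allclose(res_adj["z"], res_model["z"], atol=1e-6)


class TestIvwMeta:
    def _table(self, beta, se, freq=0.3, n=1000, a1="A", a2="G"):
        return pd.DataFrame({
            "chrom": "1", "pos": [100], "id": ["rs1"], "a1": a1, "a2": a2,
            "freq_a1": freq, "beta": beta, "se": se, "z": beta / se,
            "p": 1e-4, "n": n,
        })

    def test_duplicate_study(self):
        meta, _ = bw.ivw_meta([self._table(0.1, 0.1), self._table(0.1, 0.1)],
                              apply_filters=False)
        assert meta["beta"].iloc[0] == pytest.approx(0.1)
        assert meta["se"].iloc[0] == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_computed_ivw(self):
        """b = (0.1/0.01 + 0.3/0.04)/(1/0.01 + 1/0.04) = 0.14,
        se = (1/0.01 + 1/0.04)^(-1/2) = 0.089443."""
        meta, _ = bw.ivw_meta([self._table(0.1, 0.1), self._table(0.3, 0.2)],
                              apply_filters=False)
        assert meta["beta"].iloc[0] == pytest.approx(0.14, abs=1e-12)
        assert meta["se"].iloc[0] == pytest.approx(0.0894427191, abs=1e-9)

    def test_allele_swap_invariance(self):
        swapped = self._table(-0.3, 0.2, freq=0.7, a1="G", a2="A")
        meta1, _ = bw.ivw_meta([self._table(0.1, 0.1), self._table(0.3, 0.2)],
                               apply_filters=False)
        meta2, _ = bw.ivw_meta([self._table(0.1, 0.1), swapped], apply_filters=False)
        assert meta1["beta"].iloc[0] == pytest.approx(meta2["beta"].iloc[0])
        assert meta1["se"].iloc[0] == pytest.approx(meta2["se"].iloc[0])

    def test_self_meta_reproduces_z(self, small_study, small_gwas):
        """Meta of a cohort with itself (halved n) reproduces the
        single-cohort z within floating tolerance."""
        t = small_gwas.dropna(subset=["beta"]).copy()
        half = t.copy()
        half["n"] = t["n"] // 2
        half["se"] = t["se"] * np.sqrt(2)  # half the sample, sqrt(2) the SE
        meta, _ = bw.ivw_meta([half, half], apply_filters=False)
        merged = meta.merge(t, on=["chrom", "pos"], suffixes=("_m", ""))
        np.testing.assert_allclose(merged["beta_m"], merged["beta"], rtol=1e-10)
        np.testing.assert_allclose(merged["z_m"], merged["z"], rtol=1e-6)

    def test_filters_applied(self):
        t1 = pd.DataFrame({
            "chrom": "1", "pos": [100, 200], "id": ["rs1", "rs2"], "a1": "A",
            "a2": "G", "freq_a1": 0.3, "beta": [0.1, 0.1], "se": [0.02, 0.02],
            "z": 5.0, "p": 1e-6, "n": [1000, 100],
        })
        t2 = t1.copy()
        t2.loc[0, "beta"] = -0.3  # gross heterogeneity at rs1
        meta, excluded = bw.ivw_meta([t1, t2])
        assert set(excluded["reason"]) <= {"low_n", "heterogeneity"}
        assert len(excluded) == 2 and len(meta) == 0


class TestStepwiseConditional:
    def test_single_causal_ld_free(self):
        rng = np.random.default_rng(5)
        n, m = 3000, 20
        dos = rng.binomial(2, 0.3, (n, m)).astype(float)
        panel = _panel_from_matrix(dos)
        y = 0.3 * dos[:, 7] + rng.standard_normal(n)
        ss = bw.gwas_linear(panel, y)
        sel = bw.stepwise_conditional(ss, panel, y)
        assert sel["id"].tolist() == ["rs8"]
        assert sel["beta_c"].iloc[0] == pytest.approx(sel["beta"].iloc[0], abs=1e-12)
        assert sel["p_c"].iloc[0] == pytest.approx(sel["p"].iloc[0], abs=1e-12)

    @staticmethod
    def _ld_pair(rng, n, r_latent=0.55):
        z1 = rng.standard_normal(n)
        z2 = r_latent * z1 + np.sqrt(1 - r_latent**2) * rng.standard_normal(n)
        x1 = (z1 > 0).astype(float) + (rng.standard_normal(n) * 0.4 + z1 > 0)
        x2 = (z2 > 0).astype(float) + (rng.standard_normal(n) * 0.4 + z2 > 0)
        return x1, x2

    def test_two_masked_causals_joint_betas_match_ols(self):
        """Opposite-sign causals in LD mask each other marginally; the
        stepwise conditional analysis recovers both and the joint betas
        equal a full two-variant OLS oracle."""
        rng = np.random.default_rng(6)
        n = 4000
        x1, x2 = self._ld_pair(rng, n)
        dos = np.column_stack([x1, x2, rng.binomial(2, 0.3, (n, 3))]).astype(float)
        panel = _panel_from_matrix(dos)
        y = 0.25 * x1 - 0.25 * x2 + rng.standard_normal(n)
        r2 = panel.ld_r(0, 1) ** 2
        assert 0.1 < r2 < 0.7
        ss = bw.gwas_linear(panel, y)
        sel = bw.stepwise_conditional(ss, panel, y)
        assert set(sel["id"]) == {"rs1", "rs2"}
        X = sm.add_constant(dos[:, :2])
        fit = sm.OLS(y, X).fit()
        for vid, coef in zip(["rs1", "rs2"], fit.params[1:]):
            got = sel.loc[sel["id"] == vid, "beta_c"].iloc[0]
            assert got == pytest.approx(coef, abs=1e-8)

    def test_shadowed_secondary_dropped_by_magnitude_rule(self):
        """A same-sign secondary in strong LD sees its conditional p degrade
        by far more than two orders of magnitude relative to its marginal p
        and is therefore not reported as independent."""
        rng = np.random.default_rng(6)
        n = 4000
        x1, x2 = self._ld_pair(rng, n)
        dos = np.column_stack([x1, x2, rng.binomial(2, 0.3, (n, 3))]).astype(float)
        panel = _panel_from_matrix(dos)
        y = 0.25 * x1 + 0.25 * x2 + rng.standard_normal(n)
        ss = bw.gwas_linear(panel, y)
        sel = bw.stepwise_conditional(ss, panel, y)
        assert len(sel) == 1

    def test_no_significant_variants_empty(self):
        rng = np.random.default_rng(7)
        dos = rng.binomial(2, 0.3, (500, 10)).astype(float)
        panel = _panel_from_matrix(dos)
        y = rng.standard_normal(500)
        ss = bw.gwas_linear(panel, y)
        sel = bw.stepwise_conditional(ss, panel, y)
        assert len(sel) == 0

    def test_empty_input_empty_output(self):
        dos = np.random.default_rng(8).binomial(2, 0.3, (100, 2)).astype(float)
        panel = _panel_from_matrix(dos)
        empty = bw.gwas_linear(panel, np.random.default_rng(9).standard_normal(100)).iloc[:0]
        sel = bw.stepwise_conditional(empty, panel, np.zeros(100))
        assert len(sel) == 0


class TestClump:
    def _iv(self, ids, pos, p, trait="bag"):
        return pd.DataFrame({"id": ids, "chrom": "1", "pos": pos, "p": p, "trait": trait})

    def test_independent_variants_one_locus_each(self):
        rng = np.random.default_rng(10)
        dos = rng.binomial(2, 0.3, (2000, 3)).astype(float)
        panel = _panel_from_matrix(dos)
        iv = self._iv(["rs1", "rs2", "rs3"], [1000, 2000, 3000], [1e-9, 1e-8, 1e-7])
        loci = bw.clump_and_flag(iv, panel)
        assert len(loci) == 3

    def test_correlated_variants_single_locus_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        n = 2000
        z = rng.standard_normal(n)
        dos = np.column_stack([
            (z + 0.3 * rng.standard_normal(n) > 0).astype(float) * 2,
            (z + 0.3 * rng.standard_normal(n) > 0).astype(float) * 2,
            (z + 0.3 * rng.standard_normal(n) > 0).astype(float) * 2,
        ])
        panel = _panel_from_matrix(dos)
        for i in range(3):
            for j in range(i + 1, 3):
                assert panel.ld_r(i, j) ** 2 > 0.5
        p = [1e-8, 1e-10, 1e-9]
        iv = self._iv(["rs1", "rs2", "rs3"], [1000, 2000, 3000], p)
        loci = bw.clump_and_flag(iv, panel)
        assert len(loci) == 1
        assert loci["lead_id"].iloc[0] == "rs2"  # smallest p leads
        # brute-force oracle: any processing order merges all three
        assert set(loci["member_ids"].iloc[0].split(",")) == {"rs1", "rs2", "rs3"}

    def test_known_lead_not_novel(self):
        rng = np.random.default_rng(12)
        dos = rng.binomial(2, 0.3, (2000, 2)).astype(float)
        panel = _panel_from_matrix(dos)
        iv = self._iv(["rs1"], [1000], [1e-9])
        known = pd.DataFrame({"id": ["rs1"]})
        loci = bw.clump_and_flag(iv, panel, known_list=known)
        assert not loci["novel"].iloc[0]

    def test_unresolvable_known_entry_warns(self):
        rng = np.random.default_rng(13)
        dos = rng.binomial(2, 0.3, (500, 2)).astype(float)
        panel = _panel_from_matrix(dos)
        iv = self._iv(["rs1"], [1000], [1e-9])
        known = pd.DataFrame({"id": ["rs_missing"]})
        with pytest.warns(UserWarning):
            loci = bw.clump_and_flag(iv, panel, known_list=known)
        assert loci["novel"].iloc[0]
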