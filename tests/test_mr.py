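"""MR engine: Wald layer, instrument selection, SMR/HEIDI, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bloodmark import mr
from bloodmark.sumstats import LDMatrix
from conftest import identity_ld, make_pairs


class TestWaldLayer:
    @pytest.mark.parametrize("beta_id,beta_im,expected",
                             [(0.04, 0.2, 0.2), (0.0, 0.5, 0.0),
                              (-0.06, 0.3, -0.2)])
    def test_wald_ratio(self, beta_id, beta_im, expected):
        assert mr.wald_ratio(beta_id, beta_im) == pytest.approx(expected)

    def test_zero_instrument_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mr.wald_ratio(0.1, 0.0)
        with pytest.raises(ZeroDivisionError):
            mr.delta_se(0.1, 0.0)

    @pytest.mark.parametrize("se_id,beta_im,expected",
                             [(0.01, 0.2, 0.05), (0.01, -0.2, 0.05)])
    def test_delta_se(self, se_id, beta_im, expected):
        assert mr.delta_se(se_id, beta_im) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(beta_id=st.floats(-2, 2), se_id=st.floats(1e-4, 1),
           beta_im=st.floats(0.01, 2))
    def test_z_identity(self, beta_id, se_id, beta_im):
        """Wald z equals the GWAS z in magnitude (algebraic identity)."""
        z_md = mr.wald_ratio(beta_id, beta_im) / mr.delta_se(se_id, beta_im)
        assert abs(z_md) == pytest.approx(abs(beta_id / se_id), rel=1e-12)


class TestInstrumentSelection:
    def test_no_significant_snp_is_untestable(self):
        pairs = make_pairs([0.5, 0.4], [0.1, 0.1], p_qtl=[1e-6, 1e-4])
        assert mr.select_cis_instruments(pairs, 1000, identity_ld(2)) == []

    def test_prune_keeps_smaller_p(self):
        pairs = make_pairs([0.5, 0.4], [0.1, 0.1], p_qtl=[1e-10, 1e-9])
        ld = LDMatrix(["rs0", "rs1"],
                      np.array([[1.0, np.sqrt(0.95)], [np.sqrt(0.95), 1.0]]))
        assert mr.select_cis_instruments(pairs, 1000, ld) == ["rs0"]

    def test_independent_significant_all_kept(self):
        pairs = make_pairs([0.5] * 5, [0.1] * 5, p_qtl=[1e-10] * 5)
        kept = mr.select_cis_instruments(pairs, 1000, identity_ld(5))
        assert sorted(kept) == [f"rs{i}" for i in range(5)]

    def test_cis_window_excludes_distal(self):
        pairs = make_pairs([0.5, 0.5], [0.1, 0.1], p_qtl=[1e-10, 1e-10])
        pairs.loc[1, "pos"] = 3_000_000
        kept = mr.select_cis_instruments(pairs, 1000, identity_ld(2))
        assert kept == ["rs0"]

    def test_genomewide_clumping(self):
        table = pd.DataFrame({
            "snp": ["a", "b", "c"], "chrom": ["1", "1", "2"],
            "pos": [1_000_000, 1_500_000, 1_200_000],
            "p": [1e-8, 1e-6, 1e-7]})
        kept = mr.select_genomewide_instruments(table)
        # b is within 1 Mb of a (clumped away); c is on another chromosome
        assert sorted(kept) == ["a", "c"]

    def test_genomewide_all_weak_untestable(self):
        table = pd.DataFrame({"snp": ["a"], "chrom": ["1"], "pos": [1],
                              "p": [1e-4]})
        assert mr.select_genomewide_instruments(table) == []


class TestSmrMulti:
    def test_single_instrument_reduction_exact(self):
        pairs = make_pairs([0.4], [0.08], se_gwas=[0.02])
        a = mr.smr_multi(pairs, identity_ld(1))
        w = mr.wald_estimates(pairs).iloc[0]
        assert a.beta_md == pytest.approx(w["beta_md"], rel=1e-12)
        assert a.se_md == pytest.approx(w["se_md"], rel=1e-12)
        expected_p = 2 * stats.norm.sf(abs(w["z"]))
        assert a.p_smr == pytest.approx(expected_p, rel=1e-10)

    def test_four_equal_z_independent_combine_to_double(self):
        """k equal-z independent instruments: combined z = z * sqrt(k)."""
        pairs = make_pairs([0.5] * 4, [0.01] * 4, se_gwas=[0.005] * 4)
        a = mr.smr_multi(pairs, identity_ld(4))
        z_each = 0.01 / 0.005
        expected_p = 2 * stats.norm.sf(z_each * 2.0)  # combined z = 4
        assert a.p_smr == pytest.approx(expected_p, rel=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(0.2, 5.0))
    def test_scale_equivariance(self, c):
        """Scaling all beta_im by c scales beta_md by 1/c, p unchanged."""
        pairs = make_pairs([0.5, 0.3, 0.4], [0.05, 0.02, 0.03],
                           se_gwas=[0.01, 0.01, 0.01])
        base = mr.smr_multi(pairs, identity_ld(3))
        scaled_pairs = pairs.copy()
        scaled_pairs["beta_qtl"] *= c
        scaled = mr.smr_multi(scaled_pairs, identity_ld(3))
        assert scaled.beta_md == pytest.approx(base.beta_md / c, rel=1e-9)
        assert scaled.p_smr == pytest.approx(base.p_smr, rel=1e-9)

    def test_heidi_flag_assignment(self):
        a = mr.MarkerAssociation("m", "d", "RNA", 0.1, 0.05, 0.01, 1, "smr_multi")
        assert a.set_heidi(0.2).heidi_flag == "+"
        assert a.set_heidi(0.05).heidi_flag == "-"  # boundary counts as minus
        assert a.set_heidi(None).heidi_flag == "untested"


class TestHeidi:
    def _ld_ar1(self, k, rho):
        idx = np.arange(k)
        r = rho ** np.abs(idx[:, None] - idx[None, :])
        return LDMatrix([f"rs{i}" for i in range(k)], r)

    def test_identical_ratios_give_p_near_one(self):
        ld = self._ld_ar1(6, 0.8)
        b_im = np.array([0.5, 0.45, 0.4, 0.35, 0.3, 0.25])
        pairs = make_pairs(b_im, b_im * 0.2, se_qtl=[0.01] * 6,
                           se_gwas=[0.01] * 6,
                           p_qtl=[1e-12, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6])
        p = mr.heidi_test(pairs, ld)
        assert p is not None and p > 0.99

    def test_too_few_test_snps_untested(self):
        pairs = make_pairs([0.5, 0.4], [0.1, 0.08])
        assert mr.heidi_test(pairs, self._ld_ar1(2, 0.6)) is None

    def test_snps_outside_r2_window_excluded(self):
        # all non-top SNPs nearly collinear with the top -> untestable
        ld = self._ld_ar1(5, 0.99)
        pairs = make_pairs([0.5] * 5, [0.1] * 5,
                           p_qtl=[1e-12] + [1e-8] * 4)
        assert mr.heidi_test(pairs, ld) is None


class TestTwoSampleTools:
    def test_ivw_equal_weights(self):
        w = mr.wald_estimates(make_pairs([1.0, 1.0], [0.2, 0.2],
                                         se_gwas=[0.1, 0.1]))
        a = mr.ivw_estimate(w)
        assert a.beta_md == pytest.approx(0.2, rel=1e-12)
        assert a.se_md == pytest.approx(0.1 / np.sqrt(2), rel=1e-10)

    def test_ivw_single_estimate_unchanged(self):
        w = mr.wald_estimates(make_pairs([1.0], [0.3], se_gwas=[0.05]))
        a = mr.ivw_estimate(w)
        assert a.beta_md == pytest.approx(0.3)
        assert a.se_md == pytest.approx(0.05)

    def test_cochran_q_identical_estimates(self):
        w = mr.wald_estimates(make_pairs([1.0] * 3, [0.2] * 3))
        q, df, p = mr.cochran_q(w)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_cochran_q_hand_case(self):
        """Estimates 0 +/- 1 and 2 +/- 1: pooled 1, Q = 1 + 1 = 2."""
        w = mr.wald_estimates(make_pairs([1.0, 1.0], [0.0, 2.0],
                                         se_gwas=[1.0, 1.0]))
        q, df, p = mr.cochran_q(w)
        assert q == pytest.approx(2.0, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-10)

    def test_cochran_q_null_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(1_000):
            b = rng.normal(0.3, 0.05, size=5)
            w = pd.DataFrame({"snp": [f"rs{i}" for i in range(5)],
                              "beta_md": b, "se_md": 0.05})
            ps.append(mr.cochran_q(w)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_stepwise_homogeneous_untouched(self):
        w = mr.wald_estimates(make_pairs([1.0] * 4, [0.2] * 4,
                                         se_gwas=[0.05] * 4))
        kept, audit = mr.stepwise_outlier_removal(w)
        assert len(kept) == 4 and audit == []

    def test_stepwise_removes_planted_outlier_first(self):
        betas = [0.2, 0.2, 0.2, 0.2, 0.2 + 10 * 0.05]
        w = mr.wald_estimates(make_pairs([1.0] * 5, betas,
                                         se_gwas=[0.05] * 5))
        kept, audit = mr.stepwise_outlier_removal(w)
        assert audit[0]["removed"] == "rs4"
        assert "rs4" not in set(kept["snp"])

    def test_stepwise_floor_at_three(self):
        # wildly heterogeneous: removal must still stop at 3 instruments
        w = mr.wald_estimates(make_pairs([1.0] * 5, [0, 1, 2, 3, 4],
                                         se_gwas=[0.01] * 5))
        kept, _ = mr.stepwise_outlier_removal(w)
        assert len(kept) == 3
        assert mr.cochran_q(kept)[2] < 0.05  # heterogeneity remains, by design

    def test_egger_exact_proportionality(self):
        pairs = make_pairs([0.2, 0.4, 0.6, 0.8],
                           [0.1, 0.2, 0.3, 0.4], se_gwas=[0.01] * 4)
        slope, intercept, _ = mr.mr_egger(pairs)
        assert slope == pytest.approx(0.5, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_egger_offset_moves_intercept_not_slope(self):
        """Constant pleiotropic offset: intercept shifts, slope stays 0.5;
        cross-checked against a weighted-least-squares oracle."""
        import statsmodels.api as sm
        x = np.array([0.2, 0.4, 0.6, 0.8])
        y = 0.5 * x + 0.07
        pairs = make_pairs(x, y, se_gwas=[0.01, 0.02, 0.01, 0.03])
        slope, intercept, _ = mr.mr_egger(pairs)
        wls = sm.WLS(y, sm.add_constant(x),
                     weights=1 / np.array([0.01, 0.02, 0.01, 0.03]) ** 2).fit()
        assert slope == pytest.approx(wls.params[1], rel=1e-10)
        assert intercept == pytest.approx(0.07, abs=1e-10)

    def test_egger_requires_three(self):
        with pytest.raises(ValueError):
            mr.mr_egger(make_pairs([0.2, 0.4], [0.1, 0.2]))


class TestMultipleTesting:
    @pytest.mark.parametrize("alpha,n,expected",
                             [(0.05, 41, 0.05 / 41), (0.05, 1, 0.05),
                              (0.05, 119, 0.05 / 119)])
    def test_bonferroni(self, alpha, n, expected):
        assert mr.bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_bonferroni_rejects_zero(self):
        with pytest.raises(ValueError):
            mr.bonferroni_threshold(0.05, 0)

    def test_lambda_identity_on_uniform_order_stats(self):
        n = 500
        p = np.arange(1, n + 1) / (n + 1)
        assert mr.inflation_lambda(p).lam == pytest.approx(1.0, abs=1e-12)

    def test_lambda_two_for_doubled_chi_square(self):
        n = 500
        expected = np.arange(1, n + 1) / (n + 1)
        chi = stats.chi2.isf(expected, 1)
        p_obs = stats.chi2.sf(2 * chi, 1)
        assert mr.inflation_lambda(p_obs).lam == pytest.approx(2.0, abs=1e-10)

    def test_lambda_uniform_monte_carlo(self):
        rng = np.random.default_rng(5)
        rep = mr.inflation_lambda(rng.uniform(size=10_000))
        assert 0.95 <= rep.lam <= 1.05

    def test_lambda_low_confidence_flag(self):
        rep = mr.inflation_lambda([0.2, 0.5, 0.8])
        assert rep.low_confidence


class TestEnrichment:
    def test_balanced_table_no_association(self):
        # 10 of 20 markers inside, 10 of 20 background inside -> OR 1, p 1
        markers = list(range(10)) + list(range(100, 110))
        background = markers
        odds, p = mr.characterize_enrichment(markers, [(0, 50)], background)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_fisher_p_enumeration_oracle(self):
        """Two-sided Fisher p for (8,2 / 2,8) via hypergeometric enumeration."""
        table = np.array([[8, 2], [2, 8]])
        n, k1, k2 = table.sum(), table[0].sum(), table[:, 0].sum()
        probs = [stats.hypergeom.pmf(a, n, k1, k2)
                 for a in range(max(0, k1 + k2 - n), min(k1, k2) + 1)]
        p_obs = stats.hypergeom.pmf(8, n, k1, k2)
        oracle = sum(pr for pr in probs if pr <= p_obs * (1 + 1e-9))
        _, p = stats.fisher_exact(table)
        assert p == pytest.approx(oracle, rel=1e-9)
        # and the package op reproduces OR = 16 on an equivalent layout
        mk = list(range(8)) + [200, 201]
        bg = list(range(2)) + list(range(200, 208))
        odds, p_op = mr.characterize_enrichment(mk, [(0, 100)], bg)
        assert odds == pytest.approx(16.0)
        assert p_op == pytest.approx(oracle, rel=1e-9)

    def test_marker_set_equals_background(self):
        markers = list(range(5)) + [1000]
        odds, p = mr.characterize_enrichment(markers, [(0, 10)], markers)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            mr.characterize_enrichment([1], [(0, 10)], [])
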