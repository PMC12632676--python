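"""MR estimators: exact oracles, calibration, invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from renalmr.instruments import InstrumentSet
from renalmr.mr import MRResult, cochran_q, egger, heterogeneity_z, ivw_mre, run_mr, wald_ratio


def make_inst(b_exp, se_exp, b_out, se_out, pid="P", label="d"):
    k = len(b_exp)
    return InstrumentSet(pid, label, pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(k)],
        "beta_exp": b_exp, "se_exp": se_exp,
        "beta_out": b_out, "se_out": se_out,
        "eaf": [0.3] * k, "proxy_used": [False] * k,
    }))


class TestWald:
    def test_direct_ratio(self):
        r = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.04)

    def test_zero_outcome_effect(self):
        r = wald_ratio(0.5, 0.05, 0.0, 0.02)
        assert r.beta == 0.0
        assert r.pvalue == pytest.approx(1.0)

    def test_orientation_invariance(self):
        a = wald_ratio(0.5, 0.05, 0.1, 0.02)
        b = wald_ratio(-0.5, 0.05, -0.1, 0.02)
        assert (a.beta, a.se, a.pvalue) == (b.beta, b.se, b.pvalue)

    def test_zero_exposure_effect_undefined(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.05, 0.1, 0.02)


class TestIVW:
    def test_two_identical_snps_equal_single_wald(self):
        inst = make_inst([0.5, 0.5], [0.05, 0.05], [0.1, 0.1], [0.02, 0.02])
        r = ivw_mre(inst)
        w = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert r.beta == pytest.approx(w.beta)
        assert r.cochran_Q == pytest.approx(0.0, abs=1e-12)

    def test_single_snp_path_equals_wald(self):
        inst = make_inst([0.4], [0.05], [0.12], [0.03])
        r = run_mr(inst)
        w = wald_ratio(0.4, 0.05, 0.12, 0.03)
        assert r.method == "wald"
        assert r.beta == pytest.approx(w.beta) and r.se == pytest.approx(w.se)

    def test_matches_wls_oracle(self):
        """3-SNP fixture vs brute-force weighted least squares through the
        origin (statsmodels WLS), to 1e-10."""
        b_exp = np.array([0.5, 0.3, 0.8])
        b_out = np.array([0.11, 0.07, 0.21])
        se_out = np.array([0.02, 0.05, 0.03])
        inst = make_inst(b_exp, [0.05] * 3, b_out, se_out)
        r = ivw_mre(inst)
        fit = sm.WLS(b_out, b_exp[:, None], weights=1.0 / se_out**2).fit()
        assert r.beta == pytest.approx(fit.params[0], abs=1e-10)
        # fixed-effect SE from the WLS normal equations, MRE-scaled
        se_fixed = 1.0 / np.sqrt(np.sum(b_exp**2 / se_out**2))
        ratios = b_out / b_exp
        w_ratio = (b_exp / se_out) ** 2
        Q = np.sum(w_ratio * (ratios - r.beta) ** 2)
        assert r.cochran_Q == pytest.approx(Q, abs=1e-12)
        assert r.se == pytest.approx(se_fixed * np.sqrt(max(1, Q / 2)), abs=1e-10)

    def test_sign_flip_invariance(self):
        b_exp = np.array([0.5, -0.3, 0.8])
        b_out = np.array([0.11, -0.07, 0.21])
        se_out = np.array([0.02, 0.05, 0.03])
        r1 = ivw_mre(make_inst(b_exp, [0.05] * 3, b_out, se_out))
        flip = np.array([1, -1, -1.0])
        r2 = ivw_mre(make_inst(b_exp * flip, [0.05] * 3, b_out * flip, se_out))
        assert r2.beta == pytest.approx(r1.beta, abs=1e-12)
        assert r2.se == pytest.approx(r1.se, abs=1e-12)

    def test_mre_floor_never_shrinks_below_fixed_effect(self):
        # homogeneous data: Q/(k-1) < 1 must not deflate the SE
        inst = make_inst([0.5, 0.5, 0.5], [0.05] * 3, [0.1, 0.1001, 0.0999], [0.02] * 3)
        r = ivw_mre(inst)
        se_fixed = 1.0 / np.sqrt(np.sum(np.array([0.5] * 3) ** 2 / 0.02**2))
        assert r.se >= se_fixed - 1e-15

    def test_parameter_recovery_with_valid_instruments(self):
        """10 independent instruments, true effect 0.25, two-sample GWAS of
        n=50,000 each: the IVW estimate recovers the effect within 3 SE."""
        res = _two_sample_sim(seed=41)
        assert abs(res.beta - 0.25) < 3 * res.se


def _two_sample_sim(seed, n=50_000, m=10, true_effect=0.25):
    from renalmr.assoc import scan_quantitative
    from conftest import make_variants

    rng = np.random.default_rng(seed)
    variants = make_variants(m)
    alphas = rng.uniform(0.1, 0.3, size=m)

    def one_gwas(rng):
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        u = rng.standard_normal(n)
        prot = G @ alphas + 0.5 * u + rng.standard_normal(n)
        y = true_effect * prot + 0.5 * u + rng.standard_normal(n)
        return G, prot, y

    G1, prot1, _ = one_gwas(rng)
    G2, _, y2 = one_gwas(rng)
    exp_ss = scan_quantitative(prot1, G1, None, variants)
    out_ss = scan_quantitative(y2, G2, None, variants)
    inst = make_inst(
        exp_ss.records["beta"].to_numpy(), exp_ss.records["se"].to_numpy(),
        out_ss.records["beta"].to_numpy(), out_ss.records["se"].to_numpy(),
    )
    return ivw_mre(inst)


class TestEgger:
    def test_known_offset_recovered(self):
        rng = np.random.default_rng(42)
        k = 50
        b_exp = rng.uniform(0.2, 0.6, size=k)
        se_out = np.full(k, 0.01)
        b_out = 0.05 + 0.2 * b_exp + rng.normal(0, 0.01, size=k)
        intercept, slope, int_se = egger(make_inst(b_exp, [0.05] * k, b_out, se_out))
        assert intercept == pytest.approx(0.05, abs=3 * int_se)
        assert slope == pytest.approx(0.2, abs=0.05)

    def test_no_pleiotropy_intercept_near_zero(self):
        rng = np.random.default_rng(43)
        k = 30
        b_exp = rng.uniform(0.2, 0.6, size=k)
        se_out = np.full(k, 0.02)
        b_out = 0.25 * b_exp + rng.normal(0, 0.02, size=k)
        intercept, _, int_se = egger(make_inst(b_exp, [0.05] * k, b_out, se_out))
        assert abs(intercept) < 2 * int_se + 0.01

    def test_matches_wls_oracle(self):
        b_exp = np.array([0.5, 0.3, 0.8, 0.4])
        b_out = np.array([0.13, 0.08, 0.20, 0.10])
        se_out = np.array([0.02, 0.05, 0.03, 0.04])
        intercept, slope, _ = egger(make_inst(b_exp, [0.05] * 4, b_out, se_out))
        X = sm.add_constant(b_exp)
        fit = sm.WLS(b_out, X, weights=1.0 / se_out**2).fit()
        assert intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert slope == pytest.approx(fit.params[1], abs=1e-10)

    def test_two_snps_undefined(self):
        with pytest.raises(ValueError):
            egger(make_inst([0.5, 0.3], [0.05] * 2, [0.1, 0.07], [0.02] * 2))


class TestCochranQ:
    def test_identical_ratios_q_zero(self):
        inst = make_inst([0.5, 0.25], [0.05] * 2, [0.1, 0.05], [0.02, 0.01])
        Q, df, p = cochran_q(inst)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_outlier_rejected(self):
        # third ratio sits 10 SE away from the consensus
        inst = make_inst([0.5, 0.5, 0.5], [0.05] * 3,
                         [0.10, 0.10, 0.10 + 10 * 0.02], [0.02] * 3)
        _, _, p = cochran_q(inst)
        assert p < 1e-6

    def test_null_q_pvalues_uniform(self):
        """Homogeneous simulated ratios give uniform Q p-values (KS test)."""
        rng = np.random.default_rng(44)
        pvals = []
        for _ in range(1000):
            k = 6
            b_exp = rng.uniform(0.3, 0.6, size=k)
            se_out = rng.uniform(0.01, 0.03, size=k)
            b_out = 0.2 * b_exp + rng.normal(0, se_out)
            _, _, p = cochran_q(make_inst(b_exp, [0.05] * k, b_out, se_out))
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestHeterogeneityZ:
    def test_identical_estimates(self):
        a = MRResult("p", "o", "wald", 0.3, 0.05, 0.01, 1)
        z, p = heterogeneity_z(a, a)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_normal_cdf_oracle(self):
        a = MRResult("p", "o", "wald", 0.3, 0.05, 1e-9, 1)
        b = MRResult("p", "o", "wald", 0.0, 0.05, 1.0, 1)
        z, p = heterogeneity_z(a, b)
        assert z == pytest.approx(0.3 / np.sqrt(2 * 0.05**2), abs=1e-12)
        assert z == pytest.approx(4.2426, abs=1e-3)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)
        assert p == pytest.approx(2.2e-5, rel=0.05)

    def test_threshold_comparison(self):
        cutoff = 0.05 / 93
        assert not (6e-4 < cutoff)  # 6e-4 misses the 0.05/93 bar


class TestConfoundingRobustness:
    def test_ivw_unbiased_where_observational_slope_is_biased(self):
        """With a confounder on both protein and outcome, the naive
        regression is biased but genetic instruments stay valid."""
        rng = np.random.default_rng(45)
        n, m, true_effect = 4000, 6, 0.25
        reps = 60
        ivw_est, naive_est = [], []
        from renalmr.assoc import scan_quantitative
        from conftest import make_variants

        variants = make_variants(m)
        alphas = rng.uniform(0.2, 0.4, size=m)
        for _ in range(reps):
            G1 = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            u1 = rng.standard_normal(n)
            prot1 = G1 @ alphas + 0.8 * u1 + rng.standard_normal(n)
            G2 = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            u2 = rng.standard_normal(n)
            prot2 = G2 @ alphas + 0.8 * u2 + rng.standard_normal(n)
            y2 = true_effect * prot2 + 0.8 * u2 + rng.standard_normal(n)
            ess = scan_quantitative(prot1, G1, None, variants)
            oss = scan_quantitative(y2, G2, None, variants)
            inst = make_inst(ess.records["beta"].to_numpy(), ess.records["se"].to_numpy(),
                             oss.records["beta"].to_numpy(), oss.records["se"].to_numpy())
            ivw_est.append(ivw_mre(inst).beta)
            naive_est.append(np.polyfit(prot2, y2, 1)[0])
        ivw_bias = np.mean(ivw_est) - true_effect
        naive_bias = np.mean(naive_est) - true_effect
        mc_se = np.std(ivw_est, ddof=1) / np.sqrt(reps)
        assert abs(ivw_bias) < 3 * mc_se
        assert naive_bias > 10 * mc_se  # confounding inflates the naive slope
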