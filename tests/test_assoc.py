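"""Association engine: exactness vs statsmodels, calibration, equivariance."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from renalmr.assoc import scan_binary, scan_quantitative, stratified_scan
from renalmr.config import SimulationConfig
from renalmr.simulate import simulate_genotypes

from conftest import make_variants


def _sim_data(rng, n=500, m=3, binary=False, beta=0.0):
    G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    C = rng.standard_normal((n, 2))
    lin = beta * G[:, 0] + 0.5 * C[:, 0] - 0.3 * C[:, 1]
    if binary:
        p = 1 / (1 + np.exp(-(-0.5 + lin)))
        y = (rng.uniform(size=n) < p).astype(float)
    else:
        y = lin + rng.standard_normal(n)
    return y, G, C


class TestQuantitative:
    def test_matches_statsmodels_ols(self, rng):
        y, G, C = _sim_data(rng, beta=0.4)
        res = scan_quantitative(y, G, C, make_variants(3))
        for j in range(3):
            X = sm.add_constant(np.column_stack([C, G[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert res.records["beta"][j] == pytest.approx(fit.params[-1], abs=1e-10)
            assert res.records["se"][j] == pytest.approx(fit.bse[-1], abs=1e-10)

    def test_pvalue_consistent_with_z(self, rng):
        y, G, C = _sim_data(rng, beta=0.2)
        res = scan_quantitative(y, G, C, make_variants(3))
        z = res.records["beta"] / res.records["se"]
        np.testing.assert_allclose(res.records["pvalue"], 2 * stats.norm.sf(np.abs(z)),
                                   rtol=1e-8)

    def test_null_type_one_error_calibrated(self):
        cfg = SimulationConfig(n_individuals=2000, n_variants_region=2000,
                               ld_decay=0.0, maf_range=(0.1, 0.5), seed=31)
        G, variants = simulate_genotypes(cfg)
        rng = np.random.default_rng(32)
        y = rng.standard_normal(2000)
        res = scan_quantitative(y, G, None, variants)
        frac = float((res.records["pvalue"] < 0.05).mean())
        mc_se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 2 * mc_se + 1e-9

    def test_injected_effect_recovered(self):
        cfg = SimulationConfig(n_individuals=20_000, n_variants_region=3,
                               ld_decay=0.0, maf_range=(0.3, 0.3), seed=33)
        G, variants = simulate_genotypes(cfg)
        rng = np.random.default_rng(34)
        y = 0.3 * G[:, 1] + rng.standard_normal(20_000)
        res = scan_quantitative(y, G, None, variants)
        assert abs(res.records["beta"][1] - 0.3) < 3 * res.records["se"][1]

    def test_constant_trait_flagged_degenerate(self, rng):
        _, G, C = _sim_data(rng)
        res = scan_quantitative(np.ones(len(G)), G, C, make_variants(3))
        assert (res.records["beta"] == 0).all()
        assert res.records["pvalue"].isna().all()
        assert res.records.attrs["degenerate"].all()

    def test_standardized_beta_equals_partial_correlation(self, rng):
        y, G, C = _sim_data(rng, n=400, beta=0.3)
        g = G[:, 0]

        def resid(v):
            X = sm.add_constant(C)
            return v - X @ np.linalg.lstsq(X, v, rcond=None)[0]

        ry, rg = resid(y), resid(g)
        partial_r = np.corrcoef(ry, rg)[0, 1]
        ys = (y - y.mean()) / y.std(ddof=0)
        gs = (g - g.mean()) / g.std(ddof=0)
        res = scan_quantitative(ys, gs[:, None], C, make_variants(1))
        # OLS beta on standardized scales differs from the partial r only by
        # the ratio of residual scalings
        assert res.records["beta"][0] == pytest.approx(
            partial_r * np.sqrt((ry @ ry) / (rg @ rg)) / (y.std(ddof=0) / g.std(ddof=0)),
            abs=1e-10,
        )

    def test_collinear_covariate_dropped_with_warning(self, rng):
        y, G, C = _sim_data(rng)
        C2 = np.column_stack([C, C[:, 0] * 2.0])
        with pytest.warns(UserWarning, match="collinear"):
            res = scan_quantitative(y, G, C2, make_variants(3))
        clean = scan_quantitative(y, G, C, make_variants(3))
        np.testing.assert_allclose(res.records["beta"], clean.records["beta"], atol=1e-10)


class TestBinary:
    def test_matches_statsmodels_logit(self, rng):
        y, G, C = _sim_data(rng, n=800, binary=True, beta=0.4)
        res = scan_binary(y, G, C, make_variants(3))
        for j in range(3):
            X = sm.add_constant(np.column_stack([C, G[:, j]]))
            fit = sm.Logit(y, X).fit(disp=0)
            assert res.records["beta"][j] == pytest.approx(fit.params[-1], abs=1e-6)
            assert res.records["se"][j] == pytest.approx(fit.bse[-1], abs=1e-6)

    def test_collapses_to_contingency_log_odds(self, rng):
        # binary 0/1 exposure, no covariates: beta equals log(ad/bc)
        n = 2000
        g = rng.binomial(1, 0.4, size=n).astype(float)
        p = np.where(g == 1, 0.55, 0.45)
        y = (rng.uniform(size=n) < p).astype(float)
        a = np.sum((y == 1) & (g == 1))
        b = np.sum((y == 1) & (g == 0))
        c = np.sum((y == 0) & (g == 1))
        d = np.sum((y == 0) & (g == 0))
        expected = np.log((a * d) / (b * c))
        res = scan_binary(y, g[:, None], None, make_variants(1))
        assert res.records["beta"][0] == pytest.approx(expected, abs=1e-8)

    def test_null_type_one_error_calibrated(self):
        cfg = SimulationConfig(n_individuals=1500, n_variants_region=400,
                               ld_decay=0.0, maf_range=(0.2, 0.5), seed=35)
        G, variants = simulate_genotypes(cfg)
        rng = np.random.default_rng(36)
        y = rng.binomial(1, 0.3, size=1500).astype(float)
        res = scan_binary(y, G, None, variants)
        frac = float((res.records["pvalue"] < 0.05).mean())
        mc_se = np.sqrt(0.05 * 0.95 / 400)
        assert abs(frac - 0.05) < 3 * mc_se + 1e-9

    def test_all_case_input_rejected(self, rng):
        _, G, C = _sim_data(rng)
        with pytest.raises(ValueError):
            scan_binary(np.ones(len(G)), G, C, make_variants(3))

    def test_case_counts_recorded(self, rng):
        y, G, C = _sim_data(rng, binary=True)
        res = scan_binary(y, G, C, make_variants(3))
        assert res.n_case == int(y.sum())
        assert res.n_case + res.n_control == res.n


class TestAlleleFlip:
    @pytest.mark.parametrize("binary", [False, True])
    def test_flip_negates_beta_preserves_se_p(self, rng, binary):
        y, G, C = _sim_data(rng, n=600, binary=binary, beta=0.3)
        v = make_variants(3)
        res = scan_quantitative(y, G, C, v) if not binary else scan_binary(y, G, C, v)
        flipped = 2.0 - G
        vf = v.copy()
        vf["effect_allele"], vf["other_allele"] = v["other_allele"], v["effect_allele"]
        res_f = (scan_quantitative(y, flipped, C, vf) if not binary
                 else scan_binary(y, flipped, C, vf))
        tol = 1e-10 if not binary else 1e-6
        np.testing.assert_allclose(res_f.records["beta"], -res.records["beta"], atol=tol)
        np.testing.assert_allclose(res_f.records["se"], res.records["se"], atol=tol)
        np.testing.assert_allclose(res_f.records["pvalue"], res.records["pvalue"], rtol=1e-6)
        np.testing.assert_allclose(res_f.records["eaf"], 1 - res.records["eaf"], atol=1e-12)


class TestStratified:
    def test_identical_strata_give_identical_estimates(self, rng):
        y, G, C = _sim_data(rng, n=400)
        y2, G2, C2 = np.tile(y, 2), np.tile(G, (2, 1)), np.tile(C, (2, 1))
        stratum = np.repeat([True, False], 400)
        out = stratified_scan(y2, G2, C2, make_variants(3), stratum, min_stratum_n=10)
        np.testing.assert_allclose(out["stratum_true"].records["beta"],
                                   out["stratum_false"].records["beta"], atol=1e-12)

    def test_small_stratum_refused(self, rng):
        y, G, C = _sim_data(rng, n=100)
        stratum = np.zeros(100, dtype=bool)
        stratum[:5] = True
        with pytest.raises(ValueError, match="individuals"):
            stratified_scan(y, G, C, make_variants(3), stratum, min_stratum_n=50)

    def test_empty_stratum_refused(self, rng):
        y, G, C = _sim_data(rng, n=100)
        with pytest.raises(ValueError):
            stratified_scan(y, G, C, make_variants(3), np.zeros(100, dtype=bool))

    def test_stratum_specific_effect_detected_by_heterogeneity(self):
        """A diabetes-only effect produces a significant stratum difference."""
        rng = np.random.default_rng(37)
        n = 8000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        dm = rng.uniform(size=n) < 0.4
        y = np.where(dm, 0.25 * g, 0.0) + rng.standard_normal(n)
        out = stratified_scan(y, g[:, None], None, make_variants(1), dm)
        from renalmr.mr import MRResult, heterogeneity_z

        a = out["stratum_true"].records.iloc[0]
        b = out["stratum_false"].records.iloc[0]
        ra = MRResult("p", "o", "wald", a["beta"], a["se"], a["pvalue"], 1)
        rb = MRResult("p", "o", "wald", b["beta"], b["se"], b["pvalue"], 1)
        z, p = heterogeneity_z(ra, rb)
        assert p < 0.05 / 93
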