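"""Design construction, REML fitting, and the sib-difference oracle."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rge
from rge.decomp import (
    _factor_frames,
    build_design,
    fit_lmm,
    group_center,
    r2_marginal_conditional,
    sib_difference_oracle,
)

from conftest import ONE_TRAIT, null_config, rge_config


class TestGroupCenter:
    def test_pair_and_constant_examples(self):
        dev, mean = group_center([1.0, 3.0], ["f", "f"])
        np.testing.assert_array_equal(dev, [-1.0, 1.0])
        np.testing.assert_array_equal(mean, [2.0, 2.0])
        dev, _ = group_center([2.0, 2.0, 2.0], ["a", "a", "b"])
        np.testing.assert_array_equal(dev, 0.0)

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            group_center([1.0, 2.0], ["a", ""])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(2, 60), st.integers(0, 1000))
    def test_reconstruction_property(self, n, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(n) * 10
        g = rng.integers(0, max(1, n // 3), size=n)
        dev, mean = group_center(v, g)
        assert np.max(np.abs(dev + mean - v)) < 1e-12
        sums = pd.Series(dev).groupby(g).sum()
        assert np.max(np.abs(sums.to_numpy())) < 1e-10


class TestBuildDesign:
    def test_unknown_model_rejected(self, small_cohort):
        _, cohort, _, _ = small_cohort
        with pytest.raises(ValueError, match="unknown model"):
            build_design(6, cohort)

    def test_model2_within_column_mean_zero(self, small_cohort):
        _, cohort, _, _ = small_cohort
        _, X = build_design(2, cohort)
        assert abs(X["PRS_w"].mean()) < 1e-12

    def test_model4_telescoping_identity(self, small_cohort):
        # the printed columns obey c1 + c2 + 2*c3 = PRS exactly
        _, cohort, _, _ = small_cohort
        _, X = build_design(4, cohort)
        total = X["PRS_w"] + X["PRS_bf"] + 2 * X["PRS_br"]
        assert np.max(np.abs(total.to_numpy() - cohort["PRS"].to_numpy())) < 1e-12

    def test_model4_singleton_region_collapses_to_double_centering(self):
        cohort = pd.DataFrame({
            "FID": [0, 0], "IID": [0, 1], "region_current": [5, 5],
            "PRS": [1.0, 3.0], "sex": [0, 1], "age": [50.0, 52.0],
        })
        _, X = build_design(4, cohort)
        # m_k == m_j for a region holding exactly this family
        np.testing.assert_allclose(X["PRS_w"], [1.0 - 4.0, 3.0 - 4.0])

    def test_model5_equals_model2_with_single_region(self, small_cohort):
        _, cohort, _, _ = small_cohort
        one = cohort.copy()
        one["region_current"] = 0
        _, X2 = build_design(2, one)
        with pytest.warns(UserWarning) if False else _nullcontext():
            _, X5 = build_design(5, one)
        # wbar_k is then the (constant) grand mean of deviations = 0
        np.testing.assert_allclose(X5["PRS_wr"], X2["PRS_w"], atol=1e-12)

    def test_singleton_region_warns_in_model5(self):
        cohort = pd.DataFrame({
            "FID": [0, 0, 1, 1], "IID": range(4),
            "region_current": [0, 1, 1, 1],
            "PRS": [1.0, 2.0, 3.0, 4.0], "sex": [0, 1, 0, 1],
            "age": [50.0, 51.0, 52.0, 53.0],
        })
        with pytest.warns(UserWarning, match="single individual"):
            build_design(5, cohort)


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


def _fit(cohort, model_id, trait="pheno_t"):
    spec, X = build_design(model_id, cohort, response=trait)
    fit = fit_lmm(X, cohort[trait].to_numpy(), _factor_frames(cohort, spec), spec=spec)
    return fit, X


class TestFitLmm:
    def test_matches_ols_when_variance_components_zero(self):
        # h2 = 0 kills the sibling genetic covariance, so both true intercept
        # variances are exactly zero and GLS must collapse to OLS
        cfg = null_config(n_families=5000, h2_direct=0.0, var_family=0.0, seed=51)
        traits = [rge.TraitSpec("t", h2=0.0, family_var=0.0)]
        cohort, _, _ = rge.simulate_sibling_cohort(cfg, traits=traits)
        fit, X = _fit(cohort, 4)
        import statsmodels.api as sm

        ols = sm.OLS(cohort["pheno_t"].to_numpy(), sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, atol=1e-6)
        assert fit.vc.get("family", 0.0) < 1e-3
        assert fit.vc.get("region", 0.0) < 1e-3

    def test_duplicating_rows_halves_the_variance_of_estimates(self):
        cfg = null_config(n_families=2000, h2_direct=0.0, var_family=0.0, seed=53)
        cohort, _, _ = rge.simulate_sibling_cohort(
            cfg, traits=[rge.TraitSpec("t", h2=0.0, family_var=0.0)]
        )
        doubled = pd.concat([cohort, cohort.assign(FID=cohort.FID + 10**6)],
                            ignore_index=True)
        f1, _ = _fit(cohort, 2)
        f2, _ = _fit(doubled, 2)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-4)
        ratio = (f2.bse / f1.bse)["PRS_w"]
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_null_phenotype_calibration(self):
        """Estimates stay within +/-3 SE of zero almost always under the null."""
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            n_fam = 250
            fam = np.repeat(np.arange(n_fam), 2)
            cohort = pd.DataFrame({
                "FID": fam, "IID": np.arange(2 * n_fam),
                "region_current": rng.integers(0, 8, size=2 * n_fam),
                "PRS": rng.standard_normal(2 * n_fam),
                "sex": rng.integers(0, 2, size=2 * n_fam),
                "age": rng.uniform(40, 70, size=2 * n_fam),
                "pheno_t": rng.standard_normal(2 * n_fam)
                + rng.standard_normal(n_fam)[fam] * 0.5,
            })
            fit, _ = _fit(cohort, 1)
            if abs(fit.tvalues["PRS"]) <= 3:
                hits += 1
        assert hits / n_rep >= 0.99

    def test_prs_shift_changes_only_intercept(self, small_cohort):
        _, cohort, _, _ = small_cohort
        shifted = cohort.assign(PRS=cohort["PRS"] + 5.0)
        for mid in (1, 2, 3, 4, 5):
            f0, _ = _fit(cohort, mid, trait="pheno_ses")
            f1, _ = _fit(shifted, mid, trait="pheno_ses")
            keep = [ix for ix in f0.params.index if ix != "intercept"]
            np.testing.assert_allclose(
                f0.params[keep], f1.params[keep], rtol=1e-5, atol=1e-7
            )

    def test_within_family_effect_immune_to_family_confounding(self):
        cfg = null_config(n_families=3000, seed=57)
        cohort, _, _ = rge.simulate_sibling_cohort(cfg, traits=ONE_TRAIT)
        f0, _ = _fit(cohort, 2)
        rng = np.random.default_rng(0)
        shift = rng.standard_normal(cohort["FID"].nunique())
        confounded = cohort.assign(
            pheno_t=cohort["pheno_t"].to_numpy()
            + 0.5 * shift[cohort["FID"].to_numpy()]
        )
        f1, _ = _fit(confounded, 2)
        joint_se = np.hypot(f0.bse["PRS_w"], f1.bse["PRS_w"])
        assert abs(f0.params["PRS_w"] - f1.params["PRS_w"]) < 2 * joint_se


class TestAgainstLme4:
    def test_reml_matches_lme4_on_small_fixture(self, tmp_path):
        cfg = rge_config(n_families=300, n_regions=9, n_snps=100, seed=7)
        cohort, _, _ = rge.simulate_sibling_cohort(cfg)
        spec, X = build_design(4, cohort, response="pheno_ses")
        fit = fit_lmm(X, cohort["pheno_ses"].to_numpy(), _factor_frames(cohort, spec))

        df = cohort[["FID", "region_current", "pheno_ses"]].copy()
        for c in X.columns:
            df[c] = X[c].to_numpy()
        csv = tmp_path / "fix.csv"
        df.to_csv(csv, index=False)
        rcode = f"""
        d <- read.csv('{csv}')
        suppressMessages(library(lme4))
        m <- lmer(pheno_ses ~ PRS_w + PRS_bf + PRS_br + sex + age +
                  (1|FID) + (1|region_current), data=d, REML=TRUE)
        co <- fixef(m); vc <- as.data.frame(VarCorr(m))
        cat(co, vc$vcov, sep=',')
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        vals = np.array([float(v) for v in out.stdout.strip().split(",")])
        r_fixef, r_vc = vals[:6], vals[6:]
        np.testing.assert_allclose(
            fit.params[["intercept", "PRS_w", "PRS_bf", "PRS_br", "sex", "age"]],
            r_fixef, rtol=1e-4, atol=1e-6,
        )
        np.testing.assert_allclose(
            [fit.vc["family"], fit.vc["region"], fit.vc["resid"]],
            r_vc, rtol=1e-3, atol=1e-6,
        )


class TestR2:
    def test_trivial_bounds(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.standard_normal(n)
        X = pd.DataFrame({"x": x})
        # perfect fit, no noise: R2m = R2c = 1 (residual variance collapses)
        fit = fit_lmm(X, 2.0 * x, {})
        r2m, r2c = r2_marginal_conditional(fit, X, 2.0 * x)
        assert r2m == pytest.approx(1.0, abs=1e-6)
        assert r2c == pytest.approx(1.0, abs=1e-6)
        # fixed effects unrelated to the response: R2m ~ 0
        y = rng.standard_normal(n)
        X0 = pd.DataFrame({"x": rng.standard_normal(n)})
        fit0 = fit_lmm(X0, y, {})
        r2m0, _ = r2_marginal_conditional(fit0, X0, y)
        assert r2m0 < 0.02

    def test_simulated_components_match_analytic_r2(self):
        # noise-free score: PRS is the standardized genetic value, so the
        # fixed effects explain exactly h2 (+ tiny sex/age parts) of a unit
        # phenotype and R2m has a closed form
        cfg = null_config(n_families=8000, var_family=0.25, pgs_noise=0.0, seed=61)
        cohort, _, extras = rge.simulate_sibling_cohort(cfg, traits=ONE_TRAIT)
        y = cohort["pheno_t"].to_numpy()
        fit, X = _fit(cohort, 1)
        r2m, r2c = r2_marginal_conditional(fit, X, y)
        # plug the realized variance components into the formula:
        # fixed effects capture the (realized) genetic variance + sex/age parts
        expect_m = (extras["score_true"].var() + 0.005) / np.var(y)
        assert r2m == pytest.approx(expect_m, rel=0.1)
        assert 0 <= r2m <= r2c <= 1

    def test_ordering_invariant_across_models(self, small_cohort):
        _, cohort, _, _ = small_cohort
        for mid in (1, 2, 3, 4, 5):
            fit, X = _fit(cohort, mid, trait="pheno_ses")
            r2m, r2c = r2_marginal_conditional(fit, X, cohort["pheno_ses"].to_numpy())
            assert 0.0 <= r2m <= r2c <= 1.0


class TestSibDifferenceOracle:
    def test_agrees_with_model2_within_effect(self):
        cfg = null_config(n_families=3000, seed=63)
        cohort, _, _ = rge.simulate_sibling_cohort(cfg, traits=ONE_TRAIT)
        slope, se = sib_difference_oracle(cohort, response="pheno_t")
        fit, _ = _fit(cohort, 2)
        joint = np.hypot(se, fit.bse["PRS_w"])
        assert abs(slope - fit.params["PRS_w"]) < 2 * joint

    def test_pure_direct_effect_recovers_attenuated_slope(self):
        # with a noise-free score, PRS = G / sd(G), so the within-family slope
        # on Y = G + e equals sd(G) exactly in expectation
        cfg = null_config(n_families=10000, var_family=0.0, pgs_noise=0.0, seed=67)
        cohort, _, extras = rge.simulate_sibling_cohort(
            cfg, traits=[rge.TraitSpec("t", h2=0.3, effect_corr=1.0)]
        )
        slope, se = sib_difference_oracle(cohort, response="pheno_t")
        expected = extras["score_true"].std()
        assert slope == pytest.approx(expected, abs=3 * se)

    def test_identical_sibs_rejected(self):
        cohort = pd.DataFrame({
            "FID": [0, 0, 1, 1], "IID": range(4),
            "PRS": [1.0, 1.0, 2.0, 2.0], "sex": [0, 1, 0, 1],
            "age": [50.0, 51.0, 49.0, 48.0],
            "pheno": [0.1, 0.2, 0.3, 0.4],
        })
        with pytest.raises(ValueError, match="undefined"):
            sib_difference_oracle(cohort)
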