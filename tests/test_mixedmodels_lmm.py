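"""Gaussian LMM: ML estimates, type-III Satterthwaite tests, contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from broodmeth.mixedmodels import (
    ModelSpec,
    bonferroni_adjust,
    fit_lmm_ml,
    likelihood_ratio_test,
    fit_binomial_glmm_laplace,
    slope_contrasts,
    type3_anova_satterthwaite,
)

from _oracles import balanced_oneway_ml


def _balanced_frame(g=8, k=5, sigma_b=1.2, sigma_e=0.7, seed=7):
    rng = np.random.default_rng(seed)
    grp = np.repeat([f"g{i}" for i in range(g)], k)
    y = 3.0 + np.repeat(rng.normal(0, sigma_b, g), k) + rng.normal(0, sigma_e, g * k)
    return pd.DataFrame(
        {
            "y": y,
            "grp": grp,
            "x": rng.normal(size=g * k),
            "treatment": np.where(
                np.repeat(np.arange(g) % 2, k) == 0, "reduced", "enlarged"
            ),
        }
    )


class TestFitLmmMl:
    def test_balanced_oneway_matches_closed_form(self):
        df = _balanced_frame()
        fit = fit_lmm_ml(
            ModelSpec(response="y", fixed_terms=[], random_intercepts=["grp"]), df
        )
        s2b, s2e = balanced_oneway_ml(df["y"], df["grp"])
        assert fit.sigma2_resid == pytest.approx(s2e, abs=1e-6)
        assert fit.var_components["grp"] == pytest.approx(s2b, abs=1e-6)

    def test_matches_statsmodels_ml(self):
        df = _balanced_frame(seed=21)
        fit = fit_lmm_ml(
            ModelSpec(response="y", fixed_terms=["x"], random_intercepts=["grp"]), df
        )
        sm_fit = smf.mixedlm("y ~ x", df, groups=df["grp"]).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)
        np.testing.assert_allclose(fit.beta, sm_fit.fe_params.to_numpy(), atol=1e-5)

    def test_zero_variance_boundary_equals_ols(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "y": rng.normal(size=40),
                "x": rng.normal(size=40),
                "grp": np.repeat([f"g{i}" for i in range(8)], 5),
            }
        )
        fit = fit_lmm_ml(
            ModelSpec(response="y", fixed_terms=["x"], random_intercepts=["grp"]), df
        )
        # Gaussian ML loglik of the OLS fit
        X = np.column_stack([np.ones(40), df["x"]])
        beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        r = df["y"] - X @ beta
        s2 = float(r @ r) / 40
        ll_ols = -0.5 * 40 * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik >= ll_ols - 1e-8

    def test_duplicated_rows_leave_between_group_beta_unchanged(self):
        # sufficiency holds for balanced between-group effects: duplicating
        # every row leaves the group means, and hence the treatment
        # estimate, untouched (within-group covariates legitimately
        # reweight when the replication level changes)
        df = _balanced_frame(seed=5)
        spec = ModelSpec(
            response="y",
            fixed_terms=["treatment"],
            random_intercepts=["grp"],
            coding="treatment",
            ref_levels={"treatment": "reduced"},
        )
        fit1 = fit_lmm_ml(spec, df)
        fit2 = fit_lmm_ml(spec, pd.concat([df, df], ignore_index=True))
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-6)

    def test_rank_deficient_design_names_aliased(self):
        df = _balanced_frame()
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="aliased"):
            fit_lmm_ml(
                ModelSpec(
                    response="y", fixed_terms=["x", "x2"], random_intercepts=["grp"]
                ),
                df,
            )

    def test_family_mismatch_rejected(self):
        df = _balanced_frame()
        spec = ModelSpec(
            response="y",
            fixed_terms=["x"],
            random_intercepts=["grp"],
            family="binomial_logit",
        )
        with pytest.raises(TypeError):
            fit_lmm_ml(spec, df)
        gspec = ModelSpec(
            response=("m", "n"), fixed_terms=["x"], random_intercepts=["grp"]
        )
        with pytest.raises(TypeError):
            fit_binomial_glmm_laplace(gspec, df)


class TestSatterthwaite:
    def test_balanced_splitplot_exact_df(self):
        g, k = 8, 5
        df = _balanced_frame(g=g, k=k, seed=11)
        fit = fit_lmm_ml(
            ModelSpec(
                response="y",
                fixed_terms=["treatment"],
                random_intercepts=["grp"],
                coding="sum",
                ref_levels={"treatment": "reduced"},
            ),
            df,
        )
        an = type3_anova_satterthwaite(fit).set_index("term")
        assert an.loc["treatment", "den_df"] == pytest.approx(g - 2, abs=0.5)

    def test_zero_variance_limit_matches_fixed_anova(self):
        rng = np.random.default_rng(13)
        n = 60
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "x": rng.normal(size=n),
                "grp": np.repeat([f"g{i}" for i in range(12)], 5),
            }
        )
        fit = fit_lmm_ml(
            ModelSpec(response="y", fixed_terms=["x"], random_intercepts=["grp"]), df
        )
        with pytest.warns(UserWarning, match="boundary"):
            an = type3_anova_satterthwaite(fit).set_index("term")
        # classical OLS F for x with n - 2 df
        import statsmodels.api as sm

        ols = sm.OLS(df["y"], sm.add_constant(df[["x"]])).fit()
        f_ols = float(ols.tvalues["x"] ** 2)
        assert an.loc["x", "F"] == pytest.approx(f_ols, rel=0.02)
        assert an.loc["x", "den_df"] == pytest.approx(n - 2, rel=0.05)

    def test_one_df_F_equals_squared_t(self):
        # without an interaction the slope of x IS the x coefficient, so
        # the type-III F for x must equal the squared slope t statistic
        df = _balanced_frame(seed=17)
        fit = fit_lmm_ml(
            ModelSpec(
                response="y",
                fixed_terms=["treatment", "x"],
                random_intercepts=["grp"],
                coding="sum",
                ref_levels={"treatment": "reduced"},
            ),
            df,
        )
        an = type3_anova_satterthwaite(fit).set_index("term")
        slopes = slope_contrasts(fit, "x", None)
        t2 = slopes[0].statistic ** 2
        assert an.loc["x", "F"] == pytest.approx(t2, abs=1e-8)


class TestSlopeContrasts:
    def test_slopes_combine_main_and_interaction(self):
        # planted slopes: reduced 0.10, enlarged 0.21
        rng = np.random.default_rng(23)
        n = 400
        treat = np.where(rng.random(n) < 0.5, "enlarged", "reduced")
        days = rng.uniform(0, 80, n)
        y = 1.0 + np.where(treat == "enlarged", 0.21, 0.10) * days + rng.normal(0, 0.05, n)
        df = pd.DataFrame(
            {
                "y": y,
                "treatment": treat,
                "days": days,
                "grp": np.repeat([f"g{i}" for i in range(20)], n // 20),
            }
        )
        fit = fit_lmm_ml(
            ModelSpec(
                response="y",
                fixed_terms=["treatment", "days", "treatment:days"],
                random_intercepts=["grp"],
                coding="treatment",
                ref_levels={"treatment": "reduced"},
            ),
            df,
        )
        slopes = {s.group: s.slope for s in slope_contrasts(fit, "days", "treatment")}
        assert slopes["reduced"] == pytest.approx(0.10, abs=0.005)
        assert slopes["enlarged"] == pytest.approx(0.21, abs=0.005)

    def test_no_interaction_gives_identical_slopes(self):
        df = _balanced_frame(seed=29)
        fit = fit_lmm_ml(
            ModelSpec(
                response="y",
                fixed_terms=["treatment", "x"],
                random_intercepts=["grp"],
                coding="sum",
                ref_levels={"treatment": "reduced"},
            ),
            df,
        )
        slopes = slope_contrasts(fit, "x", "treatment")
        assert slopes[0].slope == pytest.approx(slopes[1].slope, abs=1e-12)

    def test_bonferroni_doubles_p(self):
        df = _balanced_frame(seed=31)
        fit = fit_lmm_ml(
            ModelSpec(
                response="y",
                fixed_terms=["treatment", "x", "treatment:x"],
                random_intercepts=["grp"],
                coding="sum",
                ref_levels={"treatment": "reduced"},
            ),
            df,
        )
        out = slope_contrasts(fit, "x", "treatment", adjust="bonferroni")
        for s in out:
            assert s.p_adjusted == pytest.approx(min(1.0, 2 * s.p_raw))

    def test_missing_slope_var_raises(self):
        df = _balanced_frame()
        fit = fit_lmm_ml(
            ModelSpec(response="y", fixed_terms=["x"], random_intercepts=["grp"]), df
        )
        with pytest.raises(ValueError, match="not in the model"):
            slope_contrasts(fit, "days", None)


class TestLrtGaussian:
    def test_identical_models_statistic_zero(self):
        df = _balanced_frame()
        spec = ModelSpec(response="y", fixed_terms=["x"], random_intercepts=["grp"])
        f1 = fit_lmm_ml(spec, df)
        f2 = fit_lmm_ml(spec, df)
        res = likelihood_ratio_test(f1, f2)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == 1.0

    def test_closed_form_chi2_survival(self):
        from dataclasses import replace

        df = _balanced_frame()
        spec0 = ModelSpec(response="y", fixed_terms=[], random_intercepts=["grp"])
        spec1 = ModelSpec(response="y", fixed_terms=["x", "treatment"],
                          random_intercepts=["grp"])
        f0 = fit_lmm_ml(spec0, df)
        f1 = fit_lmm_ml(spec1, df)
        f0 = replace(f0, loglik=-100.0)
        f1 = replace(f1, loglik=-97.5)
        res = likelihood_ratio_test(f0, f1)
        assert res.statistic == pytest.approx(5.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(np.exp(-2.5), abs=1e-12)

    def test_tiny_negative_statistic_clamped(self):
        from dataclasses import replace

        df = _balanced_frame()
        spec0 = ModelSpec(response="y", fixed_terms=[], random_intercepts=["grp"])
        spec1 = ModelSpec(response="y", fixed_terms=["x"], random_intercepts=["grp"])
        f0 = fit_lmm_ml(spec0, df)
        f1 = fit_lmm_ml(spec1, df)
        f1 = replace(f1, loglik=f0.loglik - 5e-7)
        res = likelihood_ratio_test(f0, f1)
        assert res.statistic == 0.0

    def test_non_nested_rejected(self):
        df = _balanced_frame()
        f0 = fit_lmm_ml(
            ModelSpec(response="y", fixed_terms=["x"], random_intercepts=["grp"]), df
        )
        f1 = fit_lmm_ml(
            ModelSpec(
                response="y", fixed_terms=["treatment"], random_intercepts=["grp"]
            ),
            df,
        )
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f0, f1)


def test_refit_from_optimum_is_stationary():
    df = _balanced_frame(seed=37)
    spec = ModelSpec(response="y", fixed_terms=["x"], random_intercepts=["grp"])
    f1 = fit_lmm_ml(spec, df)
    f2 = fit_lmm_ml(spec, df)
    assert abs(f1.loglik - f2.loglik) < 1e-6


def test_bonferroni_adjust_definition():
    p = np.array([0.01, 0.4, np.nan])
    out = bonferroni_adjust(p)
    assert out[0] == pytest.approx(0.02)
    assert out[1] == pytest.approx(0.8)
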