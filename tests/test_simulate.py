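"""Synthetic-data generator: design, phenotypes, methylation counts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from broodmeth.simulate import (
    CATEGORIES,
    PhenotypeParams,
    SimulationConfig,
    TraitParams,
    make_category_plan,
    simulate_design,
    simulate_methylation,
    simulate_phenotypes,
)


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            SimulationConfig(recapture_prob_reduced=1.2)

    def test_days_range_ordering(self):
        with pytest.raises(ValueError, match="days_range"):
            SimulationConfig(days_range=(110, 28))

    def test_plan_exceeding_sites_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(n_sites=10, category_plan=make_category_plan(1000))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_sites=50, category_plan=make_category_plan(2))
        path = tmp_path / "cfg.yaml"
        cfg.to_file(path)
        assert SimulationConfig.from_file(path) == cfg


class TestDesign:
    def test_brood_sizes_from_generative_rule(self):
        cfg = SimulationConfig(n_cf_pairs=16, base_brood_size=9, manipulation=3,
                               recapture_prob_reduced=1.0, recapture_prob_enlarged=1.0)
        d = simulate_design(cfg)
        sizes = d.groupby(["brood_rearing", "treatment"]).size()
        for (_, tr), size in sizes.items():
            assert size == (12 if tr == "enlarged" else 6)
        assert d["cf_pair"].nunique() == 16

    def test_zero_manipulation_identity(self):
        cfg = SimulationConfig(manipulation=0, recapture_prob_reduced=1.0,
                               recapture_prob_enlarged=1.0)
        d = simulate_design(cfg)
        sizes = d.groupby("brood_rearing").size()
        assert (sizes == cfg.base_brood_size).all()

    def test_recapture_fractions_match_probabilities(self):
        # pooled across seeds, realised fractions must sit within binomial error
        counts = {"reduced": [0, 0], "enlarged": [0, 0]}
        for seed in range(40):
            d = simulate_design(SimulationConfig(seed=seed))
            for g in counts:
                sub = d[d["treatment"] == g]
                counts[g][0] += int(sub["recaptured"].sum())
                counts[g][1] += len(sub)
        for g, p_true in (("reduced", 0.3051), ("enlarged", 0.1643)):
            k, n = counts[g]
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(k / n - p_true) < 4 * se

    def test_recaptured_have_days_and_test_date(self):
        d = simulate_design(SimulationConfig(seed=3))
        rec = d[d["recaptured"]]
        lo, hi = SimulationConfig().days_range
        assert rec["days_since_fledging"].between(lo, hi).all()
        assert (rec["test_date"] == rec["fledge_date"] + rec["days_since_fledging"]).all()
        assert d.loc[~d["recaptured"], "days_since_fledging"].isna().all()

    def test_cross_fostering_half(self):
        d = simulate_design(SimulationConfig(seed=0))
        moved = (d["brood_origin"] != d["brood_rearing"]).mean()
        assert 0.3 < moved < 0.7

    def test_zero_recapture_fails_naming_treatment(self):
        with pytest.raises(ValueError, match="enlarged"):
            simulate_design(SimulationConfig(recapture_prob_enlarged=0.0))


class TestPhenotypes:
    def test_degenerate_noise_equals_linear_predictor(self):
        d = simulate_design(SimulationConfig(seed=2))
        params = PhenotypeParams(
            p3_length=TraitParams(intercept=40.0, slope_days_enlarged=0.04,
                                  noise_sd=0.0),
        )
        ph = simulate_phenotypes(d, params, seed=2)
        expected = 40.0 + np.where(
            ph["treatment"] == "enlarged", 0.04 * ph["days_since_fledging"], 0.0
        )
        np.testing.assert_allclose(ph["p3_length"], expected, atol=1e-12)

    def test_null_effects_give_centered_slopes(self):
        # per-treatment OLS slope of exploration vs days, mean over seeds ~ 0
        slopes = []
        for seed in range(30):
            d = simulate_design(SimulationConfig(seed=seed))
            params = PhenotypeParams(
                exploration=TraitParams(intercept=10.0, noise_sd=1.0)
            )
            ph = simulate_phenotypes(d, params, seed=seed)
            for g in ("reduced", "enlarged"):
                sub = ph[ph["treatment"] == g]
                slopes.append(
                    np.polyfit(sub["days_since_fledging"], sub["exploration_score"], 1)[0]
                )
        assert abs(np.mean(slopes)) < 0.005

    def test_planted_exploration_slope_recovered(self):
        # enlarged slope 0.21/day recovered within 10% on average
        slopes = []
        for seed in range(60):
            d = simulate_design(SimulationConfig(seed=seed))
            ph = simulate_phenotypes(d, PhenotypeParams(), seed=seed)
            sub = ph[ph["treatment"] == "enlarged"]
            slopes.append(
                np.polyfit(sub["days_since_fledging"], sub["exploration_score"], 1)[0]
            )
        assert np.mean(slopes) == pytest.approx(0.21, rel=0.10)

    def test_nonfinite_parameter_rejected(self):
        d = simulate_design(SimulationConfig(seed=1))
        bad = PhenotypeParams(exploration=TraitParams(intercept=np.nan))
        with pytest.raises(ValueError, match="non-finite"):
            simulate_phenotypes(d, bad, seed=1)

    def test_delta_weight_identity(self):
        d = simulate_design(SimulationConfig(seed=4))
        ph = simulate_phenotypes(d, seed=4)
        np.testing.assert_allclose(
            ph["delta_weight"], ph["weight_post"] - ph["weight_day14"]
        )


class TestMethylation:
    def test_counts_bounded_and_deterministic(self, design50):
        cfg = SimulationConfig(seed=9, n_sites=40)
        m1, t1 = simulate_methylation(design50, cfg)
        m2, t2 = simulate_methylation(design50, cfg)
        np.testing.assert_array_equal(m1.methylated, m2.methylated)
        np.testing.assert_array_equal(m1.total, m2.total)
        pd.testing.assert_frame_equal(t1, t2)
        assert (m1.methylated <= m1.total).all()
        assert (m1.total >= 0).all()

    def test_truth_table_matches_plan(self, design50):
        plan = make_category_plan(3, 0.02)
        cfg = SimulationConfig(seed=5, n_sites=50, category_plan=plan)
        _, truth = simulate_methylation(design50, cfg)
        counts = truth["category"].value_counts()
        for lab in CATEGORIES:
            assert counts[lab] == 3
        assert counts["null"] == 50 - 18
        nulls = truth[truth["category"] == "null"]
        assert (nulls[["slope_enlarged", "slope_reduced"]] == 0).all().all()

    def test_opposing_slopes_move_methylation_as_planted(self, design50):
        # logistic-curve oracle: empirical mean fraction rises with days in
        # the enlarged group and falls in the reduced group
        plan = {"opposing_enlarged_up": (30, 0.02, -0.02)}
        cfg = SimulationConfig(
            seed=6, n_sites=30, category_plan=plan, re_sd_origin=0.0,
            re_sd_rearing=0.0, obs_overdispersion_sd=0.0,
            baseline_logit_mix=((1.0, 0.0, 0.3),),
        )
        mat, _ = simulate_methylation(design50, cfg)
        rec = design50[design50["recaptured"]].reset_index(drop=True)
        days = rec["days_since_fledging"].to_numpy(float)
        frac = np.where(mat.total > 0, mat.methylated / np.maximum(mat.total, 1), np.nan)
        for g, sign in (("enlarged", 1), ("reduced", -1)):
            cols = (rec["treatment"] == g).to_numpy()
            x = days[cols]
            y = np.nanmean(frac[:, cols], axis=0)
            slope = np.polyfit(x, y, 1)[0]
            assert sign * slope > 0

    def test_binomial_null_dispersion_near_one(self, design50):
        cfg = SimulationConfig(
            seed=7, n_sites=60, re_sd_origin=0.0, re_sd_rearing=0.0,
            obs_overdispersion_sd=0.0, baseline_logit_mix=((1.0, -0.5, 0.4),),
        )
        mat, truth = simulate_methylation(design50, cfg)
        disp = []
        for i in range(mat.n_sites):
            obs = ~mat.missing[i]
            n = mat.total[i, obs].astype(float)
            p = 1 / (1 + np.exp(-truth["baseline_logit"].iloc[i]))
            resid = (mat.methylated[i, obs] - n * p) ** 2 / (n * p * (1 - p))
            disp.append(resid.mean())
        assert np.mean(disp) == pytest.approx(1.0, abs=0.05)

    def test_goodness_of_fit_binomial_without_overdispersion(self, design50):
        # chi-square GOF against the exact generative Binomial(total, p):
        # >= 95% of sites pass at the 1% level
        cfg = SimulationConfig(
            seed=8, n_sites=100, re_sd_origin=0.0, re_sd_rearing=0.0,
            obs_overdispersion_sd=0.0, baseline_logit_mix=((1.0, 0.0, 0.5),),
        )
        mat, truth = simulate_methylation(design50, cfg)
        rec = design50[design50["recaptured"]].reset_index(drop=True)
        days = rec["days_since_fledging"].to_numpy(float)
        days = days - days.mean()  # generator anchors slopes mid-trajectory
        passed = 0
        for i in range(mat.n_sites):
            obs = ~mat.missing[i]
            n = mat.total[i, obs].astype(float)
            p = 1 / (1 + np.exp(-truth["baseline_logit"].iloc[i]))
            chi2 = float(
                (((mat.methylated[i, obs] - n * p) ** 2) / (n * p * (1 - p))).sum()
            )
            if stats.chi2.sf(chi2, obs.sum()) > 0.01:
                passed += 1
        assert passed >= 95

    def test_monotone_in_planted_slope(self, design50):
        # increasing slope_enlarged strictly increases the fitted enlarged
        # trend of the empirical logit (3 levels x pooled seeds)
        rec = design50[design50["recaptured"]].reset_index(drop=True)
        cols = (rec["treatment"] == "enlarged").to_numpy()
        days = rec.loc[cols, "days_since_fledging"].to_numpy(float)
        means = []
        for slope in (0.005, 0.015, 0.03):
            est = []
            for seed in range(10):
                cfg = SimulationConfig(
                    seed=seed, n_sites=20,
                    category_plan={"enlarged_only_up": (20, slope, 0.0)},
                    re_sd_origin=0.1, re_sd_rearing=0.1,
                    obs_overdispersion_sd=0.0,
                    baseline_logit_mix=((1.0, -0.5, 0.3),),
                )
                mat, _ = simulate_methylation(design50, cfg)
                frac = np.clip(
                    (mat.methylated[:, cols] + 0.5) / (mat.total[:, cols] + 1.0),
                    1e-6, 1 - 1e-6,
                )
                elogit = np.log(frac / (1 - frac))
                for row in elogit:
                    est.append(np.polyfit(days, row, 1)[0])
            means.append(np.mean(est))
        assert means[0] < means[1] < means[2]

    def test_empty_generation_rejected(self, design50):
        with pytest.raises(ValueError):
            simulate_methylation(
                design50, SimulationConfig(n_sites=0, category_plan={})
            )
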