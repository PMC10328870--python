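import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import gls_at_tau2, reml_grid_oracle
from silvicarbon.effects import compute_effect_sizes
from silvicarbon.meta import (
    MetaFit,
    fit_moderator_model,
    fit_random_effects,
    funnel_data,
    omnibus_test,
    sensitivity_reanalysis,
)


def _fit(y, v, study):
    return fit_random_effects(
        pd.DataFrame({"lnrr": y, "variance": v, "study_id": study})
    )


class TestRandomEffects:
    def test_single_comparison(self):
        fit = _fit([0.5], [0.04], ["a"])
        assert fit.coefficients[0] == pytest.approx(0.5)
        assert fit.se[0] == pytest.approx(0.2)
        assert fit.tau2 == 0.0

    def test_identical_effects_have_zero_heterogeneity(self):
        fit = _fit([0.3] * 5, [0.02] * 5, list("abcde"))
        assert fit.coefficients[0] == pytest.approx(0.3)
        assert fit.tau2 == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_oracle_singleton_studies(self):
        y, v, study = [0.1, 0.5, 0.9], [0.04] * 3, list("abc")
        tau2_star, beta_star = reml_grid_oracle(y, v, study)
        fit = _fit(y, v, study)
        assert fit.tau2 == pytest.approx(tau2_star, abs=1e-4)
        assert fit.coefficients[0] == pytest.approx(beta_star[0], abs=1e-6)
        # value frozen from the oracle run (also reproduced by R metafor)
        assert fit.tau2 == pytest.approx(0.12, abs=1e-4)
        assert fit.coefficients[0] == pytest.approx(0.5, abs=1e-6)

    def test_matches_grid_search_oracle_nested_studies(self, toy_effects):
        y = toy_effects["lnrr"].to_numpy()
        v = toy_effects["variance"].to_numpy()
        study = toy_effects["study_id"].to_numpy()
        tau2_star, beta_star = reml_grid_oracle(y, v, study)
        fit = fit_random_effects(toy_effects)
        assert fit.tau2 == pytest.approx(tau2_star, abs=1e-4)
        assert fit.coefficients[0] == pytest.approx(beta_star[0], abs=1e-6)

    def test_matches_r_metafor_multilevel(self, toy_effects):
        # frozen from rma.mv(yi, V, random=~1|study, method="REML"), metafor 4.8-0
        fit = fit_random_effects(toy_effects)
        assert fit.coefficients[0] == pytest.approx(0.4926669, abs=1e-6)
        assert fit.se[0] == pytest.approx(0.09592724, abs=1e-6)
        assert fit.tau2 == pytest.approx(0.01441937, abs=1e-6)

    def test_zero_tau2_collapses_to_fixed_effect_mean(self, rng):
        # identical true effect, distinct studies, heterogeneous variances
        v = rng.uniform(0.01, 0.1, size=8)
        y = np.full(8, 0.25)
        study = [f"s{i}" for i in range(8)]
        fit = _fit(y, v, study)
        assert fit.tau2 == pytest.approx(0.0, abs=1e-8)
        w = 1 / v
        assert fit.coefficients[0] == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-8)
        assert fit.se[0] == pytest.approx(math.sqrt(1 / np.sum(w)), abs=1e-8)

    def test_k_and_m_counts(self, toy_effects):
        fit = fit_random_effects(toy_effects)
        assert fit.k == 6
        assert fit.m == 4
        assert fit.k >= fit.m

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            _fit([], [], [])

    def test_ci_back_transform_preserves_order(self, toy_effects):
        fit = fit_random_effects(toy_effects)
        pct = fit.percent.iloc[0]
        assert pct["ci_low_pct"] < pct["estimate_pct"] < pct["ci_high_pct"]
        lo, hi = fit.ci95[0]
        assert pct["ci_low_pct"] == pytest.approx((math.exp(lo) - 1) * 100)
        assert pct["ci_high_pct"] == pytest.approx((math.exp(hi) - 1) * 100)


class TestModeratorModel:
    def test_cell_means_with_zero_tau2_are_weighted_category_means(self):
        y = [0.2, 0.4, 0.6, 0.8]
        v = [0.05] * 4
        study = list("abcd")
        eff = pd.DataFrame({"lnrr": y, "variance": v, "study_id": study})
        fit = fit_moderator_model(eff, values=["g1", "g1", "g2", "g2"], moderator="g")
        assert fit.tau2 == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients == pytest.approx([0.3, 0.7], abs=1e-8)
        assert fit.term_names == ["g1", "g2"]

    def test_single_observation_category_excluded(self, toy_effects):
        values = ["x", "x", "y", "y", "x", "z"]  # z has one observation
        fit = fit_moderator_model(toy_effects, values=values, moderator="g")
        assert fit.dropped_categories == ["z"]
        assert fit.term_names == ["x", "y"]
        assert fit.k == 5

    def test_matches_direct_gls_at_oracle_tau2(self, rng):
        # 3-category instance with nested studies
        y = rng.normal(0.3, 0.3, size=9)
        v = rng.uniform(0.01, 0.08, size=9)
        study = np.array(["a", "a", "b", "b", "c", "c", "d", "d", "e"])
        cats = np.array(["g1", "g2", "g3"] * 3)
        X = np.column_stack([(cats == g).astype(float) for g in ("g1", "g2", "g3")])
        tau2_star, beta_star = reml_grid_oracle(y, v, study, X=X)
        eff = pd.DataFrame({"lnrr": y, "variance": v, "study_id": study})
        fit = fit_moderator_model(eff, values=list(cats), moderator="g")
        assert fit.coefficients == pytest.approx(
            gls_at_tau2(fit.tau2, y, v, study, X), abs=1e-6
        )
        assert fit.tau2 == pytest.approx(tau2_star, abs=1e-4)
        assert fit.coefficients == pytest.approx(beta_star, abs=1e-6)

    def test_matches_r_metafor_cell_means(self, toy_effects):
        # frozen from rma.mv(yi, V, mods=~g-1, random=~1|study), metafor 4.8-0
        fit = fit_moderator_model(
            toy_effects, values=["x", "y", "x", "y", "x", "y"], moderator="g"
        )
        assert fit.coefficients == pytest.approx([0.204495, 0.6397], abs=1e-5)
        assert fit.tau2 == pytest.approx(0.004964829, abs=1e-6)
        assert fit.omnibus[0] == pytest.approx(45.50464, rel=1e-5)

    def test_live_r_metafor_cross_check(self, toy_effects):
        """The same model fitted by the independent metafor toolchain."""
        script = (
            'suppressMessages(library(metafor));'
            'd <- data.frame(y=c(.2,.5,.3,.9,.1,.6), v=c(.04,.02,.05,.03,.06,.02),'
            'study=c("a","a","b","b","c","d"));'
            'f <- rma.mv(yi=y, V=v, random=~1|study, data=d, method="REML");'
            'cat(coef(f), f$se, f$sigma2)'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        mu_r, se_r, tau2_r = map(float, proc.stdout.split())
        fit = fit_random_effects(toy_effects)
        assert fit.coefficients[0] == pytest.approx(mu_r, abs=1e-6)
        assert fit.se[0] == pytest.approx(se_r, abs=1e-6)
        assert fit.tau2 == pytest.approx(tau2_r, abs=1e-6)

    def test_continuous_moderator_tests_slope_only(self, toy_effects):
        fit = fit_moderator_model(
            toy_effects, values=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0], moderator="age"
        )
        assert fit.term_names == ["intercept", "age"]
        assert list(fit.tested) == [1]
        assert fit.omnibus[1] == 1

    def test_rows_missing_moderator_dropped_for_that_model_only(self, toy_effects):
        values = ["x", None, "x", "y", None, "y"]
        fit = fit_moderator_model(toy_effects, values=values, moderator="g")
        assert fit.k == 4

    def test_all_categories_dropped_errors(self, toy_effects):
        values = ["a", "b", "c", "d", "e", "f"]
        with pytest.raises(ValueError, match="dropped"):
            fit_moderator_model(toy_effects, values=values, moderator="g")

    def test_absent_moderator_column_errors(self, toy_effects):
        with pytest.raises(KeyError):
            fit_moderator_model(toy_effects, moderator="no_such_column")

    def test_constant_continuous_moderator_errors(self, toy_effects):
        with pytest.raises(ValueError, match="constant"):
            fit_moderator_model(toy_effects, values=[2.0] * 6, moderator="age")


class TestOmnibus:
    def test_zero_coefficients_give_qm_zero_p_one(self):
        fit = MetaFit(
            coefficients=np.zeros(2),
            coef_cov=np.eye(2) * 0.01,
            tau2=0.0,
            k=4,
            m=4,
            term_names=["a", "b"],
            tested=np.array([0, 1]),
        )
        qm, df, p = fit.omnibus
        assert qm == 0.0
        assert df == 2
        assert p == 1.0

    def test_coefficient_at_z_critical_value(self):
        se = 0.1
        fit = MetaFit(
            coefficients=np.array([1.96 * se]),
            coef_cov=np.array([[se**2]]),
            tau2=0.0,
            k=3,
            m=3,
            term_names=["a"],
            tested=np.array([0]),
        )
        qm, df, p = fit.omnibus
        assert qm == pytest.approx(3.8416)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_df_equals_tested_block_size(self, toy_effects):
        fit = fit_moderator_model(
            toy_effects, values=["x", "y", "x", "y", "x", "y"], moderator="g"
        )
        assert fit.omnibus[1] == 2


class TestFunnel:
    def test_standard_errors_are_sqrt_variance(self, toy_effects):
        table, _ = funnel_data(toy_effects)
        merged = table.sort_values("study_id")
        assert np.allclose(
            sorted(table["se"]), sorted(np.sqrt(toy_effects["variance"]))
        )

    def test_sorted_by_precision(self, toy_effects):
        table, _ = funnel_data(toy_effects)
        assert table["se"].is_monotonic_increasing

    def test_single_effect_no_egger(self):
        table, egger = funnel_data(
            pd.DataFrame({"lnrr": [0.4], "variance": [0.02], "study_id": ["a"]})
        )
        assert len(table) == 1
        assert egger is None

    def test_symmetric_effects_egger_intercept_covers_zero(self, rng):
        k = 80
        v = rng.uniform(0.005, 0.08, size=k)
        y = rng.normal(0.2, np.sqrt(v))
        eff = pd.DataFrame(
            {"lnrr": y, "variance": v, "study_id": [f"s{i}" for i in range(k)]}
        )
        _, egger = funnel_data(eff)
        assert egger["intercept_ci_low"] <= 0 <= egger["intercept_ci_high"]


class TestSensitivity:
    def test_no_imputed_records_gives_identical_fits(self, make_record):
        records = [
            make_record(study_id=f"s{i}", mean_treat=55 + 3 * i) for i in range(5)
        ]
        result = sensitivity_reanalysis(records)
        assert result.n_removed == 0
        assert result.fit_all.coefficients[0] == pytest.approx(
            result.fit_complete.coefficients[0]
        )
        assert result.fit_all.tau2 == pytest.approx(result.fit_complete.tau2)

    def test_sign_preserving_imputation_flagged_robust(self, make_record):
        records = [
            make_record(study_id=f"s{i}", mean_treat=70 + 2 * i, sd_treat=4.0)
            for i in range(6)
        ] + [make_record(study_id="s9", mean_treat=72.0, sd_treat=None)]
        result = sensitivity_reanalysis(records)
        assert result.n_removed == 1
        assert result.robust
        assert bool(result.difference["robust"].all())

    def test_removal_counts_logged(self, make_record):
        records = [
            make_record(study_id="s1", sd_treat=5.0),
            make_record(study_id="s2", sd_treat=None),
            make_record(study_id="s3", sd_ctrl=None),
        ]
        result = sensitivity_reanalysis(records)
        assert result.n_all == 3
        assert result.n_complete == 1
        assert result.n_removed == 2

    def test_no_complete_records_errors(self, make_record):
        with pytest.raises(ValueError):
            sensitivity_reanalysis([make_record(sd_treat=None, sd_ctrl=None)])
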