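import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import gls_at_tau2, reml_grid_oracle
from silvicarbon.effects import compute_effect_sizes
from silvicarbon.synthetic import SlopeSpec, default_config, generate_compilation
from silvicarbon.trends import (
    TrendFit,
    fit_time_meta_regression,
    npk_time_values,
    trim_by_covariate,
    zero_crossing,
)


class TestTrim:
    def test_interplant_age_rule_drops_two(self, make_record):
        records = [make_record(site_id=f"s{a}", stand_age=a) for a in (5, 15, 21, 28)]
        kept, dropped = trim_by_covariate(records, "stand_age", 20.0)
        assert dropped == 2
        assert [r.stand_age for r in kept] == [5, 15]

    def test_infinite_max_keeps_everything(self, make_record):
        records = [
            make_record(site_id=f"s{t}", time_since_treatment=t) for t in (1, 30, 80)
        ]
        kept, dropped = trim_by_covariate(records, "time_since_treatment", math.inf)
        assert dropped == 0
        assert kept == records

    def test_empty_input(self):
        kept, dropped = trim_by_covariate([], "stand_age", 20.0)
        assert kept == [] and dropped == 0

    def test_missing_covariate_records_kept(self, make_record):
        records = [make_record(stand_age=None), make_record(stand_age=25.0)]
        kept, dropped = trim_by_covariate(records, "stand_age", 20.0)
        assert dropped == 1
        assert kept[0].stand_age is None


class TestTimeMetaRegression:
    def test_noiseless_line_recovered_exactly(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = -0.2 + 0.05 * x
        eff = pd.DataFrame(
            {"lnrr": y, "variance": [0.02] * 5, "study_id": list("abcde")}
        )
        fit = fit_time_meta_regression(eff, covariate="age", values=list(x))
        assert fit.slope == pytest.approx(0.05, abs=1e-8)
        assert fit.intercept == pytest.approx(-0.2, abs=1e-8)
        assert fit.tau2 == pytest.approx(0.0, abs=1e-8)

    def test_matches_gls_oracle_on_six_point_instance(self, rng):
        x = np.array([0.5, 1.5, 2.5, 3.5, 4.5, 5.5])
        y = rng.normal(0.1 + 0.04 * x, 0.15)
        v = rng.uniform(0.01, 0.05, size=6)
        study = np.array(["a", "a", "b", "b", "c", "c"])
        X = np.column_stack([np.ones(6), x])
        tau2_star, beta_star = reml_grid_oracle(y, v, study, X=X)
        eff = pd.DataFrame({"lnrr": y, "variance": v, "study_id": study})
        fit = fit_time_meta_regression(eff, covariate="t", values=list(x))
        assert fit.tau2 == pytest.approx(tau2_star, abs=1e-4)
        assert [fit.intercept, fit.slope] == pytest.approx(beta_star, abs=1e-6)

    def test_synthetic_slope_recovered_within_ci(self):
        cfg = replace(
            default_config("interplant", seed=42),
            n_publications=150,
            comparisons_per_publication=(1, 2),
            moderator_spec={},
            slope_spec=(SlopeSpec("stand_age", 0.036, 1.0, 20.0),),
            missing_sd_fraction=0.0,
        )
        records, _ = generate_compilation(cfg)
        eff = compute_effect_sizes(records)
        fit = fit_time_meta_regression(
            eff, covariate="stand_age", values=[r.stand_age for r in records]
        )
        lo, hi = fit.ci95_slope
        assert lo <= 0.036 <= hi
        assert fit.percent_per_unit == pytest.approx(100 * fit.slope)

    def test_too_few_covariate_values_errors(self, toy_effects):
        with pytest.raises(ValueError, match=">= 3"):
            fit_time_meta_regression(
                toy_effects, covariate="t",
                values=[1.0, 2.0, None, None, None, None],
            )

    def test_constant_covariate_errors(self, toy_effects):
        with pytest.raises(ValueError, match="constant"):
            fit_time_meta_regression(toy_effects, covariate="t", values=[3.0] * 6)

    def test_trim_then_fit_equals_fit_of_pretrimmed(self, make_record):
        records = [
            make_record(study_id=f"s{i}", mean_treat=50 + 2 * i, stand_age=float(i))
            for i in range(2, 26, 3)
        ]
        kept, _ = trim_by_covariate(records, "stand_age", 20.0)
        eff_kept = compute_effect_sizes(kept)
        direct = fit_time_meta_regression(
            eff_kept, covariate="stand_age", values=[r.stand_age for r in kept]
        )
        eff_all = compute_effect_sizes(records)
        masked = [
            r.stand_age if r.stand_age <= 20 else None for r in records
        ]
        via_mask = fit_time_meta_regression(
            eff_all, covariate="stand_age", values=masked
        )
        assert via_mask.slope == pytest.approx(direct.slope, abs=1e-10)
        assert via_mask.intercept == pytest.approx(direct.intercept, abs=1e-10)

    def test_prediction_band_brackets_fit(self, toy_effects):
        fit = fit_time_meta_regression(
            toy_effects, covariate="t", values=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        )
        band = fit.predict(lo=1.0, hi=6.0, n_points=11)
        assert (band["lnrr_low"] <= band["lnrr_fit"]).all()
        assert (band["lnrr_fit"] <= band["lnrr_high"]).all()


class TestZeroCrossing:
    def _trend(self, intercept, slope):
        return TrendFit(
            covariate="t",
            intercept=intercept,
            slope=slope,
            ci95_intercept=(intercept, intercept),
            ci95_slope=(slope, slope),
            p_slope=0.01,
            tau2=0.0,
            n_used=10,
            n_dropped=0,
            meta_fit=None,
        )

    def test_crossing_arithmetic(self):
        assert zero_crossing(self._trend(-0.2, 0.05)) == pytest.approx(4.0)

    def test_zero_slope_has_no_crossing(self):
        assert zero_crossing(self._trend(-0.2, 0.0)) is None

    def test_same_sign_intercept_and_slope_no_positive_crossing(self):
        assert zero_crossing(self._trend(0.2, 0.05)) is None

    @given(
        intercept=st.floats(min_value=-2, max_value=-0.01),
        slope=st.floats(min_value=0.001, max_value=1),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    def test_invariant_to_common_rescaling(self, intercept, slope, scale):
        a = zero_crossing(self._trend(intercept, slope))
        b = zero_crossing(self._trend(intercept * scale, slope * scale))
        assert a == pytest.approx(b, rel=1e-9)


class TestNpkTimeVariable:
    def test_continuous_studies_use_stand_age(self, make_record):
        records = [
            make_record(
                treatment="npk", application_method="continuous",
                stand_age=12.0, time_since_treatment=3.0,
            ),
            make_record(
                treatment="npk", application_method="pulse",
                stand_age=12.0, time_since_treatment=3.0,
            ),
            make_record(treatment="npk", time_since_treatment=4.0),
        ]
        assert npk_time_values(records) == [12.0, 3.0, 4.0]
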