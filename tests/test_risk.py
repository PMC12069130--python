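import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from retriage import (
    MixedLogit,
    STDRRiskModel,
    build_training_table,
    calibrate_threshold,
    predict_risk,
    prepare_eligible,
    select_fp_transform,
    summarise_measurements,
)
from retriage.risk import FPTransform, ModelSpec, RiskModelFit
from retriage.simulate import hazard_intervals

from conftest import make_history


class TestMeasurementImputation:
    def test_empty_series_yield_the_fixed_constants(self):
        """No linked measurements: median HbA1c 51, SD 6.2, DBP 76, SBP 130."""
        hist = make_history(["R0M0", "R0M0", "R0M0"])
        s = summarise_measurements(hist, hist.appointments[-1].date)
        assert (s.median_hba1c, s.sd_hba1c, s.dbp, s.sbp) == (51.0, 6.2, 76.0, 130.0)
        assert s.imputed_median_hba1c and s.imputed_sd_hba1c
        assert s.imputed_dbp and s.imputed_sbp

    def test_observed_values_used_directly(self):
        d = dt.date
        hist = make_history(
            ["R0M0", "R0M0", "R0M0"],
            hba1c_series=[(d(2015, 2, 1), 50.0), (d(2015, 8, 1), 60.0), (d(2016, 2, 1), 70.0)],
            dbp_series=[(d(2015, 2, 1), 80.0), (d(2015, 8, 1), 90.0)],
        )
        s = summarise_measurements(hist, d(2017, 1, 1))
        assert s.median_hba1c == 60.0
        assert s.sd_hba1c == pytest.approx(np.std([50, 60, 70], ddof=1))
        assert s.dbp == 85.0
        assert not s.imputed_median_hba1c and not s.imputed_sd_hba1c

    def test_single_value_keeps_median_imputes_sd(self):
        hist = make_history(["R0M0", "R0M0"], hba1c_series=[(dt.date(2015, 2, 1), 48.0)])
        s = summarise_measurements(hist, dt.date(2016, 1, 1))
        assert (s.median_hba1c, s.sd_hba1c) == (48.0, 6.2)
        assert not s.imputed_median_hba1c and s.imputed_sd_hba1c

    def test_only_values_before_reference_date_count(self):
        hist = make_history(["R0M0", "R0M0"], hba1c_series=[(dt.date(2015, 6, 1), 90.0)])
        s = summarise_measurements(hist, dt.date(2015, 6, 1))  # same day: not "before"
        assert s.median_hba1c == 51.0


class TestTrainingTable:
    def _table_for(self, grades, gaps):
        e = prepare_eligible(make_history(grades, gaps))
        return build_training_table([e])

    def test_event_within_590_days_is_positive(self):
        # STDR 400 days after the 2nd qualifying visit
        t = self._table_for(["R0M0", "R0M0", "R0M0", "R2M0"], [365, 365, 400])
        assert list(t["outcome"]) == [0.0, 1.0]  # row 1: 765d away; row 2: 400d

    def test_event_beyond_590_days_is_negative(self):
        t = self._table_for(["R0M0", "R0M0", "R2M0"], [365, 600])
        assert list(t["outcome"]) == [0.0]

    def test_event_at_exactly_590_days_is_positive(self):
        t = self._table_for(["R0M0", "R0M0", "R2M0"], [365, 590])
        assert list(t["outcome"]) == [1.0]

    def test_no_qualifying_visits_gives_empty_table(self):
        hist = make_history(["R0M0", "R1M0", "R0M0"])
        e = prepare_eligible(hist)
        assert e is None  # never two consecutive R0M0 with follow-up

    def test_prior_dna_flag_from_raw_record(self):
        e = prepare_eligible(make_history(["R0M0", "DNA", "R0M0", "R0M0", "R0M0"]))
        t = build_training_table([e])
        assert (t["prior_dna"] == 1.0).all()


class TestFPSelection:
    @staticmethod
    def _simulate(rng, shape, n=400):
        x = rng.uniform(0.5, 10.0, n)
        eta = -1.0 + (0.35 * x if shape == "linear" else 1.5 * np.log(x))
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        return pd.DataFrame({"x": x, "outcome": y})

    def test_linear_effect_keeps_linear_term(self):
        """With a truly linear effect the closed test retains the linear
        term in at least 90% of replicates (test level 0.05)."""
        rng = np.random.default_rng(2024)
        kept = sum(
            select_fp_transform(self._simulate(rng, "linear"), "x").is_linear
            for _ in range(100)
        )
        assert kept >= 90

    def test_log_effect_prefers_nonlinear(self):
        rng = np.random.default_rng(99)
        results = [select_fp_transform(self._simulate(rng, "log", n=1500), "x")
                   for _ in range(30)]
        nonlinear = sum(not t.is_linear for t in results)
        assert nonlinear > sum(t.is_linear for t in results)

    def test_constant_covariate_warns_and_stays_linear(self):
        table = pd.DataFrame({"x": np.ones(50), "outcome": [0, 1] * 25})
        with pytest.warns(UserWarning, match="constant"):
            tr = select_fp_transform(table, "x")
        assert tr.is_linear

    def test_fp_design_shapes(self):
        x = np.array([1.0, 2.0, 4.0])
        assert FPTransform((0.0,)).design(x) == pytest.approx(np.log(x)[:, None])
        two = FPTransform((2.0, 2.0)).design(x)
        assert two[:, 0] == pytest.approx(x**2)
        assert two[:, 1] == pytest.approx(x**2 * np.log(x))


class TestThresholdCalibration:
    def _fit_with_probs(self, probs):
        class Stub(RiskModelFit):
            def __init__(self):
                self._p = np.asarray(probs, dtype=float)

            def predict(self, table):
                return self._p

        return Stub()

    def test_lower_quantile_on_ten_distinct_probabilities(self):
        probs = np.linspace(0.01, 0.10, 10)
        thr = calibrate_threshold(self._fit_with_probs(probs), pd.DataFrame(index=range(10)))
        assert thr == pytest.approx(probs[7])  # 8th order statistic

    def test_flag_fraction_near_one_flags_everyone(self):
        probs = [0.2, 0.4, 0.6]
        thr = calibrate_threshold(self._fit_with_probs(probs), pd.DataFrame(index=range(3)),
                                  flag_fraction=0.999)
        assert thr <= min(probs)

    def test_all_equal_probabilities_tie_rule(self):
        thr = calibrate_threshold(self._fit_with_probs([0.3] * 8), pd.DataFrame(index=range(8)))
        assert thr == 0.3  # downstream >= comparison flags all

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(self._fit_with_probs([0.1]), pd.DataFrame(index=[0]),
                                flag_fraction=1.2)

    def test_calibrated_flagged_share_within_one_row(self, model2_fit):
        table = model2_fit._training_table
        p = model2_fit.predict(table)
        frac = float(np.mean(p >= model2_fit.threshold_p))
        assert 0.20 <= frac <= 0.20 + 1.0 / len(table) + 1e-12


class TestPrediction:
    def test_zero_linear_predictor_gives_half(self):
        fit = RiskModelFit.from_dict(
            {"covariate_set": 1, "coefficients":
             {"intercept": 0.0, "age": 0.0, "duration": 0.0, "type1": 0.0, "prior_dna": 0.0},
             "re_variance": 0.0}
        )
        row = {"age": 60.0, "duration": 5.0, "type1": 0.0, "prior_dna": 1.0}
        assert predict_risk(fit, row) == pytest.approx(0.5)

    def test_hand_computed_inverse_logit(self):
        fit = RiskModelFit.from_dict(
            {"covariate_set": 1, "coefficients":
             {"intercept": -4.0, "age": -0.02, "duration": 0.05, "type1": 0.3,
              "prior_dna": 0.8},
             "re_variance": 0.25}
        )
        row = {"age": 50.0, "duration": 12.0, "type1": 1.0, "prior_dna": 0.0}
        eta = -4.0 - 0.02 * 50 + 0.05 * 12 + 0.3
        assert predict_risk(fit, row) == pytest.approx(1 / (1 + math.exp(-eta)))

    def test_monotone_in_positive_coefficient(self):
        fit = RiskModelFit.from_dict(
            {"covariate_set": 1, "coefficients":
             {"intercept": -3.0, "age": 0.0, "duration": 0.1, "type1": 0.0, "prior_dna": 0.0},
             "re_variance": 0.0}
        )
        base = {"age": 50.0, "duration": 5.0, "type1": 0.0, "prior_dna": 0.0}
        more = dict(base, duration=15.0)
        assert predict_risk(fit, more) > predict_risk(fit, base)

    def test_missing_covariate_named_in_error(self):
        fit = RiskModelFit.from_dict(
            {"covariate_set": 1, "coefficients":
             {"intercept": 0.0, "age": 0.0, "duration": 0.0, "type1": 0.0, "prior_dna": 0.0},
             "re_variance": 0.0}
        )
        with pytest.raises(ValueError, match="prior_dna"):
            predict_risk(fit, {"age": 50.0, "duration": 5.0, "type1": 0.0})


class TestFitting:
    def test_degenerate_random_effect_matches_plain_logit(self):
        """Independent rows (one per person): beta agrees with statsmodels
        Logit within 1e-3."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 3000
        table = pd.DataFrame(
            {
                "person_id": np.arange(n),
                "age": rng.uniform(30, 80, n),
                "duration": rng.exponential(7, n),
                "type1": rng.binomial(1, 0.1, n).astype(float),
                "prior_dna": rng.binomial(1, 0.3, n).astype(float),
            }
        )
        eta = -3.0 - 0.01 * table.age + 0.05 * table.duration + 0.6 * table.prior_dna
        table["outcome"] = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        fit = STDRRiskModel(table, 1).fit()
        X = np.column_stack([np.ones(n), table.age, table.duration, table.type1,
                             table.prior_dna])
        plain = sm.Logit(table.outcome, X).fit(disp=0)
        assert np.allclose(fit.params.to_numpy(), plain.params, atol=1e-3)

    def test_parameter_recovery_on_interval_table(self, recovery_cohort):
        """Fitting the generator's own hazard covariates on the ground-truth
        interval table recovers every fixed effect within 3 SE."""
        df = hazard_intervals(recovery_cohort)
        covs = ["duration_ge10", "age_le40", "eth_black", "eth_south_asian",
                "eth_other_asian", "eth_mixed", "eth_other"]
        res = MixedLogit.from_dataframe(df, "event", covs, "person_id").fit()
        truth = {
            "intercept": -4.70, "duration_ge10": 0.69, "age_le40": 0.90,
            "eth_black": 0.85, "eth_south_asian": 0.65, "eth_other_asian": 0.40,
            "eth_mixed": 0.75, "eth_other": 0.50,
        }
        for name, true_val in truth.items():
            err = abs(res.params[name] - true_val)
            assert err < 3 * res.bse[name], (name, res.params[name], res.bse[name])

    def test_serialisation_round_trip(self, model2_fit, tmp_path):
        path = tmp_path / "fit.json"
        model2_fit.to_json(path)
        back = RiskModelFit.from_json(path)
        assert back.params.to_dict() == pytest.approx(model2_fit.params.to_dict())
        assert back.threshold_p == model2_fit.threshold_p
        row = {"age": 55.0, "duration": 8.0, "type1": 0.0, "prior_dna": 1.0,
               **{f"eth_{e}": 0.0 for e in
                  ("black", "south_asian", "other_asian", "mixed", "other")}}
        assert predict_risk(back, row) == pytest.approx(predict_risk(model2_fit, row))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(5)
        assert ModelSpec(2).includes_ethnicity
        assert not ModelSpec(3).includes_ethnicity
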