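"""Landmark risk sets, CV models, calibration, decision curves, survival."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mskmark import landmark, phantoms


def tiny_cohort(event_rows):
    """Hand-built cohort: event_rows = [(knee, event_time, event, kl), ...]."""
    visits = []
    for i, (knee, *_) in enumerate(event_rows):
        # distinct baselines and slopes so reference SDs are > 0
        base = 2.2 + 0.05 * i
        slope = -0.001 * (1 + 0.2 * i)
        for month in phantoms.VISIT_MONTHS:
            for comp in phantoms.LANDMARK_COMPARTMENTS:
                visits.append((knee, f"P_{knee}", month, comp,
                               base + slope * month))
    knees = pd.DataFrame([
        {"knee_id": k, "participant_id": f"P_{k}", "event_time": t, "event": e,
         "censor_time": max(t, 96.0) if e else t, "kl": kl,
         "age": 60.0, "sex": 1, "bmi": 27.0}
        for k, t, e, kl in event_rows
    ])
    visits = pd.DataFrame(visits, columns=[
        "knee_id", "participant_id", "visit_month", "compartment", "thickness_mm"])
    return phantoms.LandmarkCohortData(visits=visits, knees=knees)


class TestBuildLandmark:
    def test_risk_set_rules(self):
        data = tiny_cohort([
            ("early_event", 36.0, 1, 0),   # event before landmark -> excluded
            ("in_window", 60.0, 1, 0),     # event inside window -> outcome 1
            ("late_event", 100.0, 1, 1),   # event after window -> outcome 0
            ("censored_in", 50.0, 0, 0),   # censored inside window -> 0 + flag
            ("full_follow", 96.0, 0, 1),
            ("extra1", 96.0, 0, 0),
            ("extra2", 96.0, 0, 1),
        ])
        lm = landmark.build_landmark(data, task="tkr", horizon_months=48.0)
        assert "early_event" not in lm.features.index
        assert lm.outcome.loc["in_window"] == 1
        assert lm.outcome.loc["late_event"] == 0
        assert lm.outcome.loc["censored_in"] == 0
        assert lm.meta.loc["censored_in", "censored_in_window"] == 1
        assert lm.meta.loc["full_follow", "censored_in_window"] == 0

    def test_censored_in_window_can_be_excluded(self):
        data = tiny_cohort([
            ("censored_in", 50.0, 0, 0),
            ("a", 96.0, 0, 0), ("b", 96.0, 0, 1), ("c", 60.0, 1, 0),
        ])
        lm = landmark.build_landmark(data, exclude_censored_in_window=True)
        assert "censored_in" not in lm.features.index

    def test_oa_task_restricted_to_low_kl(self):
        data = tiny_cohort([
            ("kl0", 96.0, 0, 0), ("kl1", 96.0, 0, 1),
            ("kl2", 96.0, 0, 2), ("kl3", 60.0, 1, 3),
        ])
        lm = landmark.build_landmark(data, task="oa")
        assert set(lm.features.index) == {"kl0", "kl1"}

    def test_incomplete_biomarkers_excluded(self):
        data = tiny_cohort([("a", 96.0, 0, 0), ("b", 96.0, 0, 1),
                            ("c", 96.0, 0, 0), ("d", 60.0, 1, 1)])
        visits = data.visits
        gap = ~((visits["knee_id"] == "a") & (visits["visit_month"] == 24))
        data = phantoms.LandmarkCohortData(visits=visits[gap], knees=data.knees)
        lm = landmark.build_landmark(data)
        assert "a" not in lm.features.index

    def test_mean_imputation_identical_when_nothing_missing(self, landmark_cohort_data):
        plain = landmark.build_landmark(landmark_cohort_data)
        imputed = landmark.build_landmark(landmark_cohort_data,
                                          mean_impute_missing_visits=True)
        pd.testing.assert_frame_equal(plain.features, imputed.features)


class TestFitRiskModel:
    def test_trajectory_signal_recovered(self, landmark_cohort, landmark_predictions):
        auc = roc_auc_score(landmark_predictions["outcome"],
                            landmark_predictions["raw_probability"])
        assert auc > 0.70

    def test_slope_features_carry_negative_lr_sign(self, landmark_cohort):
        # faster thickness loss (more negative annual change) raises risk
        from sklearn.linear_model import LogisticRegression

        X = landmark_cohort.features.to_numpy(float)
        y = landmark_cohort.outcome.to_numpy(int)
        lr = LogisticRegression(class_weight="balanced", max_iter=5000).fit(X, y)
        chg_cols = [i for i, c in enumerate(landmark_cohort.features.columns)
                    if "_chg_" in c]
        assert np.mean(lr.coef_[0][chg_cols]) < 0

    def test_null_cohort_gives_chance_auc(self):
        aucs = []
        for seed in range(20):
            spec = phantoms.LongitudinalCohortSpec(
                n_knees=400, hazard_coef_per_mm_lost=0.0,
                baseline_hazard_per_month=0.002, rng_seed=seed)
            lm = landmark.build_landmark(phantoms.make_landmark_cohort(spec))
            preds = landmark.fit_risk_model(lm, model="lr", seed=seed)
            aucs.append(roc_auc_score(preds["outcome"], preds["raw_probability"]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_paired_knees_co_assigned_to_folds(self):
        spec = phantoms.LongitudinalCohortSpec(n_knees=300,
                                               knees_per_participant=2, rng_seed=2)
        lm = landmark.build_landmark(phantoms.make_landmark_cohort(spec))
        preds = landmark.fit_risk_model(lm, model="lr", seed=0)
        assert (preds.groupby("participant_id")["fold"].nunique() == 1).all()

    def test_isotonic_calibration_monotone_within_fold(self, landmark_predictions):
        for _, fold in landmark_predictions.groupby("fold"):
            srt = fold.sort_values("raw_probability")
            assert (np.diff(srt["calibrated_probability"]) >= -1e-12).all()


class TestEvaluateRisk:
    def _constant_preds(self, rng, n=5000, p=0.2):
        y = (rng.uniform(size=n) < p).astype(int)
        return pd.DataFrame({
            "knee_id": range(n), "participant_id": range(n), "fold": 0,
            "raw_probability": np.full(n, p),
            "calibrated_probability": np.full(n, p),
            "outcome": y,
        })

    def test_brier_matches_analytic_expectation(self, rng):
        preds = self._constant_preds(rng, p=0.2)
        m = landmark.evaluate_risk(preds, n_boot=10, seed=0)
        assert m.brier_calibrated == pytest.approx(0.2 * 0.8, abs=0.01)

    def test_constant_predictions_slope_is_nan(self, rng):
        preds = self._constant_preds(rng)
        m = landmark.evaluate_risk(preds, n_boot=10, seed=0)
        assert np.isnan(m.calibration_slope_raw)

    def test_calibrated_simulation_slope_near_one(self, rng):
        p = rng.uniform(0.05, 0.95, size=5000)
        y = (rng.uniform(size=5000) < p).astype(int)
        preds = pd.DataFrame({
            "knee_id": range(5000), "participant_id": range(5000), "fold": 0,
            "raw_probability": p, "calibrated_probability": p, "outcome": y,
        })
        m = landmark.evaluate_risk(preds, n_boot=10, seed=0)
        assert m.calibration_slope_raw == pytest.approx(1.0, abs=0.1)

    def test_perfect_ranking_auc_one(self):
        preds = pd.DataFrame({
            "knee_id": range(6), "participant_id": range(6), "fold": 0,
            "raw_probability": [0.1, 0.2, 0.3, 0.7, 0.8, 0.9],
            "calibrated_probability": [0.1, 0.2, 0.3, 0.7, 0.8, 0.9],
            "outcome": [0, 0, 0, 1, 1, 1],
        })
        assert landmark.evaluate_risk(preds, n_boot=50, seed=0).auc == 1.0


class TestDecisionCurve:
    def _preds(self, y, p):
        return pd.DataFrame({
            "knee_id": range(len(y)), "participant_id": range(len(y)), "fold": 0,
            "raw_probability": p, "calibrated_probability": p, "outcome": y,
        })

    def test_treat_none_reference_is_zero(self, rng):
        y = rng.integers(0, 2, 100)
        dc = landmark.decision_curve(self._preds(y, rng.uniform(size=100)),
                                     thresholds=[0.1, 0.2], n_boot=20, seed=0)
        assert (dc["net_benefit_treat_none"] == 0.0).all()

    def test_treat_all_closed_form_at_prevalence(self, rng):
        y = np.array([1] * 20 + [0] * 80)
        dc = landmark.decision_curve(self._preds(y, rng.uniform(size=100)),
                                     thresholds=[0.2], n_boot=20, seed=0)
        assert dc["net_benefit_treat_all"].iloc[0] == pytest.approx(
            0.2 - 0.8 * 0.25)  # = 0.0

    def test_toy_confusion_net_benefit(self):
        # n=100, TP=10, FP=20 at pt=0.2 -> NB = 0.10 - 0.20*0.25 = 0.05
        y = np.array([1] * 10 + [0] * 20 + [0] * 65 + [1] * 5)
        p = np.array([0.9] * 30 + [0.05] * 70)
        dc = landmark.decision_curve(self._preds(y, p), thresholds=[0.2],
                                     n_boot=20, seed=0)
        assert dc["net_benefit"].iloc[0] == pytest.approx(0.05)

    def test_harm_penalty_shifts_curve_down(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.uniform(size=200)
        base = landmark.decision_curve(self._preds(y, p), thresholds=[0.2],
                                       n_boot=10, seed=0)
        pen = landmark.decision_curve(self._preds(y, p), thresholds=[0.2],
                                      harm=0.05, n_boot=10, seed=0)
        assert pen["net_benefit"].iloc[0] == pytest.approx(
            base["net_benefit"].iloc[0] - 0.05)

    def test_unit_threshold_rejected(self, rng):
        y = rng.integers(0, 2, 20)
        with pytest.raises(ValueError, match="thresholds"):
            landmark.decision_curve(self._preds(y, rng.uniform(size=20)),
                                    thresholds=[1.0], n_boot=10, seed=0)


class TestSurvivalComparators:
    def test_perfect_risk_order_gives_unit_c(self):
        time = np.array([2.0, 4.0, 6.0, 8.0])
        event = np.ones(4, dtype=int)
        score = np.array([0.9, 0.7, 0.5, 0.1])
        assert landmark.harrell_c(time, event, score) == 1.0

    def test_one_swap_gives_five_sixths(self):
        time = np.array([2.0, 4.0, 6.0, 8.0])
        event = np.ones(4, dtype=int)
        score = np.array([0.7, 0.9, 0.5, 0.1])  # swap the top two
        assert landmark.harrell_c(time, event, score) == pytest.approx(5 / 6)

    def test_random_scores_give_chance_c(self, rng):
        time = rng.exponential(10, size=500)
        event = np.ones(500, dtype=int)
        score = rng.uniform(size=500)
        assert landmark.harrell_c(time, event, score) == pytest.approx(0.5, abs=0.05)

    def test_matches_lifelines_on_censored_data(self, rng):
        from lifelines.utils import concordance_index

        time = rng.exponential(10, size=50)
        event = rng.integers(0, 2, size=50)
        if event.sum() == 0:
            event[0] = 1
        score = rng.uniform(size=50)
        ours = landmark.harrell_c(time, event, score)
        # lifelines ranks by predicted survival time (low score = long life)
        theirs = concordance_index(time, -score, event)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_cox_comparator_on_synthetic_cohort(self, landmark_cohort):
        out = landmark.cox_comparator(landmark_cohort)
        assert 0.5 < out.harrell_c <= 1.0
        assert 0.0 < out.ipcw_c <= 1.0
        assert len(out.coefficients) > 0

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="no comparable pairs"):
            landmark.harrell_c([5.0, 5.0], [0, 0], [0.2, 0.8])


class TestKaplanMeier:
    def _preds(self, n, p=None):
        rng = np.random.default_rng(0)
        prob = p if p is not None else rng.uniform(size=n)
        return pd.DataFrame({
            "knee_id": range(n), "participant_id": range(n), "fold": 0,
            "raw_probability": prob, "calibrated_probability": prob,
            "outcome": 0,
        })

    def test_no_events_gives_flat_survival(self):
        preds = self._preds(10)
        out = landmark.km_by_risk_group(preds, time=np.full(10, 48.0),
                                        event=np.zeros(10, int),
                                        times=[12.0, 24.0, 48.0])
        assert (out["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        # all three in one group (constant risk): S(2) = (2/3)*(1/2) = 1/3
        preds = self._preds(3, p=np.full(3, 0.5))
        out = landmark.km_by_risk_group(preds, time=[1.0, 2.0, 3.0],
                                        event=[1, 1, 1], times=[2.0])
        low = out[out["group"] == "low_risk"]
        assert low["survival"].iloc[0] == pytest.approx(1 / 3)

    def test_median_split_balanced(self, rng):
        preds = self._preds(101)
        out = landmark.km_by_risk_group(preds, time=rng.exponential(50, 101),
                                        event=rng.integers(0, 2, 101),
                                        times=[10.0])
        sizes = out.groupby("group")["n"].first()
        assert abs(sizes["low_risk"] - sizes["high_risk"]) <= 1
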