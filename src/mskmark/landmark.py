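"""Landmark-time risk models for knee replacement and incident osteoarthritis.

A landmark at 48 months fixes the prediction time t0: the risk set contains
knees event-free and uncensored at t0 with complete biomarkers through 48
months, and the outcome is the event within the following horizon. Features
are thickness levels and annual changes through t0 plus demographics, z-scored
to a KL 0-1 reference. Models (400-tree random forest with min_samples_leaf 10
for joint replacement, L2 logistic regression for incident OA, both
class-balanced) are fit with five-fold participant-grouped stratified CV;
out-of-fold probabilities are isotonically calibrated per fold. Evaluation
covers AUC with percentile bootstrap CIs, Brier score, calibration slope,
decision-curve net benefit, Cox comparators on month-0 features (Harrell's C
and IPCW C) and Kaplan-Meier curves by median risk split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from . import biomarkers
from .phantoms import LANDMARK_COMPARTMENTS, LandmarkCohortData, VISIT_MONTHS
from .volume_io import logger


# ---------------------------------------------------------------------------
# Risk-set construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkCohort:
    """Feature matrix + outcome for the knees at risk at the landmark."""

    features: pd.DataFrame  # indexed by knee, includes demographics
    outcome: pd.Series
    groups: pd.Series  # participant ids, aligned with features
    meta: pd.DataFrame  # event_time, event, censored_in_window, kl
    landmark_month: float
    horizon_months: float
    feature_names: tuple[str, ...]


def build_landmark(cohort: LandmarkCohortData, task: str = "tkr",
                   landmark_month: float = 48.0, horizon_months: float = 48.0,
                   mean_impute_missing_visits: bool = False,
                   exclude_censored_in_window: bool = False) -> LandmarkCohort:
    """Assemble the landmark risk set and its binary outcome.

    Knees with an event or censoring at or before the landmark are excluded,
    as are knees with incomplete biomarkers through the landmark (unless
    ``mean_impute_missing_visits`` fills gaps with the knee's own mean). The
    outcome is an event in (landmark, landmark + horizon]; knees censored
    inside the window without an event are coded 0 and flagged
    (``exclude_censored_in_window`` drops them instead). The OA task restricts
    to baseline KL < 2. Features are z-scored to the KL 0-1 reference,
    computed once globally.
    """
    if task not in {"tkr", "oa"}:
        raise ValueError("task must be 'tkr' or 'oa'")
    knees = cohort.knees.copy()
    bad = knees["event_time"] > knees["censor_time"]
    if (bad & (knees["event"] == 1)).any():
        raise ValueError("bookkeeping inconsistency: event recorded after censoring")

    visits = cohort.visits
    expected_visits = [m for m in VISIT_MONTHS if m <= landmark_month]

    # wide per-knee features: level at each visit + annual change per interval
    levels = visits[visits["visit_month"] <= landmark_month].pivot_table(
        index="knee_id", columns=["compartment", "visit_month"],
        values="thickness_mm", aggfunc="first",
    )
    levels.columns = [f"{c}_thk_m{int(m)}" for c, m in levels.columns]

    changes = biomarkers.annual_changes(
        visits[visits["visit_month"] <= landmark_month])
    change_wide = changes.pivot_table(
        index="knee_id", columns=["compartment", "visit_month"],
        values="annual_change", aggfunc="first",
    )
    change_wide.columns = [f"{c}_chg_m{int(m)}" for c, m in change_wide.columns]

    expected_cols = [f"{c}_thk_m{int(m)}" for c in LANDMARK_COMPARTMENTS
                     for m in expected_visits]
    expected_cols += [f"{c}_chg_m{int(m)}" for c in LANDMARK_COMPARTMENTS
                      for m in expected_visits if m != expected_visits[0]]
    feats = levels.join(change_wide, how="outer").reindex(columns=expected_cols)
    if mean_impute_missing_visits:
        # per-scan (per-knee) mean imputation within each compartment family
        for comp in LANDMARK_COMPARTMENTS:
            for kind in ("thk", "chg"):
                cols = [c for c in feats.columns if c.startswith(f"{comp}_{kind}_")]
                if cols:
                    block = feats[cols]
                    feats[cols] = block.apply(
                        lambda row: row.fillna(row.mean()), axis=1)
    complete = feats.notna().all(axis=1)

    knees = knees.set_index("knee_id")
    at_risk = (knees["event_time"] > landmark_month) & \
              (knees["censor_time"] > landmark_month)
    keep = feats.index[complete].intersection(knees.index[at_risk])
    if task == "oa":
        keep = keep.intersection(knees.index[knees["kl"] < 2])
    if len(keep) == 0:
        raise ValueError("empty landmark risk set")

    feats = feats.loc[keep].sort_index()
    sub = knees.loc[feats.index]

    window_end = landmark_month + horizon_months
    outcome = ((sub["event"] == 1) & (sub["event_time"] <= window_end)).astype(int)
    censored_in_window = ((sub["event"] == 0)
                          & (sub["event_time"] < window_end)).astype(int)
    if censored_in_window.any():
        logger.warning(
            "landmark: %d knees censored inside the prediction window coded as "
            "outcome 0 (sensitivity flag available)", int(censored_in_window.sum()),
        )
    if exclude_censored_in_window:
        keep2 = censored_in_window == 0
        feats, sub = feats[keep2.values], sub[keep2.values]
        outcome = outcome[keep2.values]
        censored_in_window = censored_in_window[keep2.values]

    # z-score trajectory features to the KL 0-1 reference, frozen globally
    ref_mask = (sub["kl"] < 2).to_numpy()
    feature_cols = list(feats.columns)
    if ref_mask.sum() >= 3:
        ref = biomarkers.fit_reference(feats, feature_cols, ref_mask,
                                       provenance="baseline KL 0-1 knees")
        feats = biomarkers.zscore(feats, ref)
    else:
        logger.warning("landmark: fewer than 3 KL 0-1 knees; features left unscaled")

    feats = feats.join(sub[["age", "sex", "bmi"]])
    meta = sub[["event_time", "event", "kl"]].copy()
    meta["censored_in_window"] = censored_in_window

    return LandmarkCohort(
        features=feats,
        outcome=outcome,
        groups=sub["participant_id"],
        meta=meta,
        landmark_month=landmark_month,
        horizon_months=horizon_months,
        feature_names=tuple(feats.columns),
    )


# ---------------------------------------------------------------------------
# Cross-validated risk models with isotonic calibration
# ---------------------------------------------------------------------------

def _make_model(model: str, seed: int, rf_trees: int = 400,
                rf_min_samples_leaf: int = 10):
    if model == "rf":
        return RandomForestClassifier(
            n_estimators=rf_trees, min_samples_leaf=rf_min_samples_leaf,
            class_weight="balanced", random_state=seed, n_jobs=1,
        )
    if model == "lr":
        # default regularization is the L2 penalty
        return LogisticRegression(class_weight="balanced",
                                  max_iter=5000, random_state=seed)
    raise ValueError("model must be 'rf' or 'lr'")


def fit_risk_model(cohort: LandmarkCohort, model: str = "rf", seed: int = 0,
                   n_splits: int = 5) -> pd.DataFrame:
    """Out-of-fold raw and isotonically calibrated risk predictions.

    Five-fold stratified CV grouped by participant keeps paired knees
    together. Isotonic calibration is fit per fold on the training split only
    — against internal 3-fold cross-validated predictions, since a model's
    predictions on its own training data are over-confident — and applied to
    the held-out fold, so calibrated probabilities are monotone in the raw
    probabilities within each fold.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    X = cohort.features.to_numpy(dtype=float)
    y = cohort.outcome.to_numpy(dtype=int)
    groups = cohort.groups.to_numpy()

    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    raw = np.full(len(y), np.nan)
    calibrated = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    for i, (train, test) in enumerate(cv.split(X, y, groups)):
        if y[train].sum() < 2 or y[test].sum() < 1:
            raise ValueError(f"fold {i} has too few events; use fewer folds")
        clf = _make_model(model, seed)
        clf.fit(X[train], y[train])
        p_test = clf.predict_proba(X[test])[:, 1]
        inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        p_train_cv = cross_val_predict(_make_model(model, seed), X[train], y[train],
                                       cv=inner, method="predict_proba")[:, 1]
        iso = IsotonicRegression(out_of_bounds="clip", y_min=0.0, y_max=1.0)
        iso.fit(p_train_cv, y[train])
        raw[test] = p_test
        calibrated[test] = iso.predict(p_test)
        fold_of[test] = i
    assert not np.isnan(raw).any(), "out-of-fold predictions must cover every knee"

    return pd.DataFrame({
        "knee_id": cohort.features.index,
        "participant_id": groups,
        "fold": fold_of,
        "raw_probability": raw,
        "calibrated_probability": calibrated,
        "outcome": y,
    })


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskMetrics:
    auc: float
    auc_ci: tuple[float, float]
    brier_raw: float
    brier_calibrated: float
    calibration_slope_raw: float
    calibration_slope_calibrated: float


def _calibration_slope(y: np.ndarray, p: np.ndarray) -> float:
    """Slope of a logistic fit of outcome on the log-odds of the prediction."""
    if np.ptp(p) == 0.0:
        logger.warning("calibration slope undefined for constant predictions")
        return float("nan")
    import statsmodels.api as sm

    logit = np.log(np.clip(p, 1e-9, 1 - 1e-9) / (1 - np.clip(p, 1e-9, 1 - 1e-9)))
    fit = sm.GLM(y, sm.add_constant(logit),
                 family=sm.families.Binomial()).fit()
    return float(fit.params[1])


def evaluate_risk(predictions: pd.DataFrame, use: str = "calibrated_probability",
                  n_boot: int = 1000, seed: int = 0) -> RiskMetrics:
    """AUC (knee-level percentile bootstrap CI), Brier, and calibration slopes."""
    y = predictions["outcome"].to_numpy(dtype=int)
    p = predictions[use].to_numpy(dtype=float)
    p_raw = predictions["raw_probability"].to_numpy(dtype=float)
    p_cal = predictions["calibrated_probability"].to_numpy(dtype=float)

    auc = float(roc_auc_score(y, p))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(y)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        boots[i] = roc_auc_score(y[idx], p[idx])

    return RiskMetrics(
        auc=auc,
        auc_ci=(float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))),
        brier_raw=float(np.mean((p_raw - y) ** 2)),
        brier_calibrated=float(np.mean((p_cal - y) ** 2)),
        calibration_slope_raw=_calibration_slope(y, p_raw),
        calibration_slope_calibrated=_calibration_slope(y, p_cal),
    )


# ---------------------------------------------------------------------------
# Decision curves (net benefit)
# ---------------------------------------------------------------------------

def net_benefit(y: np.ndarray, p: np.ndarray, pt: float, harm: float = 0.0) -> float:
    """NB(pt) = TP/n - (FP/n) * pt/(1-pt) - harm, decision rule p >= pt."""
    if not 0.0 < pt < 1.0:
        raise ValueError("threshold probability must be in (0, 1)")
    n = len(y)
    pos = p >= pt
    tp = np.sum(pos & (y == 1))
    fp = np.sum(pos & (y == 0))
    return tp / n - (fp / n) * pt / (1 - pt) - harm


def decision_curve(predictions: pd.DataFrame, thresholds=None,
                   harm: float = 0.0, use: str = "calibrated_probability",
                   n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Net benefit per threshold with treat-all/treat-none references and
    percentile bootstrap bands. ``harm`` is a constant per-intervention
    penalty subtracted from the model's net benefit.
    """
    y = predictions["outcome"].to_numpy(dtype=int)
    p = predictions[use].to_numpy(dtype=float)
    if thresholds is None:
        thresholds = np.arange(0.05, 0.51, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")

    prevalence = y.mean()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(y), size=(n_boot, len(y)))

    rows = []
    for pt in thresholds:
        nb = net_benefit(y, p, pt, harm)
        nb_all = prevalence - (1 - prevalence) * pt / (1 - pt) - harm
        boots = np.array([net_benefit(y[idx[i]], p[idx[i]], pt, harm)
                          for i in range(n_boot)])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((pt, nb, lo, hi, nb_all, 0.0))
    return pd.DataFrame(rows, columns=[
        "threshold", "net_benefit", "nb_ci_low", "nb_ci_high",
        "net_benefit_treat_all", "net_benefit_treat_none",
    ])


# ---------------------------------------------------------------------------
# Survival comparators
# ---------------------------------------------------------------------------

def harrell_c(time, event, score) -> float:
    """Harrell's concordance: concordant comparable pairs / comparable pairs.

    A pair is comparable when the earlier time is an event; tied scores count
    0.5. Higher score must mean earlier event for concordance.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    score = np.asarray(score, dtype=float)
    n = len(time)
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if time[j] > time[i] or (time[j] == time[i] and event[j] == 0):
                comparable += 1
                if score[i] > score[j]:
                    concordant += 1.0
                elif score[i] == score[j]:
                    concordant += 0.5
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return concordant / comparable


@dataclass(frozen=True)
class CoxComparator:
    harrell_c: float
    ipcw_c: float
    coefficients: pd.Series


def cox_comparator(cohort: LandmarkCohort, month0_features: list[str] | None = None,
                   horizon: float | None = None) -> CoxComparator:
    """Cox proportional-hazards comparator on month-0 features.

    Time is measured from the landmark. Reports Harrell's C on the model's
    risk scores and the IPCW C with Kaplan-Meier censoring weights truncated
    at the horizon.
    """
    if month0_features is None:
        month0_features = [c for c in cohort.features.columns
                           if c.endswith("_thk_m0")] + ["age", "sex", "bmi"]
    df = cohort.features[month0_features].copy()
    time = cohort.meta["event_time"].to_numpy(dtype=float) - cohort.landmark_month
    event = cohort.meta["event"].to_numpy(dtype=int)
    df["time"] = np.clip(time, 1e-6, None)
    df["event"] = event

    cph = CoxPHFitter(penalizer=0.01)
    cph.fit(df, duration_col="time", event_col="event")
    risk = cph.predict_partial_hazard(df[month0_features]).to_numpy()

    c_harrell = harrell_c(df["time"], df["event"], risk)

    from sksurv.metrics import concordance_index_ipcw

    struct = np.array(list(zip(event.astype(bool), df["time"])),
                      dtype=[("event", bool), ("time", float)])
    tau = horizon if horizon is not None else cohort.horizon_months
    c_ipcw = float(concordance_index_ipcw(struct, struct, risk, tau=tau)[0])

    return CoxComparator(harrell_c=float(c_harrell), ipcw_c=c_ipcw,
                         coefficients=cph.params_)


def km_by_risk_group(predictions: pd.DataFrame, time, event,
                     times=None) -> pd.DataFrame:
    """Kaplan-Meier survival per median-split risk group.

    Splits at the median calibrated risk; returns product-limit survival
    evaluated at ``times`` (default: observed event times) per group.
    """
    p = predictions["calibrated_probability"].to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    median = np.median(p)
    high = p > median
    if times is None:
        times = np.unique(time[event == 1])

    rows = []
    for name, mask in (("low_risk", ~high), ("high_risk", high)):
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask])
        surv = km.survival_function_at_times(times).to_numpy()
        for t, s in zip(np.atleast_1d(times), np.atleast_1d(surv)):
            rows.append((name, float(t), float(s), int(mask.sum())))
    return pd.DataFrame(rows, columns=["group", "time", "survival", "n"])
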