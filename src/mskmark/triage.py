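"""Three-stage knee triage cascade with workload accounting.

Stage A is a normal-knee screen: a stack of elastic-net logistic regression,
XGBoost and histogram gradient boosting trained with five-fold subject-grouped
cross-validation whose out-of-fold probabilities feed a logistic meta-learner.
Scans below the Stage-A operating point (chosen for a specificity target) are
removed; the pass set goes to Stage B (same stack, its own thresholds), and
forwarded scans reach Stage C, an equal-weight logistic-regression/XGBoost
ensemble that localizes abnormality to joints (C1) and tissues within joints
(C2). Metrics carry subject-level bootstrap CIs and verification workload is
reported per 1000 scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import calibration_curve
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold
from xgboost import XGBClassifier

from .volume_io import logger

TRIAGE_FEATURES = (
    "femur_cartilage_thickness",
    "tibia_cartilage_thickness",
    "patella_cartilage_thickness",
    "femur_bone_volume",
    "tibia_bone_volume",
    "patella_bone_volume",
    "sex",
    "age",
    "weight",
)


# ---------------------------------------------------------------------------
# Stage fitting (stacked learners, grouped CV)
# ---------------------------------------------------------------------------

def _base_learners(seed: int) -> dict:
    return {
        "elastic_net_lr": LogisticRegression(
            l1_ratio=0.5, solver="saga",  # elastic-net mixing 0.5
            class_weight="balanced", C=1.0, max_iter=5000, random_state=seed,
        ),
        "xgboost": XGBClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            subsample=1.0, colsample_bytree=1.0, tree_method="hist",
            n_jobs=1, random_state=seed, eval_metric="logloss",
        ),
        "hist_gb": HistGradientBoostingClassifier(random_state=seed),
    }


@dataclass
class StageFit:
    """Out-of-fold stacked probabilities plus the fitted base/meta models."""

    oof_probs: np.ndarray
    oof_base_probs: pd.DataFrame
    fold_of: np.ndarray
    base_models: dict
    meta_model: LogisticRegression


def _grouped_folds(y: np.ndarray, groups: np.ndarray, n_splits: int, seed: int):
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(cv.split(np.zeros_like(y), y, groups))
    for i, (train, test) in enumerate(folds):
        for name, idx in (("training", train), ("test", test)):
            if len(np.unique(y[idx])) < 2:
                raise ValueError(
                    f"fold {i} {name} split is missing a class; use fewer folds"
                )
        if set(groups[train]) & set(groups[test]):
            raise AssertionError("group appears in train and test of the same fold")
    return folds


def fit_stage(features: pd.DataFrame, labels, groups, seed: int = 0,
              n_splits: int = 5) -> StageFit:
    """Fit the stacked screen and return one out-of-fold probability per scan.

    Features are assumed already z-scored against the global reference (never
    per fold). ``groups`` are subject identifiers; no subject straddles a
    fold boundary.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    folds = _grouped_folds(y, groups, n_splits, seed)

    learners = _base_learners(seed)
    oof_base = np.full((len(y), len(learners)), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    for i, (train, test) in enumerate(folds):
        fold_of[test] = i
        for j, name in enumerate(learners):
            model = _base_learners(seed)[name]
            model.fit(X[train], y[train])
            oof_base[test, j] = model.predict_proba(X[test])[:, 1]
    assert not np.isnan(oof_base).any(), "every scan must receive out-of-fold probabilities"

    # meta-learner: logistic on the out-of-fold base probabilities, itself
    # cross-validated on the same grouped folds so stacked probabilities are
    # out-of-fold too
    oof_meta = np.full(len(y), np.nan)
    for train, test in folds:
        meta = LogisticRegression(max_iter=1000, random_state=seed)
        meta.fit(oof_base[train], y[train])
        oof_meta[test] = meta.predict_proba(oof_base[test])[:, 1]
    assert not np.isnan(oof_meta).any()

    base_models = {}
    for name in learners:
        model = _base_learners(seed)[name]
        model.fit(X, y)
        base_models[name] = model
    meta_model = LogisticRegression(max_iter=1000, random_state=seed)
    meta_model.fit(oof_base, y)

    return StageFit(
        oof_probs=oof_meta,
        oof_base_probs=pd.DataFrame(oof_base, columns=list(learners)),
        fold_of=fold_of,
        base_models=base_models,
        meta_model=meta_model,
    )


# ---------------------------------------------------------------------------
# Operating points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    stage: str
    specificity_target: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")


def _confusion(probs: np.ndarray, y: np.ndarray, t: float):
    pos = probs >= t
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    tn = int(np.sum(~pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    return tp, fp, tn, fn


def threshold_at_specificity(probs, labels, target: float,
                             stage: str = "A") -> OperatingPoint:
    """Smallest threshold whose achieved specificity meets the target.

    The decision rule is ``p >= t`` (inclusive). Candidates are the sorted
    unique probabilities plus a point just above the maximum; choosing the
    smallest qualifying candidate resolves ties toward higher sensitivity.
    If only the above-maximum point qualifies, sensitivity is 0 and a warning
    is emitted.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to set an operating point")
    eps = 1e-9 + 1e-6 * max(1.0, np.abs(probs).max())
    candidates = np.concatenate([np.unique(probs), [probs.max() + eps]])
    neg = probs[y == 0]
    for t in candidates:
        specificity = np.mean(neg < t)
        if specificity >= target:
            tp, fp, tn, fn = _confusion(probs, y, float(t))
            op = OperatingPoint(stage, target, float(t), tp, fp, tn, fn)
            if op.sensitivity == 0.0:
                logger.warning(
                    "stage %s: specificity target %.2f only reachable with zero "
                    "sensitivity", stage, target,
                )
            return op
    raise AssertionError("unreachable: the above-maximum candidate always qualifies")


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeResult:
    routes: pd.DataFrame  # scan_id, route in {removed_A, not_forwarded_B, forwarded}
    forwarded_fraction: float
    n_total: int
    n_removed_a: int
    n_not_forwarded_b: int
    n_forwarded: int


def route_cascade(stage_a_probs, stage_b_probs, op_a: OperatingPoint,
                  op_b: OperatingPoint, scan_ids=None) -> CascadeResult:
    """Route every scan through the two-threshold cascade.

    ``stage_b_probs`` is defined on the Stage-A pass set only (NaN elsewhere
    is accepted); routes are mutually exclusive and exhaustive.
    """
    pa = np.asarray(stage_a_probs, dtype=float)
    pb = np.asarray(stage_b_probs, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("stage A and B probability arrays must align per scan")
    n = len(pa)
    ids = np.asarray(scan_ids) if scan_ids is not None else np.arange(n)

    passed_a = pa >= op_a.threshold
    if np.isnan(pb[passed_a]).any():
        raise ValueError("stage B probabilities missing on the Stage-A pass set")
    forwarded = passed_a & (pb >= op_b.threshold)

    route = np.where(~passed_a, "removed_A",
                     np.where(forwarded, "forwarded", "not_forwarded_B"))
    routes = pd.DataFrame({"scan_id": ids, "route": route,
                           "stage_a_prob": pa, "stage_b_prob": pb})
    n_fwd = int(forwarded.sum())
    return CascadeResult(
        routes=routes,
        forwarded_fraction=n_fwd / n,
        n_total=n,
        n_removed_a=int((~passed_a).sum()),
        n_not_forwarded_b=int((passed_a & ~forwarded).sum()),
        n_forwarded=n_fwd,
    )


# ---------------------------------------------------------------------------
# Stage C localization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageCTask:
    task: str
    probabilities: np.ndarray
    labels: np.ndarray
    calibration: pd.DataFrame  # bin mean predicted vs observed frequency


def stage_c(features: pd.DataFrame, task_labels: Mapping[str, Sequence[int]],
            seed: int = 0, n_bins: int = 10) -> dict[str, StageCTask]:
    """Equal-weight LR + XGBoost ensemble per localization task.

    Fit on the routed subset without additional cross-validation (apparent
    performance; optimistic by construction). Calibration uses ``n_bins``
    equal-width bins with empty bins omitted and no recalibration. Tasks with
    a single class are skipped with a warning.
    """
    X = np.asarray(features, dtype=float)
    out: dict[str, StageCTask] = {}
    for task, labels in task_labels.items():
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            logger.warning("stage C task %r has a single class; skipped", task)
            continue
        lr = LogisticRegression(max_iter=5000, class_weight="balanced",
                                random_state=seed)
        xgb = XGBClassifier(n_estimators=200, max_depth=3, learning_rate=0.1,
                            tree_method="hist", n_jobs=1, random_state=seed,
                            eval_metric="logloss")
        lr.fit(X, y)
        xgb.fit(X, y)
        probs = (lr.predict_proba(X)[:, 1] + xgb.predict_proba(X)[:, 1]) / 2.0
        frac_pos, mean_pred = calibration_curve(y, probs, n_bins=n_bins,
                                                strategy="uniform")
        calibration = pd.DataFrame({"mean_predicted": mean_pred,
                                    "observed_frequency": frac_pos})
        out[task] = StageCTask(task, probs, y, calibration)
    return out


# ---------------------------------------------------------------------------
# Metrics with subject-level bootstrap CIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageMetrics:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    npv: float
    ppv: float
    n_redrawn_resamples: int


def evaluate_stage(probs, labels, op: OperatingPoint, subject_ids=None,
                   n_boot: int = 2000, seed: int = 0) -> StageMetrics:
    """AUC and sensitivity at the stored operating point, with percentile 95%
    CIs from subject-level bootstrap resampling; NPV/PPV from the operating
    point's confusion counts. Degenerate (single-class) resamples are redrawn
    and counted.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    subjects = (np.asarray(subject_ids) if subject_ids is not None
                else np.arange(len(y)))
    uniq = np.unique(subjects)
    by_subject = {s: np.flatnonzero(subjects == s) for s in uniq}

    auc = float(roc_auc_score(y, probs))
    tp, fp, tn, fn = _confusion(probs, y, op.threshold)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")

    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    senss = np.empty(n_boot)
    redrawn = 0
    for i in range(n_boot):
        while True:
            take = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([by_subject[s] for s in take])
            if len(np.unique(y[idx])) == 2:
                break
            redrawn += 1
        aucs[i] = roc_auc_score(y[idx], probs[idx])
        btp, _, _, bfn = _confusion(probs[idx], y[idx], op.threshold)
        senss[i] = btp / (btp + bfn) if (btp + bfn) else np.nan
    if redrawn:
        logger.info("evaluate_stage: redrew %d degenerate bootstrap resamples", redrawn)

    return StageMetrics(
        auc=auc,
        auc_ci=(float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))),
        sensitivity=float(sens),
        sensitivity_ci=(float(np.nanpercentile(senss, 2.5)),
                        float(np.nanpercentile(senss, 97.5))),
        npv=op.npv,
        ppv=op.ppv,
        n_redrawn_resamples=redrawn,
    )


# ---------------------------------------------------------------------------
# Workload accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkloadEstimate:
    forwarded: int
    total: int
    minutes_per_exam: float
    forwarded_fraction: float
    minutes_per_1000: float
    hours_per_1000: float

    @property
    def minutes_per_1000_display(self) -> float:
        return round(self.minutes_per_1000, 1)

    @property
    def hours_per_1000_display(self) -> float:
        return round(self.hours_per_1000, 1)


def workload(forwarded: int, total: int, minutes_per_exam: float) -> WorkloadEstimate:
    """Verification workload: forwarded_fraction x per-exam minutes per 1000 scans."""
    if total <= 0:
        raise ValueError("total scan count must be positive")
    if not 0 <= forwarded <= total:
        raise ValueError("forwarded count must lie in [0, total]")
    if minutes_per_exam <= 0:
        raise ValueError("minutes per exam must be positive")
    frac = forwarded / total
    minutes = frac * 1000.0 * minutes_per_exam
    return WorkloadEstimate(
        forwarded=int(forwarded),
        total=int(total),
        minutes_per_exam=float(minutes_per_exam),
        forwarded_fraction=frac,
        minutes_per_1000=minutes,
        hours_per_1000=minutes / 60.0,
    )
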