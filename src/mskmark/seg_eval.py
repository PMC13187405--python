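"""Overlap metrics and the paired model-comparison statistical framework.

Dice and Jaccard are computed per slice, aggregated slice -> subject by the
mean and subject -> structure by the median, with dataset tail summaries
(median, 5th percentile, minimum) to expose worst-case behaviour. Models are
compared on the same subjects with a Friedman test followed by pairwise
Wilcoxon signed-rank tests under Benjamini-Hochberg FDR control at 5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

OVERLAP_COLUMNS = ["subject_id", "slice", "label_id", "dice", "jaccard"]


def dice_jaccard(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Dice = 2|A.B|/(|A|+|B|), Jaccard = |A.B|/|AuB| for binary arrays."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    inter = np.count_nonzero(pred & ref)
    a, b = np.count_nonzero(pred), np.count_nonzero(ref)
    union = a + b - inter
    dice = 2.0 * inter / (a + b) if (a + b) else 1.0
    jacc = inter / union if union else 1.0
    return dice, jacc


def overlap_metrics(pred: np.ndarray, ref: np.ndarray, label_id: int,
                    subject_id: str = "subject",
                    include_empty_reference: bool = False) -> pd.DataFrame:
    """Per-slice Dice/Jaccard records for one label of one subject.

    Slices whose reference is empty are excluded (they would otherwise
    inflate aggregates); set ``include_empty_reference`` to score them 1 when
    the prediction is also empty (0 otherwise) for sensitivity analyses.
    An empty prediction against a non-empty reference scores 0.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    if pred.ndim == 2:
        pred, ref = pred[None], ref[None]
    rows = []
    for k in range(pred.shape[0]):
        p = pred[k] == label_id
        r = ref[k] == label_id
        if not r.any():
            if not include_empty_reference:
                continue
            d, j = (1.0, 1.0) if not p.any() else (0.0, 0.0)
        else:
            d, j = dice_jaccard(p, r)
        rows.append((subject_id, k, label_id, d, j))
    return pd.DataFrame(rows, columns=OVERLAP_COLUMNS)


@dataclass(frozen=True)
class TailSummary:
    median: float
    p5: float
    minimum: float


def summarize_subjects(records: pd.DataFrame,
                       subject_agg: str = "mean") -> tuple[pd.DataFrame, dict[int, TailSummary]]:
    """Aggregate per-slice records to subject and dataset levels.

    Slice -> subject uses the mean of slice Dice per (subject, label)
    (``subject_agg='median'`` is available); dataset tails (median, linearly
    interpolated 5th percentile, minimum) are taken across subjects per label.
    """
    if records.empty:
        raise ValueError("no overlap records to summarize")
    agg = {"mean": "mean", "median": "median"}[subject_agg]
    per_subject = (
        records.groupby(["subject_id", "label_id"])[["dice", "jaccard"]]
        .agg(agg)
        .reset_index()
    )
    tails: dict[int, TailSummary] = {}
    for label_id, grp in per_subject.groupby("label_id"):
        d = grp["dice"].to_numpy()
        tails[int(label_id)] = TailSummary(
            median=float(np.median(d)),
            p5=float(np.percentile(d, 5)),  # linear interpolation between order stats
            minimum=float(np.min(d)),
        )
    return per_subject, tails


def structure_median(per_subject: pd.DataFrame) -> pd.Series:
    """Structure-level summary: median of per-subject Dice per label."""
    return per_subject.groupby("label_id")["dice"].median()


def compare_models(scores: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Friedman test then pairwise Wilcoxon signed-rank with BH FDR control.

    ``scores`` is subjects x models (one column per model, paired rows).
    Identical paired samples give Wilcoxon p = 1 (no evidence of difference).
    """
    if scores.isna().any().any():
        raise ValueError("unpaired input: scores contain missing values")
    if scores.shape[1] < 2:
        raise ValueError("need at least two models to compare")
    arrays = [scores[c].to_numpy(dtype=float) for c in scores.columns]

    if all(np.allclose(a, arrays[0]) for a in arrays[1:]):
        friedman_stat, friedman_p = 0.0, 1.0
    elif len(arrays) == 2:
        # the Friedman test needs >= 3 models; with two, the pairwise
        # Wilcoxon below is the whole comparison
        friedman_stat, friedman_p = float("nan"), float("nan")
    else:
        friedman_stat, friedman_p = stats.friedmanchisquare(*arrays)

    pairs, stats_w, raw_p = [], [], []
    for (name_a, a), (name_b, b) in combinations(zip(scores.columns, arrays), 2):
        diff = a - b
        if np.allclose(diff, 0.0):
            w, p = 0.0, 1.0
        else:
            w, p = stats.wilcoxon(a, b, alternative="two-sided")
        pairs.append((name_a, name_b))
        stats_w.append(float(w))
        raw_p.append(float(p))

    reject, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
    pairwise = pd.DataFrame({
        "model_a": [p[0] for p in pairs],
        "model_b": [p[1] for p in pairs],
        "wilcoxon_stat": stats_w,
        "p_raw": raw_p,
        "p_fdr": p_adj,
        "significant": reject,
    })
    return {
        "friedman_stat": float(friedman_stat),
        "friedman_p": float(friedman_p),
        "pairwise": pairwise,
        "alpha": alpha,
    }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (5% convention lives in caller)."""
    _, p_adj, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return p_adj
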