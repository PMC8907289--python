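"""Evaluation statistics for the binary grading task.

Grade II is the positive class throughout: sensitivity is the fraction of
Grade II subjects called II, specificity the fraction of Grade I called I.
Probability ties at the decision threshold are predicted positive
(deterministic, documented convention).  Undefined metric denominators yield
NaN — flagged, never silently 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "POSITIVE_CLASS",
    "ConfusionCounts",
    "Metrics",
    "confusion_from_predictions",
    "compute_metrics",
    "roc_auc",
    "fold_ranges",
    "stratified_accuracy",
    "misclassified_r_summary",
    "round_half_up",
    "table1_style_report",
]

POSITIVE_CLASS = "II"
GRADES = ("I", "II")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with halves away from zero (report convention)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with Grade II fixed as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    positive_class = POSITIVE_CLASS

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float

    def rounded(self, decimals: int = 2) -> "Metrics":
        return Metrics(
            *(
                round_half_up(v, decimals) if not math.isnan(v) else v
                for v in (self.accuracy, self.sensitivity, self.specificity)
            )
        )


def _validate_aligned(predictions, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} predictions vs {y.shape} labels")
    bad = set(np.unique(y)) - set(GRADES)
    if bad:
        raise ValueError(f"labels must be in {GRADES}, found {sorted(bad)}")
    return p, y


def confusion_from_predictions(
    predictions, labels, threshold: float = 0.5
) -> ConfusionCounts:
    """Tally confusion counts; p_grade2 >= threshold predicts Grade II."""
    p, y = _validate_aligned(predictions, labels)
    pred_pos = p >= threshold
    actual_pos = y == POSITIVE_CLASS
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & actual_pos)),
        fp=int(np.sum(pred_pos & ~actual_pos)),
        tn=int(np.sum(~pred_pos & ~actual_pos)),
        fn=int(np.sum(~pred_pos & actual_pos)),
    )


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity; undefined denominators give NaN."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero subjects")
    accuracy = (counts.tp + counts.tn) / counts.total
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sensitivity = counts.tp / pos if pos else math.nan
    specificity = counts.tn / neg if neg else math.nan
    return Metrics(accuracy, sensitivity, specificity)


def roc_auc(predictions, labels) -> tuple[float, pd.DataFrame]:
    """ROC by threshold sweep over unique scores; AUC by trapezoid.

    Equivalent to the Mann-Whitney rank statistic with ties counted 1/2.
    Raises on single-class input.
    """
    p, y = _validate_aligned(predictions, labels)
    pos = y == POSITIVE_CLASS
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-p, kind="stable")
    p_sorted, pos_sorted = p[order], pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # collapse ties: keep the last index of each distinct score
    distinct = np.nonzero(np.diff(p_sorted, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    thresholds = np.concatenate([[np.inf], p_sorted[distinct]])
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return auc, points


def fold_ranges(per_fold_metrics) -> dict[str, tuple[float, float]]:
    """(min, max) per metric over folds; NaN folds excluded with a warning."""
    if len(per_fold_metrics) == 0:
        raise ValueError("need at least one fold")
    by_metric: dict[str, list[float]] = {
        "accuracy": [], "sensitivity": [], "specificity": []
    }
    for m in per_fold_metrics:
        for name in by_metric:
            v = getattr(m, name)
            if math.isnan(v):
                warnings.warn(f"excluding undefined {name} for one fold", stacklevel=2)
            else:
                by_metric[name].append(v)
    out = {}
    for name, vals in by_metric.items():
        if not vals:
            raise ValueError(f"{name} undefined in every fold")
        out[name] = (min(vals), max(vals))
    return out


def stratified_accuracy(
    predictions, labels, strata, threshold: float = 0.5, decimals: int = 2
) -> pd.DataFrame:
    """Per-stratum (n, n_correct, accuracy); empty strata are dropped with a
    warning.  Accuracy is reported both raw and rounded."""
    p, y = _validate_aligned(predictions, labels)
    strata = np.asarray(strata)
    if strata.shape != y.shape:
        raise ValueError("every subject must carry a stratum label")
    pred = np.where(p >= threshold, "II", "I")
    rows = []
    for s in pd.unique(strata):
        sel = strata == s
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"stratum {s!r} is empty; excluded", stacklevel=2)
            continue
        n_correct = int(np.sum(pred[sel] == y[sel]))
        acc = n_correct / n
        rows.append(
            {
                "stratum": s,
                "n": n,
                "n_correct": n_correct,
                "accuracy": acc,
                "accuracy_rounded": round_half_up(acc, decimals),
            }
        )
    return pd.DataFrame(rows)


def misclassified_r_summary(
    predictions, labels, r_values, threshold: float = 0.5
) -> dict:
    """R values of misclassified subjects split by true grade, plus cohort
    summary statistics (mean, sample SD, median, IQR = Q3 - Q1 with
    linear-interpolation quantiles)."""
    p, y = _validate_aligned(predictions, labels)
    r = np.asarray(r_values, dtype=float)
    if r.shape != y.shape:
        raise ValueError("r_values must align with predictions")
    pred = np.where(p >= threshold, "II", "I")
    wrong = pred != y
    q1, q3 = np.percentile(r, [25, 75])
    return {
        "misclassified_grade1_r": sorted(float(v) for v in r[wrong & (y == "I")]),
        "misclassified_grade2_r": sorted(float(v) for v in r[wrong & (y == "II")]),
        "cohort_mean": float(r.mean()),
        "cohort_sd": float(r.std(ddof=1)) if r.size > 1 else math.nan,
        "cohort_median": float(np.median(r)),
        "cohort_iqr": float(q3 - q1),
    }


def table1_style_report(
    variant_predictions: dict[str, pd.DataFrame], decimals: int = 2
) -> tuple[str, dict]:
    """Summary table over model variants from prediction DataFrames with
    columns (subject_id, grade, p_grade2, fold).

    Returns the plain-text table and a JSON-serializable payload with both
    rounded and full-precision values.
    """
    lines = [
        f"{'model':<10}{'accuracy':>16}{'sensitivity':>18}{'specificity':>18}{'auc':>8}",
        "-" * 70,
    ]
    payload = {}
    for name, df in variant_predictions.items():
        counts = confusion_from_predictions(df["p_grade2"], df["grade"])
        metrics = compute_metrics(counts)
        auc, _ = roc_auc(df["p_grade2"], df["grade"])
        per_fold = []
        for _, fold_df in df.groupby("fold"):
            per_fold.append(
                compute_metrics(
                    confusion_from_predictions(fold_df["p_grade2"], fold_df["grade"])
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranges = fold_ranges(per_fold)
        rounded = metrics.rounded(decimals)

        def _fmt(value: float, metric: str) -> str:
            lo, hi = ranges[metric]
            return (
                f"{value:.{decimals}f} "
                f"({round_half_up(lo, decimals):.{decimals}f}-"
                f"{round_half_up(hi, decimals):.{decimals}f})"
            )

        lines.append(
            f"{name:<10}{_fmt(rounded.accuracy, 'accuracy'):>16}"
            f"{_fmt(rounded.sensitivity, 'sensitivity'):>18}"
            f"{_fmt(rounded.specificity, 'specificity'):>18}"
            f"{round_half_up(auc, decimals):>8.{decimals}f}"
        )
        payload[name] = {
            "confusion": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
            "accuracy": metrics.accuracy,
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "auc": auc,
            "fold_ranges": {k: list(v) for k, v in ranges.items()},
            "rounded": {
                "accuracy": rounded.accuracy,
                "sensitivity": rounded.sensitivity,
                "specificity": rounded.specificity,
                "auc": round_half_up(auc, decimals),
            },
        }
    return "\n".join(lines), payload
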