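"""Evaluation: MAE, one-vs-rest ROC-AUC, subgroup analysis, and the
cardiologist-agreement arithmetic.

MAE treats the four critical values as integers, so it penalizes a
two-level miss twice as much as a one-level miss — the property that makes
it the natural headline metric for an ordinal target. AUC is computed
one-vs-rest per class from the predicted class probabilities (midrank tie
handling); the macro score is the unweighted mean over classes present in
the labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["mae", "roc_auc_ovr", "roc_points", "subgroup_eval",
           "agreement_stats", "EvalReport"]


def mae(predictions, labels) -> float:
    """Mean absolute error between predicted and true critical values."""
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.size == 0 or p.shape != y.shape:
        raise ValueError(f"need equal-length nonempty inputs, got "
                         f"{p.shape} vs {y.shape}")
    return float(np.mean(np.abs(p - y)))


def roc_auc_ovr(class_probabilities, labels):
    """Per-class one-vs-rest ROC-AUC and the macro (unweighted) average.

    ``class_probabilities`` is (N, 4). A class absent from ``labels`` (or
    covering all of them) has no defined AUC: its entry is NaN and it is
    excluded from the macro average, with a warning.
    """
    q = np.asarray(class_probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if q.ndim != 2 or q.shape[1] != 4 or q.shape[0] != y.size:
        raise ValueError(f"expected (n, 4) probabilities aligned with labels, "
                         f"got {q.shape} and {y.shape}")
    aucs = np.full(4, np.nan)
    for c in range(4):
        pos = y == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} absent (or alone) in labels; its AUC "
                          f"is undefined and excluded from the macro average",
                          stacklevel=2)
            continue
        aucs[c] = roc_auc_score(pos, q[:, c])
    macro = float(np.nanmean(aucs)) if np.isfinite(aucs).any() else float("nan")
    return aucs, macro


def roc_points(scores, positives):
    """(fpr, tpr, thresholds) of one one-vs-rest curve, for export/plotting."""
    fpr, tpr, thr = roc_curve(np.asarray(positives, bool), scores)
    return fpr, tpr, thr


@dataclass
class EvalReport:
    """Metrics for the full test set and the sex / age subgroups."""

    rows: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.rows, orient="index")

    def to_dict(self) -> dict:
        return {k: dict(v) for k, v in self.rows.items()}


def _metrics_row(pred, probs, labels) -> dict:
    row = {"n": int(len(labels))}
    row["mae"] = mae(pred, labels) if len(labels) else float("nan")
    if probs is not None and len(labels):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aucs, macro = roc_auc_ovr(probs, labels)
        row.update({f"auc_{c}": float(aucs[c]) for c in range(4)})
        row["macro_auc"] = macro
    return row


def subgroup_eval(predictions, class_probabilities, labels,
                  metadata: pd.DataFrame, age_cut: float = 65.0) -> EvalReport:
    """Evaluate on the full set and on sex (male/female) and age
    (< cut, >= cut) subgroups, reusing the same predictions.

    ``metadata`` rows align positionally with the predictions and carry
    ``sex`` ("male"/"female") and ``age`` columns. Records with missing
    sex or age are excluded from that stratification only (their count is
    reported under ``excluded_sex`` / ``excluded_age`` of the full row).
    """
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    probs = (None if class_probabilities is None
             else np.asarray(class_probabilities))
    if len(metadata) != len(y):
        raise ValueError("metadata must align with predictions")
    sex = metadata["sex"].astype("string").str.lower()
    age = pd.to_numeric(metadata["age"], errors="coerce")
    report = EvalReport()
    report.rows["full"] = _metrics_row(pred, probs, y)
    report.rows["full"]["excluded_sex"] = int(sex.isna().sum())
    report.rows["full"]["excluded_age"] = int(age.isna().sum())

    def sub(mask):
        m = np.asarray(mask.fillna(False), dtype=bool)
        return _metrics_row(pred[m], None if probs is None else probs[m], y[m])

    report.rows["male"] = sub(sex == "male")
    report.rows["female"] = sub(sex == "female")
    report.rows[f"age<{age_cut:g}"] = sub(age < age_cut)
    report.rows[f"age>={age_cut:g}"] = sub(age >= age_cut)
    return report


def agreement_stats(n_wrong: int, n_agree_model: int, n_agree_original: int):
    """Reviewer-agreement arithmetic over the model's wrongly predicted cases.

    Given the number of wrong predictions re-read by an independent
    cardiologist, the number where the reviewer sides with the model and the
    number where the reviewer sides with the original labels, returns
    (model-reviewer %, original-reviewer %, residual) with percentages
    rounded to 2 decimals and residual = cases where the reviewer disagreed
    with both.
    """
    if n_wrong <= 0:
        raise ValueError("n_wrong must be positive")
    if n_agree_model + n_agree_original > n_wrong:
        raise ValueError("agreement counts exceed the number of wrong cases")
    pct_model = round(100.0 * n_agree_model / n_wrong, 2)
    pct_original = round(100.0 * n_agree_original / n_wrong, 2)
    residual = n_wrong - n_agree_model - n_agree_original
    return pct_model, pct_original, residual
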