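"""Class-conditional inductive conformal prediction.

Each fold's validation set doubles as a calibration set: every calibration
sample contributes a nonconformity score 1 - p(true class) to its own
class's list (a Mondrian / class-conditional construction). For a test
sample, each class label receives a p-value by rank of its nonconformity
score among the same-class calibration scores, with the +1 correction and
ties counted as >=:

    p_c = (#{calibration scores of class c >= s_c} + 1) / (n_c + 1)

The prediction set at significance alpha contains every class with p-value
strictly greater than alpha; under exchangeability the true label is in the
set with probability at least 1 - alpha. Samples with a singleton set form
the *certain* cohort; empty or two-label sets form the *uncertain* cohort.
No randomized tie smoothing is used, so results are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import FoldResult
from .exceptions import DegenerateDataError
from .metrics import compute_metrics
from .table import FeatureTable

DEFAULT_ALPHA = 0.05


def nonconformity(probability):
    """Score 1 - p(class); 0 when fully conforming, 1 when maximally not."""
    p = np.asarray(probability, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    out = 1.0 - p
    return out if out.ndim else float(out)


@dataclass
class ConformalCalibration:
    """Per-class calibration score lists plus the significance level."""

    scores_by_class: dict[int, np.ndarray]
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        for c in (0, 1):
            if c not in self.scores_by_class or len(self.scores_by_class[c]) == 0:
                raise DegenerateDataError(
                    f"calibration set has no samples of class {c}"
                )


def calibrate(
    probabilities_pos: np.ndarray, labels: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> ConformalCalibration:
    """Build class-conditional calibration from positive-class probabilities."""
    p = np.asarray(probabilities_pos, float)
    y = np.asarray(labels, int)
    scores = {
        1: nonconformity(p[y == 1]),
        0: nonconformity(1.0 - p[y == 0]),
    }
    return ConformalCalibration(scores, alpha)


def conformal_pvalue(score: float, calibration_scores: np.ndarray) -> float:
    """Rank-based p-value with the +1 correction; ties counted as >=."""
    cal = np.asarray(calibration_scores, float)
    if cal.size == 0:
        raise DegenerateDataError("empty calibration score list")
    return (int((cal >= score).sum()) + 1) / (cal.size + 1)


def prediction_sets(
    probabilities_pos: np.ndarray,
    calibration: ConformalCalibration,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Per-sample p-values, prediction set and certain/uncertain cohort.

    Class c enters the set iff its p-value exceeds alpha (strict), so empty
    sets are possible when both labels are implausible.
    """
    alpha = calibration.alpha if alpha is None else alpha
    p = np.asarray(probabilities_pos, float)
    s1 = nonconformity(p)
    s0 = nonconformity(1.0 - p)
    cal0, cal1 = calibration.scores_by_class[0], calibration.scores_by_class[1]
    pv0 = np.array([conformal_pvalue(s, cal0) for s in s0])
    pv1 = np.array([conformal_pvalue(s, cal1) for s in s1])
    in0, in1 = pv0 > alpha, pv1 > alpha
    set_code = np.select(
        [in0 & in1, in0 & ~in1, ~in0 & in1], ["{0,1}", "{0}", "{1}"], default="{}"
    )
    return pd.DataFrame(
        {
            "p_value_0": pv0,
            "p_value_1": pv1,
            "set": set_code,
            "set_size": in0.astype(int) + in1.astype(int),
            "cohort": np.where(in0 ^ in1, "certain", "uncertain"),
        }
    )


def fold_conformal(
    fold: FoldResult, table: FeatureTable, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Conformal records for one fold's test samples.

    Calibration probabilities come from the fold's winning model evaluated
    on its validation (= calibration) set, exactly as fitted in the main
    pipeline.
    """
    calibration = calibrate(
        fold.val_probabilities, table.labels.loc[fold.val_ids].to_numpy(int), alpha
    )
    sets = prediction_sets(fold.records["probability"].to_numpy(float), calibration)
    sets.insert(0, "sample_id", fold.records["sample_id"].to_numpy())
    sets.insert(1, "fold", fold.iteration)
    return sets


def conformal_table(
    folds: list[FoldResult], table: FeatureTable, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Pooled conformal records across all folds."""
    return pd.concat([fold_conformal(f, table, alpha) for f in folds], ignore_index=True)


def cohort_metrics(conformal: pd.DataFrame, records: pd.DataFrame) -> dict:
    """Per-cohort composition and performance (certain vs uncertain).

    Counts successes (label 0) and failures (label 1) per cohort and
    computes accuracy/AUC/sensitivity/specificity at each record's own fold
    threshold. Empty cohorts report zero counts with metrics undefined.
    """
    merged = records.merge(
        conformal[["sample_id", "cohort", "set", "p_value_0", "p_value_1"]],
        on="sample_id",
        validate="one_to_one",
    )
    out: dict = {"total": int(len(merged))}
    for cohort in ("certain", "uncertain"):
        sub = merged[merged["cohort"] == cohort]
        entry = {
            "n": int(len(sub)),
            "successes_0": int((sub["true"] == 0).sum()),
            "failures_1": int((sub["true"] == 1).sum()),
        }
        if len(sub):
            entry["metrics"] = compute_metrics(sub).to_dict()
        else:
            entry["metrics"] = None
        out[cohort] = entry
    return out


def coverage(conformal: pd.DataFrame, true_labels) -> float:
    """Fraction of samples whose true label lies in the prediction set."""
    y = np.asarray(true_labels, int)
    if len(y) != len(conformal):
        raise ValueError("label vector and conformal frame length mismatch")
    sets = conformal["set"].to_numpy()
    covered = np.array([str(label) in s for label, s in zip(y, sets)])
    return float(covered.mean())
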