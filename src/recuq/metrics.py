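"""Confusion-matrix and ranking metrics over prediction records.

Predictions are kept as one record per test sample (probability, the fold's
decision threshold, predicted and true label), so metrics can be computed on
any subset — a fold, the pooled test set, an uncertainty-filtered cohort.
Thresholded metrics use each record's own threshold; ranking metrics (AUC,
PRAUC) use the raw probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import DegenerateDataError

#: Columns of a prediction-record frame.
RECORD_COLUMNS = ("sample_id", "fold", "probability", "threshold", "predicted", "true")


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1; 1 when perfect, 0 at chance."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0,1]")
    return sensitivity + specificity - 1.0


@dataclass
class MetricsReport:
    """Confusion counts plus the seven headline metrics.

    Ratios that are undefined on the subset (one-class AUC, empty
    denominators) are NaN and listed in ``undefined``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    auc: float
    prauc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def youden(self) -> float:
        return youden_index(self.sensitivity, self.specificity)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        d["n"] = self.n
        return d


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def compute_metrics(records: pd.DataFrame, positive_label: int = 1) -> MetricsReport:
    """Metrics over a frame of prediction records.

    Each record is thresholded at its own ``threshold`` (folds carry their
    own Youden-optimal cut); AUC uses the rank statistic with tie
    correction, PRAUC is average precision. A single-class subset keeps its
    confusion metrics but flags AUC/PRAUC undefined.
    """
    if len(records) == 0:
        raise DegenerateDataError("no prediction records")
    true = (records["true"].to_numpy() == positive_label).astype(int)
    prob = records["probability"].to_numpy(float)
    pred = (prob >= records["threshold"].to_numpy(float)).astype(int)

    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())

    undefined: list[str] = []
    if true.min() == true.max():
        auc = prauc = float("nan")
        undefined += ["auc", "prauc"]
    else:
        auc = float(roc_auc_score(true, prob))
        prauc = float(average_precision_score(true, prob))

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    for name, v in (("sensitivity", sens), ("specificity", spec), ("ppv", ppv), ("npv", npv)):
        if np.isnan(v):
            undefined.append(name)

    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(true),
        auc=auc, prauc=prauc,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        undefined=tuple(undefined),
    )


def metrics_from_counts(tn: int, fp: int, fn: int, tp: int) -> MetricsReport:
    """Confusion-only report from raw counts (AUC/PRAUC undefined)."""
    n = tn + fp + fn + tp
    if n == 0:
        raise DegenerateDataError("empty confusion table")
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        auc=float("nan"), prauc=float("nan"),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        undefined=("auc", "prauc"),
    )
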