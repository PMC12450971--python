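"""Candidate classifiers, threshold optimization, fold-level model selection.

Five probability-producing families compete per fold: logistic regression
(LR), support-vector classifiers with linear (SVC) and degree-3 polynomial
(SVCP) kernels, a gradient-boosted additive-tree classifier (GBC), and
XGBoost (XGB). Each candidate's decision threshold is tuned on the
validation fold by an exhaustive Youden scan of the grid {0.01, ..., 0.50};
the candidate with the highest validation Youden index wins the fold, ties
broken by the simplest family first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .exceptions import DegenerateDataError
from .metrics import youden_index

#: Family codes in tie-break order (simpler families first).
FAMILIES: tuple[str, ...] = ("LR", "SVC", "SVCP", "GBC", "XGB")

#: Threshold grid: half-open (0, 0.5] in steps of 0.01. tau = 0 would predict
#: all-positive and is excluded; 0.50 is included.
THRESHOLD_GRID: np.ndarray = np.round(np.arange(1, 51) * 0.01, 2)


def calibrated_svc(kernel: str = "linear", degree: int = 3, seed: int = 0):
    """SVC with Platt-style probability calibration on the training data.

    Calibration folds are unshuffled, so the fit is deterministic
    irrespective of seed; the seed is kept for interface symmetry.
    """
    base = SVC(kernel=kernel, degree=degree, random_state=seed)
    return CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)


def fit_candidate(family: str, train_values: pd.DataFrame, train_labels: pd.Series, seed: int):
    """Fit one candidate family; deterministic given seed and inputs."""
    y = train_labels.to_numpy(int)
    if y.min() == y.max():
        raise DegenerateDataError(f"{family}: single-class training labels")
    X = train_values.to_numpy(float)
    if family == "LR":
        model = LogisticRegression(max_iter=5000)
    elif family == "SVC":
        model = calibrated_svc("linear", seed=seed)
    elif family == "SVCP":
        model = calibrated_svc("poly", degree=3, seed=seed)
    elif family == "GBC":
        model = GradientBoostingClassifier(random_state=seed)
    elif family == "XGB":
        model = XGBClassifier(
            objective="binary:logistic",
            eval_metric="logloss",
            random_state=seed,
            verbosity=0,
            n_jobs=1,
        )
    else:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    model.fit(X, y)
    return model


def optimize_threshold(
    probabilities: np.ndarray, labels: np.ndarray, grid: np.ndarray = THRESHOLD_GRID
) -> tuple[float, float]:
    """Exhaustive Youden scan over the threshold grid.

    Predicted positive iff p >= tau. Returns (tau, J at tau); ties take the
    largest tau among maximizers (favoring specificity under imbalance).
    """
    labels = np.asarray(labels, int)
    if labels.min() == labels.max():
        raise DegenerateDataError("one-class validation set: threshold undefined")
    probabilities = np.asarray(probabilities, float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    best_tau, best_j = None, -np.inf
    for tau in grid:
        pred = probabilities >= tau
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        j = youden_index(float(sens), float(spec))
        if j >= best_j:  # >= keeps the largest tau among ties
            best_tau, best_j = float(tau), j
    return best_tau, best_j


@dataclass
class FittedFoldModel:
    """A trained candidate with its selected features and tuned threshold."""

    family: str
    feature_names: list[str]
    threshold: float
    validation_youden: float
    standardizer: object  # Standardizer frozen on the training fold
    estimator: object = field(repr=False)
    flags: tuple[str, ...] = ()

    def predict_proba(self, values: pd.DataFrame) -> np.ndarray:
        """Positive-class probability from raw-scale feature values."""
        X = self.standardizer.transform(values[self.feature_names])
        return self.estimator.predict_proba(X.to_numpy(float))[:, 1]

    def predict(self, values: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(values) >= self.threshold).astype(int)


def select_best_model(candidates: list[FittedFoldModel]) -> FittedFoldModel:
    """Highest validation Youden; exact ties go to the simpler family."""
    usable = [c for c in candidates if not np.isnan(c.validation_youden)]
    if not usable:
        raise DegenerateDataError("every candidate model is degenerate")

    def key(c: FittedFoldModel):
        return (-c.validation_youden, FAMILIES.index(c.family))

    return min(usable, key=key)
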