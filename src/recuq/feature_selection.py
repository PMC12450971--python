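"""Per-fold radiomic feature selection.

Two stages, run on training (and validation) data only:

1. Redundancy filter — greedy removal of pairwise-correlated radiomic
   features until no retained pair exceeds |Pearson r| = 0.7. At each step
   the currently most-correlated offending pair is found and the member with
   the higher mean absolute correlation to all currently retained features
   is dropped.
2. LASSO candidate sets — an L1-penalized logistic path over a descending
   geometric grid of penalties yields candidate supports of 6-10 radiomic
   features; each candidate is scored by fitting a linear SVC on the
   training data and evaluating the Youden index on the validation set at
   the 0.5 probability cut. The best candidate is combined with all
   clinical variables downstream.

Features are z-scored with training-fold statistics before either stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .exceptions import DegenerateDataError
from .metrics import youden_index
from .modeling import calibrated_svc

CORRELATION_THRESHOLD = 0.7
CANDIDATE_SIZE_RANGE = (6, 10)
LASSO_GRID_POINTS = 50
LASSO_GRID_DECADES = 1e3  # penalty sweeps from the all-zero value down by 10^3


@dataclass
class CandidateFeatureSet:
    """A LASSO support of radiomic features with its inner validation score."""

    radiomic_names: tuple[str, ...]
    lasso_strength: float
    validation_youden: float = float("nan")
    flags: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.radiomic_names)


@dataclass
class Standardizer:
    """Column z-scoring frozen on training data; zero-variance SD -> 1."""

    mean: pd.Series
    scale: pd.Series

    @classmethod
    def fit(cls, values: pd.DataFrame) -> "Standardizer":
        mean = values.mean()
        scale = values.std(ddof=0).replace(0.0, 1.0)
        return cls(mean, scale)

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return (values - self.mean[values.columns]) / self.scale[values.columns]


def correlation_filter(
    values: pd.DataFrame, threshold: float = CORRELATION_THRESHOLD
) -> list[str]:
    """Greedily prune features until no retained pair has |r| > threshold.

    Deterministic and invariant to input column order: columns are processed
    in canonical (sorted-name) order and ties break by name. Zero-variance
    columns are removed up front (their correlation is undefined). Returns
    the kept names in the original column order.
    """
    if len(values) < 2:
        raise DegenerateDataError("correlation filter needs at least 2 samples")
    original_order = list(values.columns)
    cols = sorted(original_order)
    if len(cols) == 1:
        return original_order

    variances = values.var(ddof=0)
    cols = [c for c in cols if variances[c] > 0.0]  # r undefined on constants
    if len(cols) <= 1:
        return [c for c in original_order if c in set(cols)]

    corr = np.abs(np.corrcoef(values[cols].to_numpy(float), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)
    alive = np.ones(len(cols), dtype=bool)

    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        live_idx = np.flatnonzero(alive)
        # most-correlated offending pair; ties -> first in canonical order
        i_rel, j_rel = np.unravel_index(int(np.argmax(sub)), sub.shape)
        i, j = live_idx[i_rel], live_idx[j_rel]
        if i > j:
            i, j = j, i
        # mean |r| to all other currently retained features
        denom = alive.sum() - 1
        mean_i = corr[i, alive].sum() / denom
        mean_j = corr[j, alive].sum() / denom
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # tie: drop the canonically later name
        alive[drop] = False

    kept = {cols[k] for k in np.flatnonzero(alive)}
    return [c for c in original_order if c in kept]


def _lasso_penalty_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest L1 penalty (summed-loss convention) zeroing all coefficients."""
    resid = y - y.mean()
    return float(np.abs(X.T @ resid).max())


def lasso_candidate_sets(
    train_values: pd.DataFrame,
    train_labels: pd.Series,
    size_range: tuple[int, int] = CANDIDATE_SIZE_RANGE,
    grid_points: int = LASSO_GRID_POINTS,
) -> list[CandidateFeatureSet]:
    """Sweep the L1-logistic path and collect distinct supports of 6-10 features.

    The penalty grid is geometric with ``grid_points`` values descending from
    the smallest penalty that zeroes every coefficient down by a factor of
    10^3. Duplicate supports from adjacent penalties are deduplicated (the
    largest penalty producing each support is recorded). When no penalty
    yields a support inside ``size_range``, the support closest in size is
    returned with a ``size_fallback`` flag.
    """
    y = train_labels.to_numpy(int)
    if y.min() == y.max():
        raise DegenerateDataError("all training labels identical; LASSO path undefined")
    X = train_values.to_numpy(float)
    lam_max = _lasso_penalty_max(X, y)
    if lam_max == 0.0:
        raise DegenerateDataError("degenerate design: all penalty gradients zero")
    lambdas = np.geomspace(lam_max, lam_max / LASSO_GRID_DECADES, grid_points)

    lo, hi = size_range
    seen: dict[frozenset, CandidateFeatureSet] = {}
    fallback: CandidateFeatureSet | None = None
    cols = list(train_values.columns)
    for lam in lambdas:
        model = LogisticRegression(
            l1_ratio=1, C=1.0 / lam, solver="liblinear", max_iter=2000
        )
        model.fit(X, y)
        support = frozenset(np.flatnonzero(model.coef_[0] != 0.0))
        size = len(support)
        if size == 0:
            continue
        names = tuple(sorted(cols[k] for k in support))
        cand = CandidateFeatureSet(names, lasso_strength=float(lam))
        if lo <= size <= hi:
            seen.setdefault(support, cand)
        elif fallback is None or _range_distance(size, size_range) < _range_distance(
            fallback.size, size_range
        ):
            fallback = CandidateFeatureSet(names, float(lam), flags=("size_fallback",))

    if seen:
        return list(seen.values())
    if fallback is not None:
        return [fallback]
    raise DegenerateDataError("LASSO path produced no non-empty support")


def _range_distance(size: int, size_range: tuple[int, int]) -> int:
    lo, hi = size_range
    return max(lo - size, size - hi, 0)


def score_candidate_set(
    candidate: CandidateFeatureSet,
    train_values: pd.DataFrame,
    train_labels: pd.Series,
    val_values: pd.DataFrame,
    val_labels: pd.Series,
    seed: int = 0,
) -> CandidateFeatureSet:
    """Inner scoring: linear SVC on the candidate's radiomic columns.

    Clinical variables do not participate at this stage. The Youden index is
    computed on the validation set at the 0.5 probability cut. A one-class
    validation set leaves the score NaN with a ``one_class_validation`` flag.
    """
    if candidate.size == 0:
        raise DegenerateDataError("empty candidate feature set")
    names = list(candidate.radiomic_names)
    yv = val_labels.to_numpy(int)
    if yv.min() == yv.max():
        return CandidateFeatureSet(
            candidate.radiomic_names, candidate.lasso_strength,
            float("nan"), candidate.flags + ("one_class_validation",),
        )
    svc = calibrated_svc("linear", seed=seed)
    svc.fit(train_values[names].to_numpy(float), train_labels.to_numpy(int))
    prob = svc.predict_proba(val_values[names].to_numpy(float))[:, 1]
    pred = (prob >= 0.5).astype(int)
    sens = ((pred == 1) & (yv == 1)).sum() / (yv == 1).sum()
    spec = ((pred == 0) & (yv == 0)).sum() / (yv == 0).sum()
    return CandidateFeatureSet(
        candidate.radiomic_names, candidate.lasso_strength,
        youden_index(float(sens), float(spec)), candidate.flags,
    )


def select_feature_set(
    candidates: list[CandidateFeatureSet], clinical_names: list[str]
) -> tuple[CandidateFeatureSet, list[str]]:
    """Argmax of validation Youden; ties -> smaller set, then first name.

    Returns the winning candidate and the final feature list (winner's
    radiomics plus every clinical variable).
    """
    if not candidates:
        raise DegenerateDataError("no candidate feature sets to select from")

    def key(c: CandidateFeatureSet):
        score = c.validation_youden
        score = -np.inf if np.isnan(score) else score
        return (-score, c.size, c.radiomic_names)

    winner = min(candidates, key=key)
    final = list(winner.radiomic_names) + list(clinical_names)
    return winner, final
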