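"""Five-fold rotation with per-fold selection, pooled evaluation, repeats.

Each of the five iterations designates one fold as validation, the next as
test, and trains on the remaining three; across the rotation every fold
serves as validation exactly once and as test exactly once, so the pooled
test predictions cover every sample exactly once per seed. All feature
selection and model selection see only training and validation data; test
folds are touched once, at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import DegenerateDataError
from .feature_selection import (
    Standardizer,
    correlation_filter,
    lasso_candidate_sets,
    score_candidate_set,
    select_feature_set,
)
from .metrics import MetricsReport, compute_metrics
from .modeling import FAMILIES, FittedFoldModel, fit_candidate, optimize_threshold, select_best_model
from .table import CLINICAL_GROUP, FeatureTable, group_of

N_FOLDS = 5


def _child_seeds(seed: int, *key: int, n: int = 16) -> list[int]:
    """Stable stream of sub-seeds (< 2^31) keyed by (seed, *key)."""
    ss = np.random.SeedSequence([int(seed), *map(int, key)])
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


@dataclass
class CVPlan:
    """Fold assignment plus the five (train, validation, test) role triples."""

    seed: int
    fold_of_sample: pd.Series  # sample_id -> fold index 0..4
    iterations: list[tuple[tuple[int, ...], int, int]]

    def ids_for(self, table: FeatureTable, iteration: int):
        train_folds, val_fold, test_fold = self.iterations[iteration]
        f = self.fold_of_sample
        train = f.index[f.isin(train_folds)]
        val = f.index[f == val_fold]
        test = f.index[f == test_fold]
        return train, val, test


def make_cv_plan(labels: pd.Series, seed: int, stratify: bool = True) -> CVPlan:
    """Assign samples to five near-equal folds; deterministic given seed.

    Stratified by default so every fold carries both classes at realistic
    prevalence. Iteration i uses fold i as validation and fold (i+1) mod 5
    as test.
    """
    n = len(labels)
    if n < 2 * N_FOLDS:
        raise DegenerateDataError(f"need at least {2 * N_FOLDS} samples for {N_FOLDS} folds")
    splitter_cls = StratifiedKFold if stratify else KFold
    splitter = splitter_cls(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    y = labels.to_numpy(int)
    fold = np.empty(n, dtype=int)
    for k, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        fold[test_idx] = k
    iterations = [
        (tuple(f for f in range(N_FOLDS) if f not in (i, (i + 1) % N_FOLDS)), i, (i + 1) % N_FOLDS)
        for i in range(N_FOLDS)
    ]
    return CVPlan(seed, pd.Series(fold, index=labels.index, name="fold"), iterations)


@dataclass
class FoldResult:
    """Everything the downstream uncertainty layers need from one iteration."""

    iteration: int
    winner: FittedFoldModel
    candidates: list[FittedFoldModel]
    selection_report: dict
    records: pd.DataFrame  # test-fold prediction records
    val_ids: pd.Index
    val_probabilities: np.ndarray  # winner's probabilities on validation
    train_radiomic_sd: pd.Series  # raw-scale SDs for TTA noise


def run_iteration(
    table: FeatureTable,
    plan: CVPlan,
    iteration: int,
    seed: int,
    filter_scope: str = "fold",
    global_kept: list[str] | None = None,
) -> FoldResult:
    """Filter -> LASSO -> candidate scoring -> five models -> fold winner.

    ``filter_scope='global'`` reuses a correlation filter computed once on
    the full table (``global_kept``); the default recomputes it on the
    training fold only, which is the leak-free reading.
    """
    train_ids, val_ids, test_ids = plan.ids_for(table, iteration)
    seeds = _child_seeds(seed, iteration)
    rad_cols = table.radiomic_columns
    clin_cols = table.clinical_columns

    train_vals = table.values.loc[train_ids]
    std = Standardizer.fit(train_vals)
    z_train = std.transform(train_vals)
    z_val = std.transform(table.values.loc[val_ids])
    y_train = table.labels.loc[train_ids]
    y_val = table.labels.loc[val_ids]

    if filter_scope == "global":
        if global_kept is None:
            raise ValueError("filter_scope='global' requires global_kept")
        kept = list(global_kept)
    elif filter_scope == "fold":
        kept = correlation_filter(z_train[rad_cols])
    else:
        raise ValueError(f"filter_scope must be 'fold' or 'global', got {filter_scope!r}")

    candidates = lasso_candidate_sets(z_train[kept], y_train)
    scored = [
        score_candidate_set(c, z_train, y_train, z_val, y_val, seed=seeds[0])
        for c in candidates
    ]
    winner_set, final_features = select_feature_set(scored, clin_cols)

    fold_models: list[FittedFoldModel] = []
    yv = y_val.to_numpy(int)
    for k, family in enumerate(FAMILIES):
        est = fit_candidate(family, z_train[final_features], y_train, seed=seeds[1 + k])
        probs = est.predict_proba(z_val[final_features].to_numpy(float))[:, 1]
        try:
            tau, j = optimize_threshold(probs, yv)
            flags: tuple[str, ...] = ()
        except DegenerateDataError:
            tau, j, flags = 0.5, float("nan"), ("one_class_validation",)
        fold_models.append(
            FittedFoldModel(family, final_features, tau, j, std, est, flags)
        )

    best = select_best_model(fold_models)

    test_vals = table.values.loc[test_ids]
    p_test = best.predict_proba(test_vals)
    test_fold = plan.iterations[iteration][2]
    records = pd.DataFrame(
        {
            "sample_id": test_ids,
            "fold": iteration,
            "test_fold": test_fold,
            "probability": p_test,
            "threshold": best.threshold,
            "predicted": (p_test >= best.threshold).astype(int),
            "true": table.labels.loc[test_ids].to_numpy(int),
        }
    )

    report = {
        "iteration": iteration,
        "n_radiomic": len(rad_cols),
        "n_surviving_filter": len(kept),
        "filter_scope": filter_scope,
        "candidates": [
            {
                "features": list(c.radiomic_names),
                "lasso_strength": c.lasso_strength,
                "validation_youden": c.validation_youden,
                "flags": list(c.flags),
            }
            for c in scored
        ],
        "winning_set": list(winner_set.radiomic_names),
        "final_features": final_features,
        "model_card": {
            m.family: {"threshold": m.threshold, "validation_youden": m.validation_youden}
            for m in fold_models
        },
        "best_family": best.family,
    }
    return FoldResult(
        iteration=iteration,
        winner=best,
        candidates=fold_models,
        selection_report=report,
        records=records,
        val_ids=val_ids,
        val_probabilities=best.predict_proba(table.values.loc[val_ids]),
        train_radiomic_sd=train_vals[rad_cols].std(ddof=0),
    )


@dataclass
class SeedResult:
    """One full pass of the pipeline for a single random state."""

    seed: int
    plan: CVPlan
    folds: list[FoldResult]
    records: pd.DataFrame = field(repr=False)
    metrics: MetricsReport | None = None
    importance: dict | None = None


def run_pipeline(
    table: FeatureTable,
    seed: int,
    stratify: bool = True,
    filter_scope: str = "fold",
    importance: bool = True,
) -> SeedResult:
    """Full five-fold rotation for one seed; pools test records and metrics."""
    plan = make_cv_plan(table.labels, seed, stratify=stratify)
    global_kept = None
    if filter_scope == "global":
        std_all = Standardizer.fit(table.values)
        global_kept = correlation_filter(std_all.transform(table.values)[table.radiomic_columns])
    folds = [
        run_iteration(table, plan, i, seed, filter_scope=filter_scope, global_kept=global_kept)
        for i in range(N_FOLDS)
    ]
    records = pd.concat([f.records for f in folds], ignore_index=True)
    result = SeedResult(seed, plan, folds, records, metrics=compute_metrics(records))
    if importance:
        splits = [
            grouped_importance(
                f.winner,
                table.values.loc[f.val_ids],
                table.labels.loc[f.val_ids],
                seed=_child_seeds(seed, f.iteration, 99)[0],
            )
            for f in folds
        ]
        result.importance = {
            "per_fold": splits,
            "clinical_pct": float(np.mean([s["clinical_pct"] for s in splits])),
            "radiomic_pct": float(np.mean([s["radiomic_pct"] for s in splits])),
        }
    return result


def repeat_over_random_states(
    table: FeatureTable,
    seeds: list[int],
    stratify: bool = True,
    filter_scope: str = "fold",
    importance: bool = True,
) -> dict:
    """Run the whole pipeline per random state; summarize mean +/- sample SD."""
    if not seeds:
        raise ValueError("need at least one random state")
    results = [
        run_pipeline(table, s, stratify=stratify, filter_scope=filter_scope, importance=importance)
        for s in seeds
    ]
    metric_names = ("accuracy", "auc", "sensitivity", "specificity", "ppv", "npv", "prauc")
    per_seed = {
        s: {m: getattr(r.metrics, m) for m in metric_names} for s, r in zip(seeds, results)
    }
    summary = {}
    for m in metric_names:
        vals = np.array([per_seed[s][m] for s in seeds], float)
        summary[m] = {
            "mean": float(np.nanmean(vals)),
            "sd": float(np.nanstd(vals, ddof=1)) if len(seeds) > 1 else float("nan"),
        }
    fold_choices = {
        s: {
            f"fold_{f.iteration + 1}": f"{f.winner.family}, {f.winner.threshold:.2f}"
            for f in r.folds
        }
        for s, r in zip(seeds, results)
    }
    return {
        "seeds": list(seeds),
        "per_seed_metrics": per_seed,
        "summary": summary,
        "fold_choices": fold_choices,
        "importance": {s: r.importance for s, r in zip(seeds, results) if r.importance},
        "results": results,
    }


def grouped_importance(
    model: FittedFoldModel,
    values: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    n_repeats: int = 10,
) -> dict:
    """Permutation importance summed by group and normalized to 100%.

    Each selected feature is shuffled ``n_repeats`` times on the validation
    data; its importance is the mean AUC drop, clipped at zero. Group shares
    (clinical vs radiomic) are the normalized sums. If every importance is
    zero the split is reported as 50/50 with a degeneracy flag.
    """
    rng = np.random.default_rng(seed)
    y = labels.to_numpy(int)
    if y.min() == y.max():
        return {"clinical_pct": 50.0, "radiomic_pct": 50.0, "flags": ["one_class_validation"]}
    base = roc_auc_score(y, model.predict_proba(values))
    drops: dict[str, float] = {}
    for name in model.feature_names:
        deltas = []
        for _ in range(n_repeats):
            shuffled = values.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            deltas.append(base - roc_auc_score(y, model.predict_proba(shuffled)))
        drops[name] = max(float(np.mean(deltas)), 0.0)
    clin = sum(v for k, v in drops.items() if group_of(k) == CLINICAL_GROUP)
    rad = sum(v for k, v in drops.items() if group_of(k) != CLINICAL_GROUP)
    total = clin + rad
    if total == 0.0:
        return {"clinical_pct": 50.0, "radiomic_pct": 50.0, "flags": ["degenerate_importance"]}
    return {
        "clinical_pct": 100.0 * clin / total,
        "radiomic_pct": 100.0 * rad / total,
        "flags": [],
        "per_feature": drops,
    }
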