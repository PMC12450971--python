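"""Correlation filter, LASSO candidate sets, inner SVC scoring, selection."""

import numpy as np
import pandas as pd
import pytest

from recuq import (
    CandidateFeatureSet,
    Standardizer,
    correlation_filter,
    lasso_candidate_sets,
    score_candidate_set,
    select_feature_set,
)
from recuq.exceptions import DegenerateDataError
from recuq.metrics import youden_index


def brute_force_filter(values: pd.DataFrame, threshold: float) -> list[str]:
    """Independent re-implementation of the greedy removal rule."""
    cols = sorted(values.columns)
    cols = [c for c in cols if values[c].var(ddof=0) > 0]
    while len(cols) > 1:
        corr = values[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        if i > j:
            i, j = j, i
        mean_i = corr.values[i].sum() / (len(cols) - 1)
        mean_j = corr.values[j].sum() / (len(cols) - 1)
        drop = i if mean_i > mean_j else j if mean_j > mean_i else max(i, j)
        cols.pop(drop)
    return [c for c in values.columns if c in set(cols)]


def _frame(arr, names):
    return pd.DataFrame(arr, columns=names)


def test_identical_columns_keep_exactly_one(rng):
    x = rng.standard_normal(30)
    values = _frame(np.column_stack([x, x]), ["ct_pre__a", "ct_pre__b"])
    assert len(correlation_filter(values)) == 1


def test_threshold_one_keeps_everything(rng):
    values = _frame(rng.standard_normal((25, 6)), [f"ct_pre__f{i}" for i in range(6)])
    assert correlation_filter(values, threshold=1.0) == list(values.columns)


def test_filter_matches_brute_force_oracle_on_toy_block(rng):
    # 20x4 matrix: three features share a latent factor, one is independent
    f = rng.standard_normal(20)
    block = np.column_stack([f + 0.2 * rng.standard_normal(20) for _ in range(3)])
    values = _frame(
        np.column_stack([block, rng.standard_normal(20)]),
        ["ct_pre__a", "ct_pre__b", "ct_pre__c", "ct_pre__d"],
    )
    kept = correlation_filter(values, 0.7)
    assert kept == brute_force_filter(values, 0.7)
    assert len(kept) == 2  # one survivor of the block plus the independent column


@pytest.mark.parametrize("threshold", [0.5, 0.7, 0.9])
def test_filter_bound_holds_exactly(rng, threshold):
    latent = rng.standard_normal((60, 4))
    mix = latent @ rng.standard_normal((4, 12)) + 0.5 * rng.standard_normal((60, 12))
    values = _frame(mix, [f"pet_pre__f{i:02d}" for i in range(12)])
    kept = correlation_filter(values, threshold)
    corr = values[kept].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert corr.max() <= threshold + 1e-12


def test_filter_invariant_to_column_order(rng):
    values = _frame(rng.standard_normal((40, 8)), [f"ct_post__f{i}" for i in range(8)])
    values.iloc[:, 3] = values.iloc[:, 0] + 0.1 * rng.standard_normal(40)
    shuffled = values[list(values.columns[::-1])]
    assert sorted(correlation_filter(values, 0.7)) == sorted(correlation_filter(shuffled, 0.7))


def test_filter_rejects_single_sample(rng):
    with pytest.raises(DegenerateDataError):
        correlation_filter(_frame(rng.standard_normal((1, 3)), ["ct_pre__a", "ct_pre__b", "ct_pre__c"]))


def test_single_feature_passes_through(rng):
    values = _frame(rng.standard_normal((10, 1)), ["ct_pre__only"])
    assert correlation_filter(values) == ["ct_pre__only"]


# -- LASSO candidate sets ---------------------------------------------------


def test_lasso_recovers_six_strong_predictors(rng):
    n, p = 300, 26
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:6] = 2.0
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
    names = [f"ct_pre__f{i:02d}" for i in range(p)]
    values = Standardizer.fit(_frame(X, names)).transform(_frame(X, names))
    sets = lasso_candidate_sets(values, pd.Series(y))
    true = set(names[:6])
    assert any(true <= set(c.radiomic_names) for c in sets)
    for c in sets:
        assert 6 <= c.size <= 10


def test_lasso_rejects_one_class_labels(rng):
    values = _frame(rng.standard_normal((20, 8)), [f"ct_pre__f{i}" for i in range(8)])
    with pytest.raises(DegenerateDataError):
        lasso_candidate_sets(values, pd.Series(np.ones(20, dtype=int)))


def test_lasso_supports_are_distinct(rng):
    n, p = 200, 20
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * X[:, 0] - 1.5 * X[:, 1]))).astype(int)
    values = _frame(X, [f"ct_pre__f{i:02d}" for i in range(p)])
    sets = lasso_candidate_sets(values, pd.Series(y))
    supports = [frozenset(c.radiomic_names) for c in sets]
    assert len(supports) == len(set(supports))


def test_lasso_size_fallback_flagged(rng):
    # two dominant predictors only: no support of size >= 6 exists on the path
    n = 400
    X = np.column_stack([rng.standard_normal((n, 2)), 0.01 * rng.standard_normal((n, 3))])
    y = (rng.random(n) < 1 / (1 + np.exp(-3 * X[:, 0] - 3 * X[:, 1]))).astype(int)
    values = _frame(X, [f"ct_pre__f{i}" for i in range(5)])
    sets = lasso_candidate_sets(values, pd.Series(y))
    assert len(sets) == 1 and "size_fallback" in sets[0].flags


# -- inner SVC scoring ------------------------------------------------------


def test_perfect_separation_scores_youden_one(rng):
    n = 60
    x = np.concatenate([rng.normal(-4, 0.3, n // 2), rng.normal(4, 0.3, n // 2)])
    y = (x > 0).astype(int)
    values = _frame(x[:, None], ["ct_pre__sep"])
    labels = pd.Series(y)
    cand = CandidateFeatureSet(("ct_pre__sep",), 1.0)
    scored = score_candidate_set(cand, values, labels, values, labels, seed=0)
    assert scored.validation_youden == pytest.approx(1.0)


def test_one_class_validation_flagged(rng):
    values = _frame(rng.standard_normal((20, 1)), ["ct_pre__x"])
    labels = pd.Series([0, 1] * 10)
    val = _frame(rng.standard_normal((5, 1)), ["ct_pre__x"])
    scored = score_candidate_set(
        CandidateFeatureSet(("ct_pre__x",), 1.0), values, labels, val, pd.Series([1] * 5)
    )
    assert np.isnan(scored.validation_youden)
    assert "one_class_validation" in scored.flags


def test_score_matches_hand_counted_confusion(two_feature_fixture):
    """Youden from score_candidate_set equals brute-force confusion counting."""
    from recuq.modeling import calibrated_svc

    values, labels = two_feature_fixture
    names = ("ct_pre__radiomic_000", "ct_pre__radiomic_001")
    scored = score_candidate_set(
        CandidateFeatureSet(names, 1.0), values, labels, values, labels, seed=0
    )
    svc = calibrated_svc("linear", seed=0)
    svc.fit(values[list(names)].to_numpy(), labels.to_numpy())
    pred = (svc.predict_proba(values[list(names)].to_numpy())[:, 1] >= 0.5).astype(int)
    y = labels.to_numpy()
    sens = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
    spec = ((pred == 0) & (y == 0)).sum() / (y == 0).sum()
    assert scored.validation_youden == pytest.approx(youden_index(sens, spec))


# -- final selection --------------------------------------------------------


def _cand(names, youden):
    return CandidateFeatureSet(tuple(names), 1.0, youden)


def test_winner_plus_clinical_counts():
    clinical = [f"clin__c{i}" for i in range(15)]
    small = _cand([f"ct_pre__f{i}" for i in range(6)], 0.5)
    large = _cand([f"ct_pre__f{i}" for i in range(10)], 0.4)
    _, final = select_feature_set([small, large], clinical)
    assert len(final) == 21
    _, final = select_feature_set([large], clinical)
    assert len(final) == 25


def test_tie_breaks_smaller_then_lexicographic():
    seven = _cand([f"ct_pre__f{i}" for i in range(7)], 0.4)
    nine = _cand([f"ct_pre__f{i}" for i in range(9)], 0.4)
    winner, _ = select_feature_set([nine, seven], [])
    assert winner is seven
    a = _cand(["ct_pre__a"] + [f"ct_pre__f{i}" for i in range(6)], 0.4)
    b = _cand(["ct_pre__b"] + [f"ct_pre__f{i}" for i in range(6)], 0.4)
    winner, _ = select_feature_set([b, a], [])
    assert winner is a


def test_single_candidate_returned_and_empty_rejected():
    only = _cand(["ct_pre__x"] * 1, 0.1)
    winner, _ = select_feature_set([only], [])
    assert winner is only
    with pytest.raises(DegenerateDataError):
        select_feature_set([], [])
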