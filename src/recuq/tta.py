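"""Test-time augmentation and off-centered entropy uncertainty.

At inference each sample's radiomic features are perturbed with Gaussian
noise (0.1 x the training-fold standard deviation of each feature, five
draws); clinical features and labels are untouched. The model's
probabilities over the perturbed copies are averaged, and an off-centered
entropy is computed from the average: a binary entropy whose maximum is
relocated from p = 0.5 to the fold's operating threshold tau, so uncertainty
peaks at the decision boundary actually in use. Exclusion thresholds are
read off the validation set's entropy distribution at fixed percentiles and
then applied, fold by fold, to the test set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cv import FoldResult, _child_seeds
from .exceptions import DegenerateDataError
from .metrics import compute_metrics
from .modeling import FittedFoldModel
from .table import FeatureTable

TTA_DRAWS = 5
TTA_NOISE_SCALE = 0.1
#: Validation-entropy percentiles defining exclusion of the top 30%, 22.5%,
#: 15%, 7.5% and 0% most uncertain test predictions.
EXCLUSION_PERCENTILES: tuple[float, ...] = (70.0, 77.5, 85.0, 92.5, 100.0)


def exclusion_fraction(percentile: float) -> float:
    """Nominal excluded fraction for a validation-entropy percentile."""
    return (100.0 - percentile) / 100.0


def tta_predict(
    model: FittedFoldModel,
    values: pd.DataFrame,
    radiomic_sd: pd.Series,
    k: int = TTA_DRAWS,
    scale: float = TTA_NOISE_SCALE,
    seed: int = 0,
) -> np.ndarray:
    """Mean probability over k noise-perturbed copies of each sample.

    Noise is drawn independently per sample and per draw, N(0, (scale*sd)^2)
    per radiomic feature on the raw scale; ``scale=0`` reproduces the
    unperturbed probabilities exactly.
    """
    if k < 1:
        raise DegenerateDataError("TTA needs at least one augmentation draw")
    if scale == 0.0:
        # noise is identically zero: return the exact unperturbed probability
        return model.predict_proba(values)
    rng = np.random.default_rng(seed)
    rad_cols = [c for c in values.columns if c in radiomic_sd.index]
    sd = radiomic_sd[rad_cols].to_numpy(float)
    acc = np.zeros(len(values))
    for _ in range(k):
        perturbed = values.copy()
        noise = rng.standard_normal((len(values), len(rad_cols))) * (scale * sd)
        perturbed[rad_cols] = perturbed[rad_cols].to_numpy(float) + noise
        acc += model.predict_proba(perturbed)
    return acc / k


def off_centered_entropy(p, tau: float):
    """Entropy (bits, normalized to max 1) peaking at p = tau.

    The probability axis is piecewise-linearly rescaled so tau maps to 0.5,
    then the standard binary entropy is applied: e = 0 iff p in {0,1},
    e = 1 iff p = tau, and the tau = 0.5 case reduces to plain binary
    entropy.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly in (0,1), got {tau}")
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    u = np.where(p <= tau, p / (2.0 * tau), 0.5 + (p - tau) / (2.0 * (1.0 - tau)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = u * np.log2(u) + (1.0 - u) * np.log2(1.0 - u)
    e = -np.where((u == 0.0) | (u == 1.0), 0.0, terms)
    return e if e.ndim else float(e)


def entropy_exclusion_thresholds(
    validation_entropies, percentiles: tuple[float, ...] = EXCLUSION_PERCENTILES
) -> dict[float, float]:
    """Empirical quantiles (linear interpolation) of validation entropies.

    A test sample is excluded at a level iff its entropy strictly exceeds
    that level's threshold, so the 100th percentile (the maximum) excludes
    nothing even with ties.
    """
    v = np.asarray(validation_entropies, float)
    if v.size < 2:
        raise DegenerateDataError("need at least 2 validation entropies")
    return {q: float(np.quantile(v, q / 100.0, method="linear")) for q in percentiles}


def fold_uncertainty(
    fold: FoldResult,
    table: FeatureTable,
    seed: int,
    k: int = TTA_DRAWS,
    scale: float = TTA_NOISE_SCALE,
) -> pd.DataFrame:
    """TTA probabilities and entropies for one fold's validation + test sets.

    Entropy is centered at the fold winner's threshold. The returned frame
    has a ``split`` column ('validation' | 'test'); validation rows feed the
    exclusion thresholds, test rows are the ones filtered.
    """
    tau = fold.winner.threshold
    seeds = _child_seeds(seed, fold.iteration, 7)
    frames = []
    for split, ids, sub_seed in (
        ("validation", fold.val_ids, seeds[0]),
        ("test", pd.Index(fold.records["sample_id"]), seeds[1]),
    ):
        p_bar = tta_predict(
            fold.winner, table.values.loc[ids], fold.train_radiomic_sd,
            k=k, scale=scale, seed=sub_seed,
        )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "fold": fold.iteration,
                    "split": split,
                    "mean_tta_probability": p_bar,
                    "entropy": off_centered_entropy(p_bar, tau),
                    "threshold": tau,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def uncertainty_table(folds: list[FoldResult], table: FeatureTable, seed: int,
                      k: int = TTA_DRAWS, scale: float = TTA_NOISE_SCALE) -> pd.DataFrame:
    """Pooled per-sample uncertainty rows across all folds."""
    return pd.concat(
        [fold_uncertainty(f, table, seed, k=k, scale=scale) for f in folds],
        ignore_index=True,
    )


def retention_flags(
    uncertainty: pd.DataFrame, percentiles: tuple[float, ...] = EXCLUSION_PERCENTILES
) -> pd.DataFrame:
    """Annotate test rows with retained/excluded flags per exclusion level.

    Thresholds are computed per fold from that fold's validation entropies
    and applied to that fold's test samples. Retention is monotone: a sample
    retained at a harsher (lower-percentile) level is retained at all milder
    levels.
    """
    out = uncertainty[uncertainty["split"] == "test"].copy()
    for q in percentiles:
        out[f"retained_at_p{q:g}"] = False
    for fold_idx, grp in uncertainty.groupby("fold"):
        val_e = grp.loc[grp["split"] == "validation", "entropy"]
        thresholds = entropy_exclusion_thresholds(val_e, percentiles)
        mask = out["fold"] == fold_idx
        for q, thr in thresholds.items():
            if q >= 100.0:
                # the 0%-exclusion level keeps every test sample by definition,
                # even one whose entropy exceeds the validation maximum
                out.loc[mask, f"retained_at_p{q:g}"] = True
            else:
                out.loc[mask, f"retained_at_p{q:g}"] = out.loc[mask, "entropy"] <= thr
    return out


def filtered_metrics(
    retention: pd.DataFrame,
    records: pd.DataFrame,
    percentiles: tuple[float, ...] = EXCLUSION_PERCENTILES,
) -> dict[float, dict]:
    """Pooled metrics over retained test samples at each exclusion level."""
    merged = records.merge(
        retention[["sample_id"] + [f"retained_at_p{q:g}" for q in percentiles]],
        on="sample_id",
        validate="one_to_one",
    )
    out = {}
    for q in percentiles:
        kept = merged[merged[f"retained_at_p{q:g}"]]
        entry = {
            "percentile": q,
            "nominal_exclusion": exclusion_fraction(q),
            "n_retained": int(len(kept)),
        }
        try:
            entry["metrics"] = compute_metrics(kept).to_dict()
        except DegenerateDataError:
            entry["metrics"] = None
        out[q] = entry
    return out
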