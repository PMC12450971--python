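"""Self-contained simulation experiments used by tests and reporting.

These run the package's own machinery on generator cohorts at sizes chosen
for desk-scale reproducibility: conformal coverage under exchangeability,
and the pipeline-vs-Bayes-oracle comparison on planted-signal cohorts.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
from sklearn.linear_model import LogisticRegression

from .conformal import calibrate, coverage, prediction_sets
from .feature_selection import Standardizer
from .synthetic import GeneratorSpec, generate_cohort

#: Narrow generator layout for simulation studies: 10 radiomic features per
#: series (55 columns total), same block structure, prevalence and default
#: effect vector as the full-width spec.
NARROW_SPEC = dict(n_radiomic_per_series=10)


def narrow_spec(seed: int, n_samples: int, **overrides) -> GeneratorSpec:
    return GeneratorSpec(n_samples=n_samples, seed=seed, **{**NARROW_SPEC, **overrides})


def conformal_coverage_experiment(
    n_seeds: int = 50,
    n_train: int = 300,
    n_cal: int = 200,
    n_test: int = 2000,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Mean marginal coverage of class-conditional conformal sets.

    Per seed: draw one exchangeable cohort, split train/calibration/test,
    fit a logistic candidate on the training part, calibrate class-wise
    nonconformity on the calibration part, and record the fraction of test
    samples whose true label lands in the prediction set at ``alpha``.
    """
    ss = np.random.SeedSequence([int(base_seed), 2024])
    seeds = ss.generate_state(n_seeds) % (2**31 - 1)
    coverages, certain_fracs = [], []
    for seed in seeds:
        table = generate_cohort(narrow_spec(int(seed), n_train + n_cal + n_test))
        ids = table.sample_ids
        tr, ca, te = ids[:n_train], ids[n_train : n_train + n_cal], ids[n_train + n_cal :]
        std = Standardizer.fit(table.values.loc[tr])
        model = LogisticRegression(max_iter=5000)
        model.fit(std.transform(table.values.loc[tr]), table.labels.loc[tr])
        p_cal = model.predict_proba(std.transform(table.values.loc[ca]))[:, 1]
        p_test = model.predict_proba(std.transform(table.values.loc[te]))[:, 1]
        calib = calibrate(p_cal, table.labels.loc[ca].to_numpy(int), alpha)
        sets = prediction_sets(p_test, calib)
        coverages.append(coverage(sets, table.labels.loc[te].to_numpy(int)))
        certain_fracs.append(float((sets["set_size"] == 1).mean()))
    return {
        "mean_coverage": float(np.mean(coverages)),
        "sd_coverage": float(np.std(coverages, ddof=1)),
        "per_seed": [float(c) for c in coverages],
        "mean_certain_fraction": float(np.mean(certain_fracs)),
        "n_seeds": n_seeds,
        "alpha": alpha,
        "n_cal": n_cal,
        "n_test": n_test,
    }


def exclusion_sweep_experiment(
    n_seeds: int = 20, n_samples: int = 200, base_seed: int = 0
) -> dict:
    """Mean pooled accuracy per entropy-exclusion level over repeated runs.

    Runs the full pipeline plus the TTA entropy sweep on narrow planted-signal
    cohorts; used to check that excluding the most uncertain test samples does
    not hurt, and at the harshest level helps, pooled accuracy.
    """
    from .cv import run_pipeline
    from .tta import EXCLUSION_PERCENTILES, filtered_metrics, retention_flags, uncertainty_table

    ss = np.random.SeedSequence([int(base_seed), 77])
    seeds = ss.generate_state(n_seeds) % (2**31 - 1)
    acc_by_level = {q: [] for q in EXCLUSION_PERCENTILES}
    for seed in seeds:
        seed = int(seed)
        table = generate_cohort(narrow_spec(seed, n_samples))
        result = run_pipeline(table, seed, importance=False)
        unc = uncertainty_table(result.folds, table, seed)
        sweep = filtered_metrics(retention_flags(unc), result.records)
        for q, entry in sweep.items():
            acc_by_level[q].append(entry["metrics"]["accuracy"])
    return {
        "mean_accuracy": {q: float(np.mean(v)) for q, v in acc_by_level.items()},
        "n_seeds": n_seeds,
        "n_samples": n_samples,
    }


def prevalence_experiment(n_samples: int = 100_000, seed: int = 0) -> dict:
    """Empirical positive fraction of one large default-layout cohort."""
    spec = GeneratorSpec(n_samples=n_samples, seed=seed)
    table = generate_cohort(spec)
    return {
        "prevalence": float(table.labels.mean()),
        "target": spec.target_prevalence,
        "n": n_samples,
    }
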