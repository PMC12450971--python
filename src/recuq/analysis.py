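"""End-to-end driver: cohort -> repeated nested CV -> uncertainty layers.

``run_full_analysis`` executes the whole study for a :class:`RunConfig`:
simulate or load the cohort, run the five-fold rotation for every random
state, add the TTA-entropy exclusion sweep and the conformal certain /
uncertain split per seed, and write all tabular artifacts (CSV) and nested
reports (JSON) under the configured output directory.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import conformal as cp
from . import tta
from .config import RunConfig, jsonify, write_report
from .cv import repeat_over_random_states
from .synthetic import generate_cohort, write_cohort
from .table import FeatureTable, read_feature_table

log = logging.getLogger("recuq")


def load_or_simulate(config: RunConfig, seed: int | None = None) -> FeatureTable:
    if config.table_path is not None:
        return read_feature_table(config.table_path)
    return generate_cohort(config.generator_spec(seed))


def run_full_analysis(config: RunConfig, write: bool = True) -> dict:
    """Run everything; return (and optionally write) the report bundle."""
    t0 = time.time()
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    table = load_or_simulate(config, seed=config.seeds[0])
    if write and config.table_path is None:
        write_cohort(table, out / "cohort.csv", config.generator_spec(config.seeds[0]))
    log.info("cohort: %d samples x %d features", table.n_samples, len(table.feature_names))

    repeated = repeat_over_random_states(
        table,
        list(config.seeds),
        stratify=config.stratify,
        filter_scope=config.filter_scope,
        importance=config.importance,
    )

    predictions, uncertainty_rows, conformal_rows = [], [], []
    exclusion_by_seed, cohorts_by_seed = {}, {}
    for seed, result in zip(config.seeds, repeated["results"]):
        t_seed = time.time()
        rec = result.records.copy()
        rec.insert(0, "seed", seed)
        predictions.append(rec)

        unc = tta.uncertainty_table(
            result.folds, table, seed, k=config.tta_draws, scale=config.tta_scale
        )
        retained = tta.retention_flags(unc, config.exclusion_percentiles)
        flag_cols = [c for c in retained.columns if c.startswith("retained_at_")]
        unc = unc.merge(
            retained[["sample_id", "fold"] + flag_cols], on=["sample_id", "fold"], how="left"
        )
        unc.insert(0, "seed", seed)
        uncertainty_rows.append(unc)
        exclusion_by_seed[seed] = tta.filtered_metrics(
            retained, result.records, config.exclusion_percentiles
        )

        conf = cp.conformal_table(result.folds, table, alpha=config.alpha)
        cohorts_by_seed[seed] = cp.cohort_metrics(conf, result.records)
        conf.insert(0, "seed", seed)
        conformal_rows.append(conf)
        log.info("seed %d: folds + uncertainty + conformal in %.1fs", seed, time.time() - t_seed)

    bundle = {
        "config": jsonify(
            {
                "seeds": list(config.seeds),
                "alpha": config.alpha,
                "exclusion_percentiles": list(config.exclusion_percentiles),
                "tta": {"draws": config.tta_draws, "scale": config.tta_scale},
                "stratify": config.stratify,
                "filter_scope": config.filter_scope,
            }
        ),
        "cohort": {"n_samples": table.n_samples, "n_features": len(table.feature_names)},
        "per_seed_metrics": repeated["per_seed_metrics"],
        "summary": repeated["summary"],
        "fold_choices": repeated["fold_choices"],
        "importance": repeated["importance"],
        "exclusion_sweep": exclusion_by_seed,
        "conformal_cohorts": cohorts_by_seed,
        "_runtime_s": time.time() - t0,  # underscore: kept out of written reports
        "_results": repeated["results"],  # in-memory only, stripped before writing
        "_predictions": pd.concat(predictions, ignore_index=True),
        "_uncertainty": pd.concat(uncertainty_rows, ignore_index=True),
        "_conformal": pd.concat(conformal_rows, ignore_index=True),
        "_table": table,
    }

    if write:
        bundle["_predictions"].to_csv(out / "predictions.csv", index=False)
        bundle["_uncertainty"].to_csv(out / "uncertainty.csv", index=False)
        bundle["_conformal"].to_csv(out / "conformal.csv", index=False)
        selection = {
            str(seed): [f.selection_report for f in result.folds]
            for seed, result in zip(config.seeds, repeated["results"])
        }
        write_report(out / "selection_reports.json", {"selection": selection}, config)
        public = {k: v for k, v in bundle.items() if not k.startswith("_")}
        write_report(out / "report.json", public, config)
        _write_summary_text(out / "summary.txt", bundle, config)
        log.info("artifacts written under %s", out)
    return bundle


def _write_summary_text(path, bundle: dict, config: RunConfig) -> None:
    lines = [
        f"recuq analysis (config {config.digest()})",
        f"cohort: {bundle['cohort']['n_samples']} samples, {bundle['cohort']['n_features']} features",
        "",
        "per-seed pooled test metrics (mean +/- SD across random states):",
    ]
    seeds = bundle["config"]["seeds"]
    header = "metric      " + "".join(f"{s:>10}" for s in seeds) + "   mean +/- SD"
    lines.append(header)
    n_seeds = len(seeds)
    for metric, agg in bundle["summary"].items():
        row = f"{metric:<12}"
        for s in seeds:
            v = bundle["per_seed_metrics"][s][metric]
            row += f"{v:>10.3f}"
        sd = agg["sd"]
        sd_txt = f"{sd:.3f}" if (n_seeds > 1 and sd == sd) else "n/a"
        row += f"   {agg['mean']:.3f} +/- {sd_txt}"
        lines.append(row)
    lines.append("")
    for seed in seeds:
        cc = bundle["conformal_cohorts"][seed]
        lines.append(
            f"seed {seed}: certain {cc['certain']['n']} / uncertain {cc['uncertain']['n']} "
            f"of {cc['total']} test samples"
        )
    Path(path).write_text("\n".join(lines) + "\n")
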