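#!/usr/bin/env python
"""Final summary: per-seed metrics, fold winners, importance split.

Reads results/report.json and prints the repeated-run summary table
(metrics per random state with mean +/- SD, the fold-winner grid, and the
clinical-vs-radiomic importance split), writing the tidy version to
results/summary_table.csv.
"""

import json
from pathlib import Path

import pandas as pd

OUT = Path("results")


def main() -> None:
    report = json.loads((OUT / "report.json").read_text())
    seeds = [str(s) for s in report["config"]["seeds"]]

    rows = []
    for fold_label in report["fold_choices"][seeds[0]]:
        rows.append(
            {"row": f"{fold_label} best model"}
            | {s: report["fold_choices"][s][fold_label] for s in seeds}
            | {"mean_sd": "-"}
        )
    for metric in ("accuracy", "auc", "sensitivity", "specificity"):
        agg = report["summary"][metric]
        rows.append(
            {"row": metric}
            | {s: f"{report['per_seed_metrics'][s][metric]:.3f}" for s in seeds}
            | {"mean_sd": f"{agg['mean']:.3f} +/- {agg['sd']:.3f}"}
        )
    imp = report["importance"]
    rows.append(
        {"row": "importance clinical vs radiomic"}
        | {
            s: f"{imp[s]['clinical_pct']:.1f}% : {imp[s]['radiomic_pct']:.1f}%"
            for s in seeds
        }
        | {"mean_sd": "-"}
    )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "summary_table.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {OUT / 'summary_table.csv'}")


if __name__ == "__main__":
    main()
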