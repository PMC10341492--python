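#!/usr/bin/env python
"""Run the group-comparison battery on every (endpoint, region): a
Shapiro–Wilk gate routes each table to one-way ANOVA + Tukey HSD or to
Kruskal–Wallis + Dunn (Bonferroni); control-vs-cuprizone contrasts are
summarized with the conventional significance stars.

Requires endpoints.csv; writes stats_summary.csv and
stats_pairwise_control.csv under results/study/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from cuprank import compare_groups
from cuprank.errors import SmallSampleWarning


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    endpoints = pd.read_csv(args.outdir / "endpoints.csv")
    rows, control_pairs = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        for (region, name), sub in endpoints.groupby(["region", "endpoint"]):
            grouped = {g: s["value"].to_numpy() for g, s in sub.groupby("group", sort=False)}
            report = compare_groups(grouped)
            rows.append(
                {
                    "region": region,
                    "endpoint": name,
                    "test": report.test,
                    "statistic": round(report.statistic, 3),
                    "pvalue": report.pvalue,
                }
            )
            vs_control = report.pairwise.query("group1 == 'control' or group2 == 'control'")
            for _, pr in vs_control.iterrows():
                control_pairs.append(
                    {"region": region, "endpoint": name, **pr.to_dict()}
                )

    summary = pd.DataFrame(rows)
    pairs = pd.DataFrame(control_pairs)
    summary.to_csv(args.outdir / "stats_summary.csv", index=False)
    pairs.to_csv(args.outdir / "stats_pairwise_control.csv", index=False)

    print(summary.to_string(index=False))
    sig = pairs[pairs["p_adj"] <= 0.05]
    print(
        f"\ncontrol-vs-cuprizone contrasts significant after adjustment: "
        f"{len(sig)}/{len(pairs)}"
    )


if __name__ == "__main__":
    main()
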