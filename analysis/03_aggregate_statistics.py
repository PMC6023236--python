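#!/usr/bin/env python
"""Aggregate the processed trials and compare the energy measures.

Builds the three-level summary (overall mean, range of subject means,
intra-/inter-subject variability) for every outcome, then runs the
Friedman test across the five energy measures and exact Wilcoxon
signed-rank tests on the method pairs (Bonferroni alpha = 0.01).
Writes results/summary_table.csv and results/statistics.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from heelstrike.study import friedman_statistic, signed_rank_exact

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

ENERGY_KEYS = ["W", "W_Z", "dE_e", "dE_p", "dE_p_CS"]
PAIRS = [("W", "dE_e"), ("W", "dE_p"), ("W", "dE_p_CS"),
         ("W_Z", "dE_e"), ("dE_e", "dE_p_CS")]


def main() -> None:
    df = pd.read_csv(RESULTS / "trials.csv")
    variables = [c for c in df.columns if df[c].dtype.kind == "f"]
    means = df.groupby("subject_id")[variables].mean()
    sds = df.groupby("subject_id")[variables].std(ddof=1)

    table = pd.DataFrame({
        "overall_mean": means.mean(),
        "subject_min": means.min(),
        "subject_max": means.max(),
        "intra_subject": sds.mean(),
        "inter_subject": means.std(ddof=1),
    })
    table.to_csv(RESULTS / "summary_table.csv", float_format="%.6g")

    chi2, df_free, p = friedman_statistic(means[ENERGY_KEYS].to_numpy())
    print(f"Friedman over {ENERGY_KEYS}: chi2({df_free}) = {chi2:.1f}, p = {p:.2e}")
    stats = {"friedman": {"chi2": chi2, "df": df_free, "p": p}}

    alpha = 0.05 / len(PAIRS)
    stats["wilcoxon"] = {}
    for a, b in PAIRS:
        w, p, sig = signed_rank_exact((means[a] - means[b]).to_numpy(), alpha)
        stats["wilcoxon"][f"{a}_vs_{b}"] = {
            "W_stat": w, "p": p, "significant": bool(sig), "alpha": alpha,
        }
        mark = "*" if sig else " "
        print(f"  {a:>6} vs {b:<7} p = {p:.4f} {mark}")

    with open(RESULTS / "statistics.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)

    sel = ["W", "W_Z", "dE_e", "dE_p", "dE_p_CS", "M_e_pct", "t_e_over_t_p",
           "Zdot_t0", "t_p_ms", "t_e_ms"]
    print(table.loc[[s for s in sel if s in table.index]].round(3).to_string())


if __name__ == "__main__":
    main()
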