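#!/usr/bin/env python
"""Condition-level statistics on the recovered quantities.

Summarises the per-condition stoichiometry and diffusion tables from
analysis/02, compares conditions pairwise with Mann-Whitney U tests, and
reports the fold-change arithmetic both for the recovered means and for the
published condition means (slimquant.reference). Writes
condition_summary.csv, comparisons.csv and fold_changes.csv to results/.
"""

import sys
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from slimquant.io import read_table, write_table
from slimquant.population import compare_conditions, fold_changes
from slimquant.reference import printed_arithmetic

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    try:
        stoich = read_table(results / "stoichiometry.csv")
        diff = read_table(results / "diffusion.csv")
    except FileNotFoundError:
        print("missing results tables; run analysis/02_quantify_aggregates.py first")
        return 1

    summaries, comparisons = [], []
    for metric, tab, col in (("stoichiometry", stoich, "stoichiometry"),
                             ("diffusion", diff, "d_coeff")):
        groups = {g: sub[col].to_numpy() for g, sub in tab.groupby("condition")}
        for g, vals in groups.items():
            summaries.append({
                "metric": metric, "condition": g, "n": len(vals),
                "mean": float(np.mean(vals)),
                "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))})
        for a, b in combinations(sorted(groups), 2):
            stat, p = compare_conditions(groups[a], groups[b], "mann_whitney")
            comparisons.append({"metric": metric, "a": a, "b": b,
                                "U": stat, "p": p})

    sm = pd.DataFrame(summaries).set_index(["metric", "condition"])
    rec_s = sm.loc["stoichiometry"]["mean"]
    rec_d = sm.loc["diffusion"]["mean"]
    fc_rows = []
    for label, ref, other, kind in (
            ("stoich_NaCl_vs_NaPi", "NaPi", "NaCl", "s"),
            ("stoich_sorbitol_vs_NaPi", "NaPi", "sorbitol", "s"),
            ("diffusion_NaCl_vs_NaPi", "NaPi", "NaCl", "d"),
            ("diffusion_sorbitol_vs_NaPi", "NaPi", "sorbitol", "d")):
        series = rec_s if kind == "s" else rec_d
        fc = fold_changes(series[ref], series[other])
        fc_rows.append({"comparison": label, **fc})
    fold = pd.DataFrame(fc_rows)

    write_table(pd.DataFrame(summaries), results / "condition_summary.csv")
    write_table(pd.DataFrame(comparisons), results / "comparisons.csv")
    write_table(fold, results / "fold_changes.csv")

    printed = printed_arithmetic()
    print("recovered means:")
    print(pd.DataFrame(summaries).to_string(index=False))
    print("\nfold changes on recovered means:")
    print(fold.to_string(index=False))
    print("\npublished-mean arithmetic for comparison:")
    for k, v in printed.items():
        print(f"  {k}: {v:.2f}")


if __name__ == "__main__":
    sys.exit(main())
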