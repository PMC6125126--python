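#!/usr/bin/env python
"""Group statistics over the simulated cohort.

Reads the per-animal tables written by 02_run_cohort.py and runs the
statistical battery: 2-SD outlier screen per group and measure, mixed
(group x timepoint) ANOVA on freezing, one-way repeated-measures ANOVAs
with Tukey post hocs on the normalized AEP and theta measures per group,
and the chance-level test of the per-animal lead/lags.  Writes
results/group_stats.csv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

warnings.filterwarnings("ignore")
sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from fearlfp import stats  # noqa: E402

BASE = Path(__file__).resolve().parent.parent / "results"
COHORT = BASE / "cohort"


def main():
    if not (COHORT / "freezing_summary.csv").exists():
        sys.exit("run analysis/02_run_cohort.py first (no cohort tables found)")
    frz = pd.read_csv(COHORT / "freezing_summary.csv")
    aep = pd.read_csv(COHORT / "aep_summary.csv")
    theta = pd.read_csv(COHORT / "theta_summary.csv")
    conn = pd.read_csv(COHORT / "conn_summary.csv")
    rows = []

    mixed = stats.rm_anova_2way_mixed(frz, dv="percent_freezing",
                                      within="timepoint", between="group",
                                      subject="animal_id")
    for name in ("group", "level", "interaction"):
        r = mixed[name]
        rows.append(("freezing_mixed", name, r.F, r.df1, r.df2, r.p))
        print(f"freezing {name:12s} F({r.df1},{r.df2}) = {r.F:7.2f}  p = {r.p:.4f}")

    for grp in ("control", "CIS"):
        for measure, tab, col in (("aep_pct", aep, "amplitude_pct_baseline"),
                                  ("theta_pct", theta, "theta_pct_baseline")):
            for region in ("dmPFC", "BLA"):
                sub = tab[(tab.group == grp) & (tab.region == region)].dropna(
                    subset=[col])
                # 2-SD outlier screen per timepoint; a flagged animal is
                # dropped from this measure's repeated-measures fit
                flagged = set()
                for tp, cell in sub.groupby("timepoint"):
                    if len(cell) >= 3:
                        keep, _ = stats.outlier_filter(cell[col].to_numpy())
                        flagged |= set(cell.loc[~keep, "animal_id"])
                if flagged:
                    print(f"  [{grp} {region} {measure}] outlier screen "
                          f"removed {sorted(flagged)}")
                sub = sub[~sub.animal_id.isin(flagged)]
                complete = sub.groupby("animal_id")["timepoint"].nunique() == 3
                keep_ids = complete[complete].index
                sub = sub[sub.animal_id.isin(keep_ids)]
                if sub.animal_id.nunique() < 3:
                    continue
                res = stats.rm_anova_1way(sub, dv=col, within="timepoint",
                                          subject="animal_id", posthoc=False)
                rows.append((f"{measure}_{region}_{grp}", "timepoint", res.F,
                             res.df1, res.df2, res.p))
                print(f"{grp:8s} {region:6s} {measure:10s} "
                      f"F({res.df1},{res.df2}) = {res.F:7.2f}  p = {res.p:.4f}")

    # per-animal lead/lags vs the chance level implied by the surrogates
    for grp in ("control", "CIS"):
        sub = conn[(conn.group == grp) & (conn.timepoint == "fear_recall")]
        lags = sub["summary_lag_s"].to_numpy() * 1000.0
        t, p = stats.lag_vs_chance(lags, mode="one-sample")
        rows.append((f"lag_vs_zero_{grp}", "fear_recall", t, len(lags) - 1,
                     np.nan, p))
        print(f"{grp:8s} lead/lag vs 0 at fear recall: t = {t:5.2f}, p = {p:.4f} "
              f"(median {np.median(lags):+.1f} ms)")

    out = pd.DataFrame(rows, columns=["analysis", "factor", "F_or_t", "df1",
                                      "df2", "p"])
    out.to_csv(BASE / "group_stats.csv", index=False)
    print(f"\nWrote {BASE/'group_stats.csv'}")


if __name__ == "__main__":
    main()
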