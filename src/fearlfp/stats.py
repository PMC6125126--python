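"""Group statistics over per-animal summaries.

Implements the analysis battery used for the behavioral and LFP
measures: a single-pass 2-SD outlier screen, one-way repeated-measures
ANOVA with Tukey HSD post hoc tests, a mixed (between-group x
within-level) ANOVA with Holm-Sidak-adjusted post hoc comparisons, and
the chance-level test for amplitude-correlation lead/lags.  Sphericity
corrections are not applied; the reported df are the uncorrected
(k-1), (k-1)(n-1) pairs.

The ANOVA engines delegate to pingouin (rm_anova / mixed_anova); the
post hoc machinery is computed here from the fitted error terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    factor: str
    F: float
    df1: int
    df2: int
    p: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------

def outlier_filter(values) -> tuple[np.ndarray, pd.DataFrame]:
    """Single-pass screen: flag x with |x - mean| > 2*SD (sample SD,
    mean and SD computed once on all values).  Returns (keep_mask,
    report).  A constant vector has SD 0 and keeps everything."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three values to screen for outliers")
    mu = x.mean()
    sd = x.std(ddof=1)
    keep = np.abs(x - mu) <= 2.0 * sd
    report = pd.DataFrame({
        "index": np.flatnonzero(~keep),
        "value": x[~keep],
        "deviation_sd": np.abs(x[~keep] - mu) / sd if sd > 0 else np.nan,
    })
    return keep, report


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _require_complete(df, subject, within) -> None:
    counts = df.groupby(subject)[within].nunique()
    k = df[within].nunique()
    if (counts != k).any() or len(df) != counts.size * k:
        raise ValueError("repeated-measures design requires complete cases")


def rm_anova_1way(df: pd.DataFrame, dv: str, within: str, subject: str,
                  posthoc: bool = True) -> AnovaResult:
    """Within-subject one-way RM ANOVA, F = MS_condition / MS_(cond x subj),
    followed by Tukey HSD across the repeated levels using the RM error
    term."""
    import pingouin as pg

    _require_complete(df, subject, within)
    aov = pg.rm_anova(dv=dv, within=within, subject=subject, data=df,
                      detailed=True, correction=False)
    row = aov.loc[aov["Source"] == within].iloc[0]
    err = aov.loc[aov["Source"] == "Error"].iloc[0]
    if "F" in aov.columns and np.isfinite(row["F"]):
        F, p = float(row["F"]), float(row["p_unc"])
    else:
        # degenerate fit (zero condition and error SS): no effect
        F, p = 0.0, 1.0
    res = AnovaResult(factor=within, F=F, df1=int(row["DF"]),
                      df2=int(err["DF"]), p=p, table=aov)
    if posthoc:
        ms_err = float(err["SS"]) / float(err["DF"])
        res.posthoc = tukey_rm(df, dv, within, subject, ms_err, int(err["DF"]))
    return res


def tukey_rm(df, dv, within, subject, ms_error: float, df_error: int) -> pd.DataFrame:
    """Tukey HSD over repeated levels with the RM ANOVA error term:
    q = |m_i - m_j| / sqrt(MS_error / n)."""
    means = df.groupby(within)[dv].mean()
    n = df[subject].nunique()
    k = means.size
    rows = []
    for a, b in itertools.combinations(means.index, 2):
        diff = means[a] - means[b]
        se = np.sqrt(ms_error / n)
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_error)) if np.isfinite(q) else 0.0
        rows.append((a, b, diff, q, p))
    return pd.DataFrame(rows, columns=["A", "B", "mean_diff", "q", "p_tukey"])


def rm_anova_2way_mixed(df: pd.DataFrame, dv: str, within: str, between: str,
                        subject: str, posthoc: bool = True) -> dict[str, AnovaResult]:
    """Mixed-design ANOVA: between factor (group), within factor (level),
    and their interaction, with subjects-within-group as the between
    error term and level x subjects-within-group as the within error
    term.  Post hoc: group comparisons at each level and level
    comparisons within each group, Holm-Sidak adjusted per family."""
    import pingouin as pg

    _require_complete(df, subject, within)
    sizes = df.groupby(between)[subject].nunique()
    if (sizes < 2).any():
        raise ValueError("each group needs at least two subjects")
    aov = pg.mixed_anova(dv=dv, within=within, between=between, subject=subject,
                         data=df, correction=False)
    out = {}
    for source, name in ((between, "group"), (within, "level"),
                         ("Interaction", "interaction")):
        row = aov.loc[aov["Source"] == source].iloc[0]
        out[name] = AnovaResult(factor=source, F=float(row["F"]),
                                df1=int(row["DF1"]), df2=int(row["DF2"]),
                                p=float(row["p_unc"]), table=aov)
    if posthoc:
        out["posthoc"] = holm_sidak_posthoc(df, dv, within, between, subject)
    return out


def holm_sidak_posthoc(df, dv, within, between, subject) -> pd.DataFrame:
    """Pairwise cells after a mixed fit: unpaired t between groups at each
    within level, and paired t between levels within each group; p values
    Holm-Sidak adjusted within each family."""
    rows = []
    groups = sorted(df[between].unique())
    levels = sorted(df[within].unique())
    fam1 = []
    for lev in levels:
        sub = df[df[within] == lev]
        xs = [sub.loc[sub[between] == g, dv].to_numpy() for g in groups[:2]]
        t, p = sps.ttest_ind(*xs)
        fam1.append((f"{groups[0]} vs {groups[1]} @ {lev}", t, p))
    fam2 = []
    for g in groups:
        sub = df[df[between] == g].pivot_table(index=subject, columns=within, values=dv)
        for a, b in itertools.combinations(levels, 2):
            t, p = sps.ttest_rel(sub[a], sub[b])
            fam2.append((f"{a} vs {b} within {g}", t, p))
    for family, items in (("between_groups", fam1), ("within_levels", fam2)):
        adj = holm_sidak([p for _, _, p in items])
        for (label, t, p), pa in zip(items, adj):
            rows.append((family, label, float(t), float(p), float(pa)))
    return pd.DataFrame(rows, columns=["family", "comparison", "t", "p", "p_adj"])


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjustment: sort ascending, adjust the i-th
    smallest as 1-(1-p)^(m-i), then enforce monotonicity.  Adjusted values
    are monotone in the raw p values and never smaller than them."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# lead/lag vs chance
# ---------------------------------------------------------------------------

def lag_vs_chance(actual, chance=None, mode: str = "two-sample"):
    """Test whether per-animal lead/lags differ from chance.

    ``two-sample`` (default, matching the published analysis): unpaired
    Student's t between the actual lags and the chance-derived lags.
    ``one-sample`` (documented alternative): one-sample t of the actual
    lags against zero.
    Returns (t, p).
    """
    a = np.asarray(actual, dtype=float)
    if mode == "one-sample":
        if a.size < 2:
            raise ValueError("need at least two values")
        t, p = sps.ttest_1samp(a, 0.0)
    elif mode == "two-sample":
        c = np.asarray(chance, dtype=float)
        if a.size < 2 or c.size < 2:
            raise ValueError("need at least two values per sample")
        if a.std(ddof=1) == 0 and c.std(ddof=1) == 0:
            if np.allclose(a.mean(), c.mean()):
                return 0.0, 1.0
            raise ValueError("zero variance in both samples")
        t, p = sps.ttest_ind(a, c)
    else:
        raise ValueError("mode must be 'two-sample' or 'one-sample'")
    return float(t), float(p)
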