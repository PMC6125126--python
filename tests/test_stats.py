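"""Outlier screening, ANOVA engines vs closed-form sums-of-squares
oracles, post hoc adjustments, and chance-level tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fearlfp.stats import (holm_sidak, lag_vs_chance, outlier_filter,
                           rm_anova_1way, rm_anova_2way_mixed)


# ---------------------------------------------------------------------------
# oracles: brute-force sums-of-squares decompositions
# ---------------------------------------------------------------------------

def oracle_rm_1way(Y):
    """Y: (n_subjects, k_levels). Returns F, df1, df2."""
    n, k = Y.shape
    G = Y.mean()
    ss_level = n * ((Y.mean(axis=0) - G) ** 2).sum()
    ss_subj = k * ((Y.mean(axis=1) - G) ** 2).sum()
    ss_total = ((Y - G) ** 2).sum()
    ss_err = ss_total - ss_level - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_level / df1) / (ss_err / df2), df1, df2


def oracle_mixed(Ys):
    """Ys: dict group -> (n_g, k) array. Returns F_group, F_level, F_inter."""
    k = next(iter(Ys.values())).shape[1]
    allY = np.vstack(list(Ys.values()))
    N = allY.shape[0]
    G = allY.mean()
    subj_means = allY.mean(axis=1)
    ss_between_subj = k * ((subj_means - G) ** 2).sum()
    ss_grp = sum(k * Y.shape[0] * (Y.mean() - G) ** 2 for Y in Ys.values())
    ss_subj_w = ss_between_subj - ss_grp
    ss_level = N * ((allY.mean(axis=0) - G) ** 2).sum()
    ss_cells = sum(Y.shape[0] * ((Y.mean(axis=0) - G) ** 2).sum()
                   for Y in Ys.values())
    ss_inter = ss_cells - ss_grp - ss_level
    ss_total = ((allY - G) ** 2).sum()
    ss_err_w = ss_total - ss_between_subj - ss_level - ss_inter
    g = len(Ys)
    F_grp = (ss_grp / (g - 1)) / (ss_subj_w / (N - g))
    den = ss_err_w / ((k - 1) * (N - g))
    return F_grp, (ss_level / (k - 1)) / den, (ss_inter / ((g - 1) * (k - 1))) / den


def _long_1way(Y):
    n, k = Y.shape
    return pd.DataFrame([(s, l, Y[s, l]) for s in range(n) for l in range(k)],
                        columns=["subj", "level", "y"])


def _long_mixed(Ys):
    rows = []
    for g, Y in Ys.items():
        for s in range(Y.shape[0]):
            for l in range(Y.shape[1]):
                rows.append((f"{g}s{s}", g, l, Y[s, l]))
    return pd.DataFrame(rows, columns=["subj", "grp", "level", "y"])


# ---------------------------------------------------------------------------
# outlier screen
# ---------------------------------------------------------------------------

def test_constant_vector_keeps_everything():
    keep, rep = outlier_filter([1.0, 1.0, 1.0, 1.0])
    assert keep.all() and rep.empty


def test_two_sd_rule_by_direct_arithmetic():
    x = np.array([0, 0, 0, 0, 0, 100.0])
    keep, rep = outlier_filter(x)
    # oracle: mean 16.67, SD(ddof=1) 40.82 -> |100-16.67| = 83.3 > 2*40.82
    mu, sd = x.mean(), x.std(ddof=1)
    expect = np.abs(x - mu) <= 2 * sd
    np.testing.assert_array_equal(keep, expect)
    assert not keep[-1]


def test_removal_rate_matches_two_sd_tail_mass():
    rng = np.random.default_rng(0)
    removed = sum((~outlier_filter(rng.standard_normal(50))[0]).sum()
                  for _ in range(2000)) / (2000 * 50)
    # empirical 2-sigma two-tail mass ~0.0455; finite-sample screen sits near it
    assert 0.03 < removed < 0.06


def test_outlier_filter_needs_three_values():
    with pytest.raises(ValueError):
        outlier_filter([1.0, 2.0])


# ---------------------------------------------------------------------------
# one-way repeated measures
# ---------------------------------------------------------------------------

def test_identical_level_means_give_zero_f():
    Y = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 4))
    res = rm_anova_1way(_long_1way(Y), "y", "level", "subj", posthoc=False)
    assert res.F == pytest.approx(0.0, abs=1e-12)


def test_one_way_rm_matches_ss_oracle():
    rng = np.random.default_rng(1)
    for _ in range(25):
        n = rng.integers(3, 10)
        k = rng.integers(2, 6)
        Y = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
        res = rm_anova_1way(_long_1way(Y), "y", "level", "subj", posthoc=False)
        F, df1, df2 = oracle_rm_1way(Y)
        assert res.F == pytest.approx(F, abs=1e-10, rel=1e-10)
        assert (res.df1, res.df2) == (df1, df2)


def test_rm_anova_invariances():
    rng = np.random.default_rng(2)
    Y = rng.normal(0, 1, (6, 3))
    base = rm_anova_1way(_long_1way(Y), "y", "level", "subj", posthoc=False).F
    shifted = rm_anova_1way(_long_1way(Y + 17.3), "y", "level", "subj",
                            posthoc=False).F
    scaled = rm_anova_1way(_long_1way(Y * 4.2), "y", "level", "subj",
                           posthoc=False).F
    assert base == pytest.approx(shifted, rel=1e-9)
    assert base == pytest.approx(scaled, rel=1e-9)


def test_missing_cells_rejected():
    df = _long_1way(np.random.default_rng(3).normal(size=(4, 3))).iloc[:-1]
    with pytest.raises(ValueError):
        rm_anova_1way(df, "y", "level", "subj")


def test_tukey_posthoc_orders_with_mean_separation():
    rng = np.random.default_rng(4)
    Y = rng.normal(0, 0.3, (8, 3)) + np.array([0.0, 0.1, 3.0])
    res = rm_anova_1way(_long_1way(Y), "y", "level", "subj")
    ph = res.posthoc.set_index(["A", "B"])
    assert ph.loc[(0, 2), "p_tukey"] < 0.01
    assert ph.loc[(0, 1), "p_tukey"] > ph.loc[(0, 2), "p_tukey"]


# ---------------------------------------------------------------------------
# mixed design
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_group_and_interaction_f():
    Y = np.random.default_rng(5).normal(size=(4, 3))
    res = rm_anova_2way_mixed(_long_mixed({"a": Y, "b": Y.copy()}), "y",
                              "level", "grp", "subj", posthoc=False)
    assert res["group"].F == pytest.approx(0.0, abs=1e-10)
    assert res["interaction"].F == pytest.approx(0.0, abs=1e-10)


def test_mixed_anova_matches_ss_oracle_including_unbalanced():
    rng = np.random.default_rng(6)
    for _ in range(20):
        k = rng.integers(2, 5)
        Ys = {g: rng.normal(0, 1, (rng.integers(3, 8), k)) for g in ("a", "b")}
        res = rm_anova_2way_mixed(_long_mixed(Ys), "y", "level", "grp",
                                  "subj", posthoc=False)
        Fg, Fl, Fi = oracle_mixed(Ys)
        assert res["group"].F == pytest.approx(Fg, rel=1e-10)
        assert res["level"].F == pytest.approx(Fl, rel=1e-10)
        assert res["interaction"].F == pytest.approx(Fi, rel=1e-10)


def test_sum_of_squares_conservation():
    """Effect SS plus the two error SS (reconstructed from the fitted F
    ratios) must tile the total SS exactly."""
    rng = np.random.default_rng(7)
    Ys = {g: rng.normal(0, 1, (6, 4)) for g in ("a", "b")}
    res = rm_anova_2way_mixed(_long_mixed(Ys), "y", "level", "grp", "subj",
                              posthoc=False)
    g, l, i = res["group"], res["level"], res["interaction"]
    tab = g.table.set_index("Source")
    ss = tab["SS"]
    ms_err_between = (ss["grp"] / g.df1) / g.F
    ms_err_within = (ss["level"] / l.df1) / l.F
    total = (ss["grp"] + ss["level"] + ss["Interaction"]
             + ms_err_between * g.df2 + ms_err_within * l.df2)
    allY = np.vstack(list(Ys.values()))
    ss_total = ((allY - allY.mean()) ** 2).sum()
    assert total == pytest.approx(ss_total, rel=1e-8)


def test_single_subject_group_rejected():
    Ys = {"a": np.random.default_rng(8).normal(size=(1, 3)),
          "b": np.random.default_rng(9).normal(size=(4, 3))}
    with pytest.raises(ValueError):
        rm_anova_2way_mixed(_long_mixed(Ys), "y", "level", "grp", "subj")


# ---------------------------------------------------------------------------
# Holm-Sidak and chance-level test
# ---------------------------------------------------------------------------

def test_holm_sidak_properties():
    rng = np.random.default_rng(10)
    p = rng.uniform(0, 1, 12)
    adj = holm_sidak(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in raw p
    # smallest p gets the full Sidak correction for m tests
    i = order[0]
    assert adj[i] == pytest.approx(1 - (1 - p[i]) ** p.size)


def test_lag_vs_chance_formula_and_modes():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    c = np.array([0.5, 1.5, 1.0, 2.0])
    t, p = lag_vs_chance(a, c)
    # textbook pooled-variance two-sample t
    na, nc = a.size, c.size
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nc - 1) * c.var(ddof=1)) / (na + nc - 2))
    t_ref = (a.mean() - c.mean()) / (sp * np.sqrt(1 / na + 1 / nc))
    assert t == pytest.approx(t_ref, abs=1e-12)

    t, p = lag_vs_chance(a, a.copy())
    assert t == 0.0 and p == pytest.approx(1.0)

    # clearly shifted small-variance sample is detected
    rng = np.random.default_rng(11)
    act = 0.02 + 0.002 * rng.standard_normal(7)
    cha = 0.000 + 0.002 * rng.standard_normal(7)
    assert lag_vs_chance(act, cha)[1] < 0.05
    assert lag_vs_chance(act, mode="one-sample")[1] < 0.05
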