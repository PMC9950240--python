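"""ANOVA engine against independent oracles, effect sizes, CIs and power."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist

from avmemory import (
    eta_sq_ci,
    mixed_anova,
    paired_t,
    partial_eta_squared,
    power_one_df_contrast,
    rm_anova,
)
from avmemory.anova import _subset_ss


def _long(Y, factors):
    """Long-form frame from a (subjects, *levels) array."""
    rows = []
    for idx in np.ndindex(Y.shape):
        row = {"subj": f"s{idx[0]}", "value": Y[idx]}
        for f, lev in zip(factors, idx[1:]):
            row[f] = f"l{lev}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated measures


def test_rm_anova_textbook_one_way():
    data = np.array(
        [[45, 50, 55], [42, 45, 48], [36, 41, 43], [39, 35, 40], [51, 55, 59]],
        dtype=float,
    )
    res = rm_anova(_long(data, ["fa"]), dv="value", subject="subj", within=["fa"])
    row = res.effect("fa")
    assert row["SS"] == pytest.approx(103.6)
    assert row["SS_error"] == pytest.approx(36.4)
    assert row["F"] == pytest.approx(103.6 / 2 / (36.4 / 8))
    assert (row["df1"], row["df2"]) == (2, 8)
    assert row["p"] == pytest.approx(float(f_dist.sf(row["F"], 2, 8)))


def test_rm_anova_matches_statsmodels_three_way():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(12)
    Y = rng.standard_normal((10, 2, 2, 3)) + rng.standard_normal((10, 1, 1, 1))
    Y[:, 1] += 0.5  # a real effect so F values are not all tiny
    data = _long(Y, ["fa", "fb", "fc"])
    ours = rm_anova(data, dv="value", subject="subj", within=["fa", "fb", "fc"])
    oracle = AnovaRM(data, depvar="value", subject="subj",
                     within=["fa", "fb", "fc"]).fit().anova_table
    for effect in oracle.index:
        row = ours.effect(effect)
        assert row["F"] == pytest.approx(oracle.loc[effect, "F Value"], abs=1e-8)
        assert row["p"] == pytest.approx(oracle.loc[effect, "Pr > F"], abs=1e-8)
        assert row["df1"] == oracle.loc[effect, "Num DF"]
        assert row["df2"] == oracle.loc[effect, "Den DF"]


def test_rm_anova_two_levels_equals_paired_t():
    rng = np.random.default_rng(13)
    Y = rng.standard_normal((16, 2))
    Y[:, 1] += 0.4
    res = rm_anova(_long(Y, ["fa"]), dv="value", subject="subj", within=["fa"])
    t, df, p = paired_t(Y[:, 0], Y[:, 1])
    row = res.effect("fa")
    assert row["F"] == pytest.approx(t**2)
    assert row["df2"] == df
    assert row["p"] == pytest.approx(p)


def test_rm_anova_sums_of_squares_decompose_total():
    rng = np.random.default_rng(14)
    Y = rng.standard_normal((8, 2, 3))
    res = rm_anova(_long(Y, ["fa", "fb"]), dv="value", subject="subj",
                   within=["fa", "fb"])
    total = float(((Y - Y.mean()) ** 2).sum())
    parts = float(res.table["SS"].sum() + res.table["SS_error"].sum())
    parts += _subset_ss(Y, (0,))  # between-subject SS
    assert parts == pytest.approx(total)


def test_rm_anova_eta_identity():
    rng = np.random.default_rng(15)
    Y = rng.standard_normal((12, 3))
    Y[:, 2] += 0.8
    res = rm_anova(_long(Y, ["fa"]), dv="value", subject="subj", within=["fa"])
    row = res.effect("fa")
    assert row["partial_eta_sq"] == pytest.approx(
        row["F"] * row["df1"] / (row["F"] * row["df1"] + row["df2"])
    )
    assert row["partial_eta_sq"] == pytest.approx(
        row["SS"] / (row["SS"] + row["SS_error"])
    )


def test_rm_anova_input_validation():
    rng = np.random.default_rng(16)
    data = _long(rng.standard_normal((4, 2)), ["fa"])
    with pytest.raises(ValueError, match="unbalanced"):
        rm_anova(data.iloc[:-1], dv="value", subject="subj", within=["fa"])
    dup = pd.concat([data, data.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError):
        rm_anova(dup, dv="value", subject="subj", within=["fa"])
    with pytest.raises(ValueError, match="not in data"):
        rm_anova(data, dv="value", subject="subj", within=["nope"])
    one = data[data["subj"] == "s0"]
    with pytest.raises(ValueError, match="two subjects"):
        rm_anova(one, dv="value", subject="subj", within=["fa"])
    with pytest.raises(ValueError):
        rm_anova(data, dv="value", subject="subj", within=["fa"],
                 sphericity_correction="huynh-feldt")


def test_rm_anova_zero_error_variance_warns():
    Y = np.tile(np.array([[0.0, 1.0]]), (6, 1))  # identical effect, no noise
    with pytest.warns(RuntimeWarning, match="zero error variance"):
        res = rm_anova(_long(Y, ["fa"]), dv="value", subject="subj", within=["fa"])
    assert math.isinf(res.effect("fa")["F"])
    assert res.effect("fa")["partial_eta_sq"] == 1.0


def test_greenhouse_geisser():
    rng = np.random.default_rng(17)
    base = rng.standard_normal((12, 1))
    Y = np.concatenate(
        [base + 0.1 * rng.standard_normal((12, 1)),
         base + 1.0 * rng.standard_normal((12, 1)),
         3.0 * rng.standard_normal((12, 1))],
        axis=1,
    )  # wildly heterogeneous covariance: epsilon well below 1
    plain = rm_anova(_long(Y, ["fa"]), dv="value", subject="subj", within=["fa"])
    gg = rm_anova(_long(Y, ["fa"]), dv="value", subject="subj", within=["fa"],
                  sphericity_correction="greenhouse-geisser")
    eps = gg.table.loc["fa", "gg_epsilon"]
    assert 0.5 <= eps < 1.0
    # matches pingouin.epsilon(..., correction="gg") for this seed
    assert eps == pytest.approx(0.6917427, abs=1e-6)
    F = gg.table.loc["fa", "F"]
    assert F == pytest.approx(plain.table.loc["fa", "F"])
    assert gg.table.loc["fa", "p"] == pytest.approx(
        float(f_dist.sf(F, 2 * eps, 22 * eps))
    )
    # two-level factors are never corrected
    gg2 = rm_anova(_long(Y[:, :2], ["fa"]), dv="value", subject="subj",
                   within=["fa"], sphericity_correction="greenhouse-geisser")
    assert gg2.table.loc["fa", "gg_epsilon"] == 1.0


# ---------------------------------------------------------------------------
# mixed design


def _mixed_data(seed=18, n_per=12):
    rng = np.random.default_rng(seed)
    rows = []
    for g, glab in enumerate(["g1", "g2"]):
        for s in range(n_per):
            subj = f"{glab}_s{s}"
            intercept = rng.standard_normal()
            for w, wlab in enumerate(["w1", "w2"]):
                value = intercept + 0.6 * g * w + rng.standard_normal() * 0.8
                rows.append({"subj": subj, "grp": glab, "fw": wlab,
                             "value": value})
    return pd.DataFrame(rows)


def test_mixed_anova_matches_pingouin():
    import pingouin as pg

    data = _mixed_data()
    ours = mixed_anova(data, dv="value", subject="subj", between="grp",
                       within=["fw"])
    oracle = pg.mixed_anova(data=data, dv="value", within="fw",
                            subject="subj", between="grp").set_index("Source")
    pairs = {"grp": "grp", "fw": "fw", "grp:fw": "Interaction"}
    for ours_name, pg_name in pairs.items():
        row = ours.effect(ours_name)
        assert row["F"] == pytest.approx(oracle.loc[pg_name, "F"], rel=1e-8)
        assert row["p"] == pytest.approx(oracle.loc[pg_name, "p_unc"], rel=1e-6)
        assert row["df1"] == oracle.loc[pg_name, "DF1"]
        assert row["df2"] == oracle.loc[pg_name, "DF2"]
        assert row["partial_eta_sq"] == pytest.approx(
            oracle.loc[pg_name, "np2"], rel=1e-8
        )


def test_mixed_anova_validation():
    data = _mixed_data()
    with pytest.raises(ValueError, match="equal sizes"):
        mixed_anova(data[data["subj"] != "g1_s0"], dv="value", subject="subj",
                    between="grp", within=["fw"])
    bad = data.copy()
    # swap one row each across groups so sizes stay equal but two subjects
    # straddle groups
    row_g1 = bad.index[(bad["subj"] == "g1_s0") & (bad["fw"] == "w1")][0]
    row_g2 = bad.index[(bad["subj"] == "g2_s0") & (bad["fw"] == "w1")][0]
    bad.loc[row_g1, "grp"] = "g2"
    bad.loc[row_g2, "grp"] = "g1"
    with pytest.raises(ValueError, match="exactly one between group"):
        mixed_anova(bad, dv="value", subject="subj", between="grp",
                    within=["fw"])
    single = data[data["grp"] == "g1"]
    with pytest.warns(RuntimeWarning, match="single between-subject group"):
        res = mixed_anova(single, dv="value", subject="subj", between="grp",
                          within=["fw"])
    assert res.design == "repeated-measures"


def test_mixed_anova_two_within_factors_runs():
    rng = np.random.default_rng(19)
    rows = []
    for g in ("g1", "g2"):
        for s in range(8):
            for w1 in ("a", "b"):
                for w2 in ("x", "y", "z"):
                    rows.append({"subj": f"{g}{s}", "grp": g, "f1": w1,
                                 "f2": w2, "value": rng.standard_normal()})
    res = mixed_anova(pd.DataFrame(rows), dv="value", subject="subj",
                      between="grp", within=["f1", "f2"])
    assert set(res.table.index) == {
        "grp", "f1", "grp:f1", "f2", "grp:f2", "f1:f2", "grp:f1:f2",
    }
    assert res.effect("f1:f2")["df2"] == 2 * (16 - 2)


# ---------------------------------------------------------------------------
# t-test edge cases


def test_paired_t_basic():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([0.5, 1.0, 2.0, 3.5])
    t, df, p = paired_t(x, y)
    from scipy.stats import ttest_rel

    ref = ttest_rel(x, y)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    assert df == 3


def test_paired_t_zero_variance():
    assert paired_t([1.0, 2.0], [1.0, 2.0]) == (0.0, 1, 1.0)
    with pytest.warns(RuntimeWarning, match="infinite"):
        t, df, p = paired_t([2.0, 3.0], [1.0, 2.0])
    assert math.isinf(t) and p == 0.0
    with pytest.raises(ValueError):
        paired_t([1.0], [2.0])


# ---------------------------------------------------------------------------
# effect sizes, CIs, power


def test_partial_eta_squared_published_values():
    assert round(partial_eta_squared(10.18, 1, 23), 2) == 0.31
    assert round(partial_eta_squared(44.38, 1, 23), 2) == 0.66
    assert round(partial_eta_squared(9.82, 1, 46), 2) == 0.18
    assert partial_eta_squared(math.inf, 1, 10) == 1.0
    with pytest.raises(ValueError):
        partial_eta_squared(-1.0, 1, 10)


@pytest.mark.parametrize(
    "F,df1,df2,n,lo,hi",
    [
        (10.18, 1, 23, 24, 0.04, 0.53),
        (16.39, 1, 23, 24, 0.11, 0.61),
        (44.38, 1, 23, 24, 0.38, 0.78),
        (9.82, 1, 46, 48, 0.02, 0.36),
    ],
)
def test_eta_sq_ci_reproduces_published_intervals(F, df1, df2, n, lo, hi):
    got_lo, got_hi = eta_sq_ci(F, df1, df2, n_total=n)
    assert round(got_lo, 2) == lo
    assert round(got_hi, 2) == hi


def test_eta_sq_ci_conventions_and_floors():
    df_ci = eta_sq_ci(10.18, 1, 23, n_total=24, convention="df")
    n_ci = eta_sq_ci(10.18, 1, 23, n_total=24, convention="n")
    assert df_ci != n_ci
    lo, hi = eta_sq_ci(0.5, 1, 23, n_total=24)
    assert lo == pytest.approx(0.0, abs=1e-6) and hi < 0.3
    with pytest.raises(ValueError):
        eta_sq_ci(1.0, 1, 10, n_total=11, level=1.2)
    with pytest.raises(ValueError):
        eta_sq_ci(1.0, 1, 10, n_total=11, convention="N")


def test_eta_sq_ci_covers_point_estimate():
    for F in (3.0, 8.0, 20.0):
        lo, hi = eta_sq_ci(F, 1, 23, n_total=24)
        assert lo <= partial_eta_squared(F, 1, 23) <= hi


def test_add_eta_ci_attaches_columns():
    rng = np.random.default_rng(20)
    Y = rng.standard_normal((10, 2))
    Y[:, 1] += 1.0
    res = rm_anova(_long(Y, ["fa"]), dv="value", subject="subj",
                   within=["fa"]).add_eta_ci()
    assert {"eta_ci_low", "eta_ci_high"} <= set(res.table.columns)
    row = res.effect("fa")
    assert row["eta_ci_low"] <= row["partial_eta_sq"] <= row["eta_ci_high"]
    assert "F(" in res.summary()


def test_power_reproduces_planning_value():
    assert round(power_one_df_contrast(0.28, 24), 2) == 0.82


def test_power_monotone_and_validated():
    p12 = power_one_df_contrast(0.28, 12)
    p24 = power_one_df_contrast(0.28, 24)
    p48 = power_one_df_contrast(0.28, 48)
    assert p12 < p24 < p48
    assert power_one_df_contrast(0.0, 24) == pytest.approx(0.05, abs=0.005)
    assert power_one_df_contrast(0.28, 24, convention="n") > p24
    with pytest.raises(ValueError):
        power_one_df_contrast(1.0, 24)
    with pytest.raises(ValueError):
        power_one_df_contrast(0.2, 1)


def test_type_one_error_calibration_quick():
    """Null rejection rate of each effect near alpha (coarse; the acceptance
    suite runs the high-replicate version)."""
    rng = np.random.default_rng(21)
    n, reps = 20, 400
    template = _long(np.zeros((n, 2, 2)), ["fa", "fb"])
    rej = {"fa": 0, "fb": 0, "fa:fb": 0}
    for _ in range(reps):
        df = template.copy()
        df["value"] = rng.standard_normal(len(df)) + np.repeat(
            rng.standard_normal(n), 4
        )
        res = rm_anova(df, dv="value", subject="subj", within=["fa", "fb"])
        for e in rej:
            rej[e] += res.table.loc[e, "p"] < 0.05
    for e, k in rej.items():
        assert 0.02 <= k / reps <= 0.09, (e, k / reps)
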