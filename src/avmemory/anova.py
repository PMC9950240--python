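"""Within-subject and mixed ANOVAs, paired t-tests, partial eta-squared with
noncentral-F confidence intervals, and the a-priori power computation.

The ANOVA engine targets exactly the designs of balanced study-test
congruency experiments: complete within-subject factorials (up to four
factors) and mixed designs with one equal-sized between-subject factor.  Sums
of squares come from the classical marginal-mean decomposition; each
within-subject effect is tested against its own effect-by-subject interaction
(no sphericity correction by default, Greenhouse-Geisser behind a flag), and
between-subject effects against subjects-within-groups.  All p-values are
two-sided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import f as f_dist, ncf, nct, t as t_dist

__all__ = [
    "AnovaResult",
    "rm_anova",
    "mixed_anova",
    "paired_t",
    "partial_eta_squared",
    "eta_sq_ci",
    "power_one_df_contrast",
]


# ---------------------------------------------------------------------------
# sums-of-squares machinery


def _subset_ss(Y: np.ndarray, axes: tuple[int, ...]) -> float:
    """SS of the pure interaction effect of ``axes`` in a balanced array.

    ``Y`` has one axis per factor with one observation per cell.  The effect
    estimate at each cell is the inclusion-exclusion alternating sum of
    marginal means over subsets of ``axes``; the SS is its square summed over
    all cells (each marginal estimate is implicitly replicated over the
    remaining axes, which supplies the usual multiplier).
    """
    hat = np.zeros_like(Y, dtype=float)
    k = len(axes)
    for r in range(k + 1):
        for sub in itertools.combinations(axes, r):
            drop = tuple(ax for ax in range(Y.ndim) if ax not in sub)
            m = Y.mean(axis=drop, keepdims=True) if drop else Y
            hat = hat + ((-1) ** (k - r)) * m
    return float((hat**2).sum())


def _pivot(data: pd.DataFrame, dv: str, subject: str,
           factors: list[str]) -> tuple[np.ndarray, list[list], list]:
    """Complete balanced array with axes (subject, *factors)."""
    for col in (dv, subject, *factors):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    subjects = sorted(data[subject].unique())
    levels = [sorted(data[f].unique()) for f in factors]
    shape = (len(subjects), *(len(l) for l in levels))
    expected = int(np.prod(shape))
    if len(data) != expected:
        raise ValueError(
            f"unbalanced data: expected {expected} rows "
            f"({len(subjects)} subjects x full factorial), got {len(data)}; "
            "aggregate or impute before the ANOVA"
        )
    idx = {subject: {s: i for i, s in enumerate(subjects)}}
    for f, ls in zip(factors, levels):
        idx[f] = {l: i for i, l in enumerate(ls)}
    Y = np.full(shape, np.nan)
    for row in data.itertuples(index=False):
        d = dict(zip(data.columns, row))
        key = (idx[subject][d[subject]],
               *(idx[f][d[f]] for f in factors))
        if not np.isnan(Y[key]):
            raise ValueError("duplicate subject x cell observation")
        Y[key] = d[dv]
    if np.isnan(Y).any():
        raise ValueError("unbalanced data: missing subject x cell combinations")
    return Y, levels, subjects


@dataclass
class AnovaResult:
    """Effect table of an ANOVA.

    ``table`` has one row per effect with F, degrees of freedom, p, and
    partial eta-squared (which satisfies
    ``peta2 = F*df1 / (F*df1 + df2)`` exactly).
    """

    table: pd.DataFrame
    n_subjects: int
    design: str

    def effect(self, name: str) -> pd.Series:
        if name not in self.table.index:
            raise KeyError(
                f"no effect {name!r}; available: {list(self.table.index)}"
            )
        return self.table.loc[name]

    def add_eta_ci(self, level: float = 0.95) -> "AnovaResult":
        """Attach noncentral-F confidence intervals for partial eta-squared."""
        lows, highs = [], []
        for _, row in self.table.iterrows():
            if not math.isfinite(row["F"]):
                lows.append(np.nan)
                highs.append(np.nan)
                continue
            lo, hi = eta_sq_ci(
                row["F"], int(row["df1"]), int(row["df2"]),
                n_total=self.n_subjects, level=level,
            )
            lows.append(lo)
            highs.append(hi)
        self.table["eta_ci_low"] = lows
        self.table["eta_ci_high"] = highs
        return self

    def summary(self) -> str:
        lines = [f"{self.design} ANOVA ({self.n_subjects} participants)"]
        for name, row in self.table.iterrows():
            lines.append(
                f"  {name}: F({int(row['df1'])}, {int(row['df2'])}) = "
                f"{row['F']:.2f}, p = {row['p']:.4f}, "
                f"partial eta^2 = {row['partial_eta_sq']:.3f}"
            )
        return "\n".join(lines)


def _effect_rows(effects: list[tuple[str, float, int, float, int]]) -> pd.DataFrame:
    rows = []
    for name, ss_e, df_e, ss_err, df_err in effects:
        ms_err = ss_err / df_err if df_err else np.nan
        if ms_err == 0 or not math.isfinite(ms_err):
            F = math.inf if ss_e > 0 else 0.0
            p = 0.0 if ss_e > 0 else 1.0
            warnings.warn(
                f"effect {name}: zero error variance, F is infinite",
                RuntimeWarning, stacklevel=3,
            )
        else:
            F = (ss_e / df_e) / ms_err
            p = float(f_dist.sf(F, df_e, df_err))
        rows.append(
            {
                "effect": name,
                "F": F,
                "df1": df_e,
                "df2": df_err,
                "p": p,
                "partial_eta_sq": partial_eta_squared(F, df_e, df_err),
                "SS": ss_e,
                "SS_error": ss_err,
            }
        )
    return pd.DataFrame(rows).set_index("effect")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    sphericity_correction: str = "none",
) -> AnovaResult:
    """Repeated-measures ANOVA on a complete balanced within-subject design.

    ``data`` is long-form with one row per subject x cell.  Every main effect
    and interaction of the ``within`` factors is tested against its
    interaction with subjects.  ``sphericity_correction='greenhouse-geisser'``
    adjusts dfs and p for effects with more than one numerator df.
    """
    Y, levels, subjects = _pivot(data, dv, subject, list(within))
    n_subj = len(subjects)
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    effects = []
    w_axes = {f: ax + 1 for ax, f in enumerate(within)}
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            axes = tuple(w_axes[f] for f in combo)
            ss_e = _subset_ss(Y, axes)
            df_e = int(np.prod([len(levels[w_axes[f] - 1]) - 1 for f in combo]))
            ss_err = _subset_ss(Y, (0, *axes))
            df_err = df_e * (n_subj - 1)
            effects.append((":".join(combo), ss_e, df_e, ss_err, df_err))
    result = AnovaResult(_effect_rows(effects), n_subjects=n_subj,
                         design="repeated-measures")
    if sphericity_correction == "greenhouse-geisser":
        _apply_gg(result, Y, within, w_axes, levels)
    elif sphericity_correction != "none":
        raise ValueError("sphericity_correction must be 'none' or "
                         "'greenhouse-geisser'")
    return result


def _apply_gg(result: AnovaResult, Y, within, w_axes, levels) -> None:
    """Greenhouse-Geisser epsilon per effect with numerator df > 1."""
    for name in result.table.index:
        combo = name.split(":")
        df1 = int(result.table.loc[name, "df1"])
        if df1 < 2:
            result.table.loc[name, "gg_epsilon"] = 1.0
            continue
        axes = tuple(w_axes[f] for f in combo)
        other = tuple(ax for ax in range(1, Y.ndim) if ax not in axes)
        M = Y.mean(axis=other) if other else Y  # subjects x effect cells
        M = M.reshape(M.shape[0], -1)
        # epsilon from the covariance of the effect's cell scores
        S = np.cov(M.T)
        k = S.shape[0]
        mean_diag = np.trace(S) / k
        mean_all = S.mean()
        num = (k * (mean_diag - mean_all)) ** 2
        den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum()
                         + k * k * mean_all**2)
        eps = 1.0 if den == 0 else float(np.clip(num / den, 1.0 / (k - 1), 1.0))
        F = result.table.loc[name, "F"]
        df2 = int(result.table.loc[name, "df2"])
        result.table.loc[name, "gg_epsilon"] = eps
        result.table.loc[name, "p"] = float(f_dist.sf(F, df1 * eps, df2 * eps))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
) -> AnovaResult:
    """Mixed ANOVA: one between-subject factor (equal group sizes) crossed
    with balanced within-subject factors.

    The between effect is tested against subjects-within-groups; every
    within-involved effect against its interaction with subjects-within-
    groups.  A single between group degenerates to :func:`rm_anova` with a
    warning.
    """
    groups = data.groupby(between)[subject].nunique()
    if len(groups) < 2:
        warnings.warn(
            "single between-subject group: degenerating to a repeated-"
            "measures ANOVA", RuntimeWarning, stacklevel=2,
        )
        return rm_anova(data, dv, subject, within)
    if groups.nunique() != 1:
        raise ValueError(f"between groups must have equal sizes; got {dict(groups)}")
    # subjects must be nested in between
    if (data.groupby(subject)[between].nunique() > 1).any():
        raise ValueError("each subject must belong to exactly one between group")

    Y, levels, subjects = _pivot(data, dv, subject, list(within))
    n_subj = len(subjects)
    group_of = data.drop_duplicates(subject).set_index(subject)[between]
    glevels = sorted(group_of.unique())
    n_groups = len(glevels)
    n_per = n_subj // n_groups
    gidx = np.array([glevels.index(group_of[s]) for s in subjects])

    # lattice of cell means over subjects within group: axes (B, *within)
    shape = (n_groups, *Y.shape[1:])
    L = np.zeros(shape)
    for g in range(n_groups):
        L[g] = Y[gidx == g].mean(axis=0)

    w_axes_Y = {f: ax + 1 for ax, f in enumerate(within)}
    w_axes_L = {f: ax + 1 for ax, f in enumerate(within)}

    effects = []
    # between-subject stratum
    ss_b = n_per * _subset_ss(L, (0,))
    ss_subj_total = _subset_ss(Y, (0,))
    ss_sb = ss_subj_total - ss_b  # subjects within groups
    df_sb = n_subj - n_groups
    effects.append((between, ss_b, n_groups - 1, ss_sb, df_sb))
    # within strata
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            axesY = tuple(w_axes_Y[f] for f in combo)
            axesL = tuple(w_axes_L[f] for f in combo)
            df_e = int(np.prod([len(levels[w_axes_Y[f] - 1]) - 1 for f in combo]))
            ss_e = n_per * _subset_ss(L, axesL)
            ss_bx = n_per * _subset_ss(L, (0, *axesL))
            ss_err = _subset_ss(Y, (0, *axesY)) - ss_bx
            df_err = df_e * (n_subj - n_groups)
            effects.append((":".join(combo), ss_e, df_e, ss_err, df_err))
            effects.append(
                (f"{between}:" + ":".join(combo), ss_bx,
                 df_e * (n_groups - 1), ss_err, df_err)
            )
    return AnovaResult(_effect_rows(effects), n_subjects=n_subj, design="mixed")


# ---------------------------------------------------------------------------
# t-tests, effect sizes, power


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test on the differences; returns (t, df, p).

    Zero-variance differences yield t = 0 (p = 1) when the mean difference is
    zero and an infinite t (p = 0, with a warning) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 pairs")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, n - 1, 1.0
        warnings.warn("zero-variance differences: t is infinite",
                      RuntimeWarning, stacklevel=2)
        return math.copysign(math.inf, d.mean()), n - 1, 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t), n - 1))
    return float(t), n - 1, p


def partial_eta_squared(F: float, df_effect: int, df_error: int) -> float:
    """Partial eta-squared recovered from F and its degrees of freedom."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if math.isinf(F):
        return 1.0
    return (F * df_effect) / (F * df_effect + df_error)


def _lambda_solve(F: float, df1: int, df2: int, target: float) -> float:
    """Noncentrality with P(F' >= F_obs) = target, floored at 0."""

    def g(lam: float) -> float:
        return float(ncf.sf(F, df1, df2, lam)) - target

    if g(0.0) >= 0.0:
        return 0.0
    hi = 1.0
    while g(hi) < 0.0:
        hi *= 2.0
        if hi > 1e7:  # pragma: no cover - pathological input
            return hi
    return float(brentq(g, 0.0, hi, xtol=1e-10))


def eta_sq_ci(
    F: float, df_effect: int, df_error: int, n_total: int,
    level: float = 0.95, convention: str = "df",
) -> tuple[float, float]:
    """Confidence interval for partial eta-squared via the noncentral-F pivot.

    The noncentrality bounds solve P(F' >= F_obs) = (1 - level)/2 and
    (1 + level)/2.  Under the default ``convention='df'`` they convert through
    eta^2 = lambda / (lambda + df_effect + df_error + 1), the conversion that
    reproduces published intervals for these designs; ``convention='n'`` uses
    lambda / (lambda + n_total) with ``n_total`` the number of participants.
    The lower bound is floored at 0 when no non-negative noncentrality
    satisfies the equation.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if convention not in {"df", "n"}:
        raise ValueError("convention must be 'df' or 'n'")
    alpha = 1.0 - level
    lam_a = _lambda_solve(F, df_effect, df_error, 1.0 - alpha / 2.0)
    lam_b = _lambda_solve(F, df_effect, df_error, alpha / 2.0)
    # sf is increasing in lambda, so the small-sf solution is the LOWER lambda
    lam_lo, lam_hi = min(lam_a, lam_b), max(lam_a, lam_b)
    denom = (df_effect + df_error + 1) if convention == "df" else n_total
    return (
        lam_lo / (lam_lo + denom),
        lam_hi / (lam_hi + denom),
    )


def power_one_df_contrast(
    eta_sq: float, n: int, alpha: float = 0.05, convention: str = "n-1"
) -> float:
    """Power of a two-sided one-df within-subject contrast at effect size
    eta^2 and sample size n.

    Cohen's f^2 = eta^2 / (1 - eta^2); the noncentrality is
    sqrt(f^2 * (n - 1)) under the default convention (sqrt(f^2 * n) under
    ``convention='n'``) and power comes from the noncentral t distribution
    with n - 1 df.
    """
    if not 0.0 <= eta_sq < 1.0:
        raise ValueError("eta_sq must lie in [0, 1)")
    if n < 2:
        raise ValueError("n must be at least 2")
    f2 = eta_sq / (1.0 - eta_sq)
    mult = (n - 1) if convention == "n-1" else n
    if convention not in {"n-1", "n"}:
        raise ValueError("convention must be 'n-1' or 'n'")
    delta = math.sqrt(f2 * mult)
    df = n - 1
    tcrit = float(t_dist.ppf(1.0 - alpha / 2.0, df))
    return float(nct.sf(tcrit, df, delta) + nct.cdf(-tcrit, df, delta))
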