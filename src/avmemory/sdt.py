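"""Equal-variance signal detection: d', criterion c, condition summaries,
and within-subject confidence intervals.

Sensitivity is d' = z(H) - z(F) and the response criterion is
c = -(z(H) + z(F)) / 2, with z the standard-normal quantile.  Positive c is a
conservative bias toward answering "new".  Extreme rates (0 or 1) make z
infinite, so a correction is applied before the transform; the log-linear
correction (add 0.5 to each response count, 1 to each total) is the default
and is applied to every cell uniformly, because correcting only boundary cells
would bias condition contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .design import SDTCell

__all__ = [
    "SDTEstimate",
    "corrected_rates",
    "dprime_criterion",
    "cell_estimate",
    "estimates_frame",
    "condition_summary",
    "condition_matrix",
    "within_subject_ci",
]


@dataclass(frozen=True)
class SDTEstimate:
    """Hit/false-alarm rates with derived sensitivity and criterion."""

    hit_rate: float
    fa_rate: float
    dprime: float
    criterion_c: float
    correction_applied: bool = False


def corrected_rates(
    cell: SDTCell, method: str = "loglinear"
) -> tuple[float, float]:
    """Hit and false-alarm rates for a cell under an extreme-rate correction.

    ``loglinear``
        (hits + 0.5) / (n_old + 1) and (fa + 0.5) / (n_foil + 1).
    ``clamp``
        raw rates, with 0 replaced by 1/(2N) and 1 by 1 - 1/(2N).
    ``none``
        raw rates; a boundary rate triggers a warning since z diverges.
    """
    n_old, n_foil = cell.n_old, cell.n_foil
    if n_old < 1 or n_foil < 1:
        raise ValueError(
            f"cell needs at least one old and one foil trial "
            f"(got {n_old} old, {n_foil} foil)"
        )
    if method == "loglinear":
        return (cell.hits + 0.5) / (n_old + 1), (cell.false_alarms + 0.5) / (n_foil + 1)
    if method == "clamp":
        h = cell.hits / n_old
        f = cell.false_alarms / n_foil
        h = min(max(h, 1.0 / (2 * n_old)), 1.0 - 1.0 / (2 * n_old))
        f = min(max(f, 1.0 / (2 * n_foil)), 1.0 - 1.0 / (2 * n_foil))
        return h, f
    if method == "none":
        h = cell.hits / n_old
        f = cell.false_alarms / n_foil
        if h in (0.0, 1.0) or f in (0.0, 1.0):
            warnings.warn(
                "boundary hit/false-alarm rate with correction 'none'; "
                "d' will be infinite",
                RuntimeWarning,
                stacklevel=2,
            )
        return h, f
    raise ValueError(f"unknown correction method {method!r}")


def dprime_criterion(hit_rate: float, fa_rate: float) -> SDTEstimate:
    """Sensitivity and criterion from rates strictly inside (0, 1)."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError(
            "rates must lie strictly in (0, 1); apply corrected_rates first"
        )
    zh = norm.ppf(hit_rate)
    zf = norm.ppf(fa_rate)
    return SDTEstimate(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        dprime=zh - zf,
        criterion_c=-(zh + zf) / 2.0,
    )


def cell_estimate(cell: SDTCell, correction: str = "loglinear") -> SDTEstimate:
    """Convenience: corrected rates then d'/c for one cell."""
    h, f = corrected_rates(cell, method=correction)
    est = dprime_criterion(h, f)
    return SDTEstimate(
        hit_rate=h,
        fa_rate=f,
        dprime=est.dprime,
        criterion_c=est.criterion_c,
        correction_applied=correction != "none",
    )


def estimates_frame(
    cells: list[SDTCell], correction: str = "loglinear"
) -> pd.DataFrame:
    """Long table with one row per cell: condition labels, counts, d' and c."""
    rows = []
    for cell in cells:
        est = cell_estimate(cell, correction=correction)
        rows.append(
            {
                "participant_id": cell.participant_id,
                "study_modality": cell.study_modality.value,
                "test_modality": cell.test_modality.value,
                "clip_length": float(cell.clip_length),
                "visual_quality": cell.visual_quality.value,
                "hits": cell.hits,
                "misses": cell.misses,
                "false_alarms": cell.false_alarms,
                "correct_rejections": cell.correct_rejections,
                "hit_rate": est.hit_rate,
                "fa_rate": est.fa_rate,
                "dprime": est.dprime,
                "criterion_c": est.criterion_c,
            }
        )
    return pd.DataFrame(rows)


_CONDITION_COLS = ["study_modality", "test_modality", "clip_length", "visual_quality"]


def condition_summary(
    cells: list[SDTCell],
    correction: str = "loglinear",
    allow_missing: bool = False,
    pool_lengths: bool = False,
) -> pd.DataFrame:
    """Per-condition means and SDs of d' and c over participants.

    One row per condition with numeric ``dprime_mean``/``dprime_sd``/
    ``c_mean``/``c_sd`` columns plus formatted ``"M (SD)"`` strings mirroring
    how such tables are printed.  With ``pool_lengths`` the participant value
    entering the summary is the mean over that participant's length cells.
    Unless ``allow_missing``, every participant must contribute every
    condition.
    """
    frame = estimates_frame(cells, correction=correction)
    cond_cols = [c for c in _CONDITION_COLS if c != "clip_length"] if pool_lengths \
        else _CONDITION_COLS
    if pool_lengths:
        frame = (
            frame.groupby(["participant_id", *cond_cols], as_index=False)[
                ["dprime", "criterion_c"]
            ].mean()
        )
    counts = frame.groupby(cond_cols)["participant_id"].nunique()
    n_participants = frame["participant_id"].nunique()
    if not allow_missing and (counts != n_participants).any():
        bad = counts[counts != n_participants]
        raise ValueError(
            "unbalanced data: conditions missing participants: "
            f"{list(bad.index)}; pass allow_missing=True to summarise anyway"
        )
    grouped = frame.groupby(cond_cols)
    out = grouped.agg(
        dprime_mean=("dprime", "mean"),
        dprime_sd=("dprime", "std"),
        c_mean=("criterion_c", "mean"),
        c_sd=("criterion_c", "std"),
        n=("participant_id", "nunique"),
    ).reset_index()
    out["dprime_fmt"] = [
        f"{m:.2f} ({s:.2f})" for m, s in zip(out["dprime_mean"], out["dprime_sd"])
    ]
    out["c_fmt"] = [
        f"{m:.2f} ({s:.2f})" for m, s in zip(out["c_mean"], out["c_sd"])
    ]
    return out


def condition_matrix(
    cells: list[SDTCell],
    value: str = "dprime",
    correction: str = "loglinear",
    pool_lengths: bool = True,
) -> pd.DataFrame:
    """Participants × conditions matrix of d' (or c), for ANOVA and CI layers."""
    frame = estimates_frame(cells, correction=correction)
    cond_cols = [c for c in _CONDITION_COLS if c != "clip_length"] if pool_lengths \
        else _CONDITION_COLS
    col = "criterion_c" if value in ("c", "criterion_c") else "dprime"
    wide = frame.pivot_table(
        index="participant_id", columns=cond_cols, values=col, aggfunc="mean"
    )
    return wide


def within_subject_ci(
    matrix, level: float = 0.95, method: str = "cousineau-morey"
) -> np.ndarray:
    """Per-condition confidence half-widths appropriate for repeated measures.

    ``cousineau-morey``: subtract each participant's mean and add the grand
    mean, scale the normalized per-condition variance by J/(J-1) for J
    conditions, and take t(level, n-1) times the corrected standard error.
    ``loftus-masson``: a single half-width per condition from the pooled
    subject-by-condition interaction mean square.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a participants x conditions matrix")
    n, j = X.shape
    if j < 2:
        raise ValueError("need at least two conditions")
    if np.isnan(X).any():
        raise ValueError("matrix must be complete (no missing cells)")
    if method == "cousineau-morey":
        normalized = X - X.mean(axis=1, keepdims=True) + X.mean()
        var = normalized.var(axis=0, ddof=1) * (j / (j - 1))
        se = np.sqrt(var / n)
        return t_dist.ppf(0.5 + level / 2.0, n - 1) * se
    if method == "loftus-masson":
        resid = X - X.mean(axis=1, keepdims=True) - X.mean(axis=0) + X.mean()
        ms_interaction = (resid**2).sum() / ((n - 1) * (j - 1))
        half = t_dist.ppf(0.5 + level / 2.0, (n - 1) * (j - 1)) * np.sqrt(
            ms_interaction / n
        )
        return np.full(j, half)
    raise ValueError(f"unknown within-subject CI method {method!r}")
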