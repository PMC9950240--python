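"""Synthetic recognition-experiment data with configurable memory structure.

Two generators live here.  :func:`simulate_counts` draws aggregated hit counts
from the binomial model underlying the Bayesian integration analysis, with the
audio-visual rate tied to the probability-summation criterion through the
indicator ratio ``x_ind``.  :func:`simulate_experiment` produces trial-level
data for the congruency experiments from an equal-variance Gaussian
signal-detection observer whose per-condition sensitivity and criterion are
drawn around published condition means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .design import (
    DesignSpec,
    RecognitionCounts,
    TrialRecord,
    build_design,
)

__all__ = [
    "TrueRates",
    "CellParams",
    "GenerativeParams",
    "DEFAULT_REANALYSIS_RATES",
    "simulate_counts",
    "simulate_experiment",
    "default_generative_params",
]


@dataclass(frozen=True)
class TrueRates:
    """Ground-truth rates for the aggregated binomial generator.

    ``theta_a``/``theta_v`` are the unimodal hit probabilities; the
    audio-visual probability is ``x_ind`` times the probability-summation
    criterion ``theta_a + theta_v - theta_a*theta_v``, so ``x_ind = 1`` encodes
    exactly independent retrieval cues, values below 1 sub-additivity.
    """

    theta_a: float
    theta_v: float
    x_ind: float
    n_per_modality: int

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_a < 1.0 and 0.0 < self.theta_v < 1.0):
            raise ValueError("theta_a and theta_v must lie strictly in (0, 1)")
        if self.x_ind <= 0:
            raise ValueError("x_ind must be positive")
        if self.theta_av > 1.0:
            raise ValueError(
                f"x_ind * probability-summation criterion = {self.theta_av:.4f} > 1"
            )
        if self.n_per_modality < 0:
            raise ValueError("n_per_modality must be non-negative")

    @property
    def theta_crt(self) -> float:
        """Probability-summation criterion for independent retrieval cues."""
        return self.theta_a + self.theta_v - self.theta_a * self.theta_v

    @property
    def theta_av(self) -> float:
        return self.x_ind * self.theta_crt


#: Regime of the pooled two-session recognition study the Bayesian model
#: reanalyses: 48 participants x 150 old trials per modality, with unimodal
#: rates whose probability summation sits at 0.829 and an indicator ratio of
#: 0.89 (audio-visual rate ~0.74).
DEFAULT_REANALYSIS_RATES = TrueRates(
    theta_a=0.55, theta_v=0.62, x_ind=0.89, n_per_modality=7200
)


def simulate_counts(rates: TrueRates, seed: int) -> RecognitionCounts:
    """Draw per-modality hit counts: y_m ~ Binomial(n, theta_m)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = rates.n_per_modality
    return RecognitionCounts(
        n_a=n,
        y_a=int(rng.binomial(n, rates.theta_a)) if n else 0,
        n_v=n,
        y_v=int(rng.binomial(n, rates.theta_v)) if n else 0,
        n_av=n,
        y_av=int(rng.binomial(n, rates.theta_av)) if n else 0,
    )


# ---------------------------------------------------------------------------
# Trial-level generator


@dataclass(frozen=True)
class CellParams:
    """Population mean and between-participant SD of d' and c for one cell."""

    mu_dprime: float
    sd_dprime: float
    mu_crit: float
    sd_crit: float

    def __post_init__(self) -> None:
        if self.sd_dprime < 0 or self.sd_crit < 0:
            raise ValueError("between-participant SDs must be non-negative")


ConditionKey = tuple[str, str, float, str]  # (study, test, length, quality)


@dataclass(frozen=True)
class GenerativeParams:
    """Population parameters of the simulated observers.

    ``cells`` maps condition keys ``(study, test, clip_length, quality)`` to
    :class:`CellParams`.  ``shared_var_frac`` is the fraction of the
    between-participant variance carried by a participant-level intercept
    common to all conditions; the remainder is condition-specific.  Published
    condition SDs conflate both sources, and recognition studies of this kind
    report large correlations between repeated measures, so the default puts
    most of the variance in the shared intercept.  Set it to 0 for fully
    independent per-condition draws.
    """

    cells: Mapping[ConditionKey, CellParams]
    shared_var_frac: float = 0.7
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_var_frac <= 1.0:
            raise ValueError("shared_var_frac must lie in [0, 1]")

    def cell(self, key: ConditionKey) -> CellParams:
        try:
            return self.cells[key]
        except KeyError:
            raise KeyError(f"no generative parameters for condition {key}") from None


# Published per-condition means (SDs) of d' and criterion c, by experiment,
# condition (study/test[/quality]) and clip length in seconds.  Values are
# (mu_d, sd_d, mu_c, sd_c) at lengths 3.0, 3.5, 4.0.
_TABLE: dict[str, dict[tuple[str, str, str], tuple[tuple[float, ...], ...]]] = {
    "1a": {
        ("av", "av", "normal"): ((0.88, 0.62, 0.31, 0.39),
                                 (1.05, 0.67, 0.27, 0.37),
                                 (1.17, 0.76, 0.25, 0.38)),
        ("av", "v", "normal"): ((0.83, 0.65, 0.49, 0.37),
                                (0.82, 0.67, 0.40, 0.33),
                                (0.80, 0.61, 0.37, 0.35)),
        ("v", "av", "normal"): ((0.70, 0.68, 0.49, 0.39),
                                (0.70, 0.75, 0.36, 0.33),
                                (0.79, 0.59, 0.38, 0.35)),
        ("v", "v", "normal"): ((0.78, 0.55, 0.46, 0.31),
                               (0.74, 0.71, 0.41, 0.33),
                               (0.86, 0.62, 0.43, 0.33)),
    },
    "1b": {
        ("v", "av", "normal"): ((1.00, 0.38, 0.52, 0.50),
                                (0.90, 0.36, 0.47, 0.45),
                                (1.04, 0.40, 0.49, 0.47)),
        ("v", "v", "normal"): ((0.89, 0.34, 0.55, 0.45),
                               (0.97, 0.41, 0.50, 0.46),
                               (1.02, 0.43, 0.52, 0.44)),
    },
    "2": {
        ("av", "av", "normal"): ((0.98, 0.82, 0.01, 0.30),
                                 (1.00, 0.95, -0.07, 0.27),
                                 (1.05, 0.92, -0.15, 0.36)),
        ("av", "a", "normal"): ((0.60, 0.54, 0.60, 0.24),
                                (0.60, 0.60, 0.46, 0.31),
                                (0.61, 0.73, 0.38, 0.34)),
        ("a", "av", "normal"): ((0.29, 0.41, 0.35, 0.27),
                                (0.34, 0.55, 0.30, 0.40),
                                (0.35, 0.54, 0.30, 0.36)),
        ("a", "a", "normal"): ((0.50, 0.51, 0.63, 0.35),
                               (0.44, 0.61, 0.51, 0.25),
                               (0.57, 0.70, 0.41, 0.24)),
    },
    "3": {
        ("a", "a", "normal"): ((0.62, 0.49, 0.79, 0.43),
                               (0.74, 0.48, 0.67, 0.39),
                               (0.86, 0.51, 0.62, 0.45)),
        ("a", "av", "normal"): ((0.30, 0.35, 0.54, 0.36),
                                (0.41, 0.49, 0.50, 0.40),
                                (0.43, 0.42, 0.40, 0.38)),
        ("v", "v", "normal"): ((0.90, 0.47, 0.41, 0.41),
                               (0.91, 0.55, 0.38, 0.47),
                               (0.96, 0.56, 0.41, 0.45)),
        ("v", "av", "normal"): ((0.72, 0.44, 0.33, 0.42),
                                (0.78, 0.51, 0.31, 0.40),
                                (0.73, 0.48, 0.29, 0.47)),
    },
    "4": {
        ("av", "av", "normal"): ((1.32, 0.78, 0.12, 0.46),
                                 (1.33, 0.74, -0.02, 0.44),
                                 (1.34, 0.71, -0.03, 0.41)),
        ("av", "v", "normal"): ((0.97, 0.58, 0.08, 0.40),
                                (1.12, 0.62, 0.07, 0.52),
                                (1.11, 0.63, 0.15, 0.41)),
        ("v", "av", "normal"): ((0.83, 0.58, 0.21, 0.40),
                                (0.97, 0.62, 0.12, 0.44),
                                (1.01, 0.58, 0.15, 0.36)),
        ("v", "v", "normal"): ((0.97, 0.60, 0.18, 0.41),
                               (1.18, 0.69, 0.11, 0.43),
                               (1.18, 0.60, 0.17, 0.46)),
        ("av", "av", "degraded"): ((0.87, 0.63, 0.35, 0.52),
                                   (0.90, 0.40, 0.30, 0.49),
                                   (1.00, 0.69, 0.25, 0.40)),
        ("av", "v", "degraded"): ((0.42, 0.48, 0.54, 0.54),
                                  (0.47, 0.49, 0.54, 0.53),
                                  (0.42, 0.34, 0.42, 0.44)),
        ("v", "av", "degraded"): ((0.35, 0.39, 0.60, 0.52),
                                  (0.40, 0.45, 0.52, 0.52),
                                  (0.37, 0.41, 0.43, 0.51)),
        ("v", "v", "degraded"): ((0.50, 0.33, 0.56, 0.56),
                                 (0.35, 0.51, 0.49, 0.56),
                                 (0.49, 0.54, 0.55, 0.54)),
    },
}

_LENGTHS = (3.0, 3.5, 4.0)


def default_generative_params(
    experiment_id: str, shared_var_frac: float = 0.7
) -> GenerativeParams:
    """Generative parameters whose population means/SDs equal the published
    per-condition d' and c values of the requested experiment."""
    key = str(experiment_id).lower().removeprefix("exp").strip()
    if key not in _TABLE:
        raise ValueError(
            f"unknown experiment id {experiment_id!r}; expected one of "
            f"{sorted(_TABLE)}"
        )
    cells: dict[ConditionKey, CellParams] = {}
    for (study, test, quality), rows in _TABLE[key].items():
        for length, (mu_d, sd_d, mu_c, sd_c) in zip(_LENGTHS, rows):
            cells[(study, test, length, quality)] = CellParams(
                mu_dprime=mu_d, sd_dprime=sd_d, mu_crit=mu_c, sd_crit=sd_c
            )
    return GenerativeParams(
        cells=cells, shared_var_frac=shared_var_frac, experiment_id=key
    )


def _participant_rng(seed: int, group: int, index: int) -> np.random.Generator:
    # stable sub-stream: adding participants never reshuffles existing ones
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(11, group, index))
    )


def simulate_experiment(
    spec: DesignSpec,
    params: GenerativeParams | None = None,
    seed: int = 0,
) -> list[TrialRecord]:
    """Simulate a full experiment: design plus old/new responses.

    Each participant gets per-condition sensitivity/criterion values drawn
    around the population means (a shared intercept plus a condition-specific
    part, split by ``params.shared_var_frac``).  Under the equal-variance
    Gaussian observer, an old item in a cell with values (d', c) is called
    "old" with probability Phi(d'/2 - c) and a foil with Phi(-d'/2 - c); a
    foil uses the values of its yoked condition cell.  Sampled d' values are
    not truncated at zero.
    """
    if params is None:
        params = default_generative_params(spec.experiment_id)
    trials = build_design(spec, seed=seed)

    # index trials by participant, preserving order
    by_pid: dict[str, list[int]] = {}
    for i, t in enumerate(trials):
        by_pid.setdefault(t.participant_id, []).append(i)

    out: list[TrialRecord | None] = [None] * len(trials)
    frac = params.shared_var_frac
    for p_index, (pid, idxs) in enumerate(by_pid.items()):
        rng = _participant_rng(seed, 0, p_index)
        z_d = rng.standard_normal()  # shared intercepts
        z_c = rng.standard_normal()
        cell_vals: dict[ConditionKey, tuple[float, float]] = {}
        conditions = sorted(
            {
                (
                    (trials[i].condition_study or trials[i].study_modality).value,
                    trials[i].test_modality.value,
                    float(trials[i].clip_length),
                    trials[i].visual_quality.value,
                )
                for i in idxs
            }
        )
        for cond in conditions:
            cp = params.cell(cond)
            e_d, e_c = rng.standard_normal(2)
            d = cp.mu_dprime + cp.sd_dprime * (
                np.sqrt(frac) * z_d + np.sqrt(1 - frac) * e_d
            )
            c = cp.mu_crit + cp.sd_crit * (
                np.sqrt(frac) * z_c + np.sqrt(1 - frac) * e_c
            )
            # equal-variance Gaussian observer: hit and false-alarm rates
            cell_vals[cond] = (
                float(norm.cdf(d / 2.0 - c)),
                float(norm.cdf(-d / 2.0 - c)),
            )
        for i in idxs:
            t = trials[i]
            cond = (
                (t.condition_study or t.study_modality).value,
                t.test_modality.value,
                float(t.clip_length),
                t.visual_quality.value,
            )
            p_hit, p_fa = cell_vals[cond]
            resp = bool(rng.random() < (p_hit if t.is_old else p_fa))
            out[i] = TrialRecord(
                participant_id=t.participant_id,
                movie_id=t.movie_id,
                clip_id=t.clip_id,
                clip_length=t.clip_length,
                study_modality=t.study_modality,
                test_modality=t.test_modality,
                visual_quality=t.visual_quality,
                is_old=t.is_old,
                response_old=resp,
                experiment_id=t.experiment_id,
                condition_study=t.condition_study,
                extra=t.extra,
            )
    return [t for t in out if t is not None]
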