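"""Trial tables, counterbalanced designs, and aggregation for old/new recognition.

The experiments this package analyses present brief movie clips in one of three
modality formats (auditory, visual, audio-visual) during a study session and
probe recognition with an old/new judgement during a test session.  This module
holds the trial-level data model, readers/writers for the plain-CSV trial
schema, the counterbalanced design builder, and the aggregations feeding the
signal-detection and Bayesian layers.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "VisualQuality",
    "TrialRecord",
    "DesignSpec",
    "RecognitionCounts",
    "SDTCell",
    "SchemaError",
    "TrialValidationError",
    "DesignError",
    "CLIP_LENGTHS",
    "TRIAL_COLUMNS",
    "design_for",
    "build_design",
    "load_trials",
    "write_trials",
    "trials_to_frame",
    "aggregate_counts",
    "filter_familiar",
    "to_sdt_cells",
]

logger = logging.getLogger(__name__)

#: permitted clip lengths in seconds
CLIP_LENGTHS = (3.0, 3.5, 4.0)


class Modality(str, Enum):
    """Presentation format of a clip. ``NONE`` marks foils (never studied)."""

    AUDITORY = "a"
    VISUAL = "v"
    AUDIOVISUAL = "av"
    NONE = "none"

    @classmethod
    def parse(cls, token: str) -> "Modality":
        aliases = {
            "a": cls.AUDITORY,
            "auditory": cls.AUDITORY,
            "v": cls.VISUAL,
            "visual": cls.VISUAL,
            "av": cls.AUDIOVISUAL,
            "audiovisual": cls.AUDIOVISUAL,
            "audio-visual": cls.AUDIOVISUAL,
            "none": cls.NONE,
        }
        key = str(token).strip().lower()
        if key not in aliases:
            raise ValueError(f"unknown modality token: {token!r}")
        return aliases[key]


class VisualQuality(str, Enum):
    """Visual degradation condition (pixelation), manipulated in one experiment."""

    NORMAL = "normal"
    DEGRADED = "degraded"

    @classmethod
    def parse(cls, token: str) -> "VisualQuality":
        key = str(token).strip().lower()
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unknown visual quality token: {token!r}") from None


class SchemaError(ValueError):
    """A trial table is missing a required column."""


class TrialValidationError(ValueError):
    """A trial row violates the trial-record invariants."""


class DesignError(ValueError):
    """A design specification cannot be realised."""


#: canonical CSV column order for trial tables
TRIAL_COLUMNS = (
    "participant_id",
    "movie_id",
    "clip_id",
    "clip_length",
    "study_modality",
    "test_modality",
    "visual_quality",
    "is_old",
    "response_old",
    "experiment_id",
)


@dataclass(frozen=True)
class TrialRecord:
    """One test-phase trial: design labels plus the observer's old/new response.

    ``condition_study`` carries the study-modality label of the experimental
    condition the clip belongs to.  For old items it equals ``study_modality``;
    for foils (``study_modality == NONE``) it is the study modality of the
    yoked target, so signal-detection cells can partition foils as well.
    ``response_old`` is ``None`` until simulated or observed.  ``extra`` keeps
    unknown CSV columns for lossless round-trips.
    """

    participant_id: str
    movie_id: str
    clip_id: str
    clip_length: float
    study_modality: Modality
    test_modality: Modality
    is_old: bool
    response_old: bool | None = None
    visual_quality: VisualQuality = VisualQuality.NORMAL
    experiment_id: str = ""
    condition_study: Modality | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if float(self.clip_length) not in CLIP_LENGTHS:
            raise TrialValidationError(
                f"clip_length {self.clip_length} not in {CLIP_LENGTHS}"
            )
        if self.is_old != (self.study_modality is not Modality.NONE):
            raise TrialValidationError(
                "is_old must be true iff study_modality is not 'none' "
                f"(got is_old={self.is_old}, study_modality={self.study_modality.value})"
            )
        if self.test_modality is Modality.NONE:
            raise TrialValidationError("test_modality cannot be 'none'")

    @property
    def condition(self) -> tuple[Modality, Modality, float, VisualQuality]:
        """Condition key: (study-side label, test modality, length, quality)."""
        study = self.condition_study or self.study_modality
        return (study, self.test_modality, float(self.clip_length), self.visual_quality)


@dataclass(frozen=True)
class ConditionCell:
    """One study×test(×quality) condition with its per-participant target count."""

    study: Modality
    test: Modality
    quality: VisualQuality = VisualQuality.NORMAL


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a recognition experiment.

    Each participant studies the targets and is tested on targets plus one
    movie/length/condition-matched foil per target.  ``cells`` lists the
    study×test(×quality) conditions; targets (and foils) are divided equally
    between cells and, within a cell, equally across ``lengths``.
    """

    experiment_id: str
    n_participants: int
    n_movies: int
    clips_per_movie: int
    lengths: tuple[float, ...] = CLIP_LENGTHS
    cells: tuple[ConditionCell, ...] = ()
    counterbalance_group_size: int = 8
    #: pair audio-visual foils from the same movie (the alternative, pairing
    #: auditory and visual tracks of different movies, is not modelled)
    av_foils_same_movie: bool = True

    def __post_init__(self) -> None:
        if self.n_participants % self.counterbalance_group_size:
            raise DesignError(
                f"n_participants={self.n_participants} not divisible by "
                f"counterbalance subgroup size {self.counterbalance_group_size}"
            )
        if self.clips_per_movie % len(self.lengths):
            raise DesignError("clips_per_movie must divide evenly across lengths")
        if not self.cells:
            raise DesignError("design needs at least one condition cell")

    @property
    def n_clips(self) -> int:
        return self.n_movies * self.clips_per_movie

    @property
    def clips_per_movie_length(self) -> int:
        return self.clips_per_movie // len(self.lengths)


_EXPERIMENT_CELLS: dict[str, tuple[tuple[str, str, str], ...]] = {
    # (study, test, quality) per condition; targets split equally between cells
    "1a": (("av", "av", "normal"), ("av", "v", "normal"),
           ("v", "av", "normal"), ("v", "v", "normal")),
    "1b": (("v", "av", "normal"), ("v", "v", "normal")),
    "2": (("av", "av", "normal"), ("av", "a", "normal"),
          ("a", "av", "normal"), ("a", "a", "normal")),
    "3": (("a", "a", "normal"), ("a", "av", "normal"),
          ("v", "v", "normal"), ("v", "av", "normal")),
    "4": (("av", "av", "normal"), ("av", "v", "normal"),
          ("v", "av", "normal"), ("v", "v", "normal"),
          ("av", "av", "degraded"), ("av", "v", "degraded"),
          ("v", "av", "degraded"), ("v", "v", "degraded")),
}


def design_for(experiment_id: str, n_participants: int = 24) -> DesignSpec:
    """Return the stock design for one of the five experiments (1a, 1b, 2, 3, 4).

    All use 1,200 clips (50 movies × 24 clips, 8 per length), 600 studied
    targets and 600 yoked foils, counterbalanced in subgroups of eight.
    """
    key = str(experiment_id).lower().removeprefix("exp").strip()
    if key not in _EXPERIMENT_CELLS:
        raise DesignError(
            f"unknown experiment id {experiment_id!r}; expected one of "
            f"{sorted(_EXPERIMENT_CELLS)}"
        )
    cells = tuple(
        ConditionCell(Modality.parse(s), Modality.parse(t), VisualQuality.parse(q))
        for s, t, q in _EXPERIMENT_CELLS[key]
    )
    return DesignSpec(
        experiment_id=key,
        n_participants=n_participants,
        n_movies=50,
        clips_per_movie=24,
        cells=cells,
    )


def _block_roles(
    spec: DesignSpec, movie_index: int, block_size: int
) -> list[tuple[ConditionCell, bool]]:
    """Role slots (cell, is_target) for one movie×length block of clips.

    With four (or fewer) condition cells the eight clips of a block host every
    cell's target and foil, and rotating the slot assignment across the eight
    members of a counterbalance subgroup gives exact balance.  With eight cells
    (the quality manipulation) each movie hosts half the cells, alternating
    between movies, and the rotation runs within the two quality strata.
    """
    cells = spec.cells
    n_cells = len(cells)
    slots_needed = 2 * n_cells  # target + foil per cell
    if slots_needed <= block_size:
        reps = block_size // slots_needed
        if block_size % slots_needed:
            raise DesignError(
                f"{block_size} clips per movie×length cannot host "
                f"{n_cells} condition cells evenly"
            )
        roles: list[tuple[ConditionCell, bool]] = []
        for _ in range(reps):
            for cell in cells:
                roles.append((cell, True))
                roles.append((cell, False))
        return roles
    # more cells than a block can host: alternate halves across movies
    if slots_needed != 2 * block_size:
        raise DesignError(
            f"cannot distribute {n_cells} cells over blocks of {block_size}"
        )
    half = n_cells // 2
    chosen = cells[:half] if movie_index % 2 == 0 else cells[half:]
    roles = []
    for cell in chosen:
        roles.append((cell, True))
        roles.append((cell, False))
    return roles


def build_design(spec: DesignSpec, seed: int) -> list[TrialRecord]:
    """Generate the full test list for every participant (responses missing).

    Within each counterbalance subgroup every clip serves in every condition
    role equally often: clips are permuted once per subgroup within each
    movie×length block and the role slots rotate across subgroup members
    (a Latin-square rotation).  Each target's foil comes from the same movie,
    the same length, and the same condition cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    block = spec.clips_per_movie_length
    lengths = spec.lengths
    n_groups = spec.n_participants // spec.counterbalance_group_size

    # clip ids: m<movie>c<clip>; clip j of movie m has length lengths[j // block]
    trials: list[TrialRecord] = []
    for g in range(n_groups):
        # per-subgroup base permutation of each movie×length block
        perms: dict[tuple[int, int], np.ndarray] = {}
        for m in range(spec.n_movies):
            for li in range(len(lengths)):
                perms[(m, li)] = rng.permutation(block)
        for within_idx in range(spec.counterbalance_group_size):
            pid = f"p{g * spec.counterbalance_group_size + within_idx + 1:03d}"
            prng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(7, g, within_idx))
            )
            p_trials: list[TrialRecord] = []
            for m in range(spec.n_movies):
                movie_id = f"m{m + 1:02d}"
                for li, length in enumerate(lengths):
                    roles = _block_roles(spec, m, block)
                    perm = perms[(m, li)]
                    n_slots = len(roles)
                    rot = within_idx % n_slots
                    for k in range(block):
                        clip_pos = perm[k]
                        clip_id = f"m{m + 1:02d}c{li * block + clip_pos + 1:02d}"
                        cell, is_target = roles[(k + rot) % n_slots]
                        p_trials.append(
                            TrialRecord(
                                participant_id=pid,
                                movie_id=movie_id,
                                clip_id=clip_id,
                                clip_length=length,
                                study_modality=cell.study if is_target else Modality.NONE,
                                test_modality=cell.test,
                                visual_quality=cell.quality,
                                is_old=is_target,
                                experiment_id=spec.experiment_id,
                                condition_study=cell.study,
                            )
                        )
            order = prng.permutation(len(p_trials))
            trials.extend(p_trials[i] for i in order)
    return trials


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_bool(token: str, column: str, row: int) -> bool | None:
    key = str(token).strip().lower()
    if key in {"", "na", "nan", "none"}:
        return None
    if key in {"true", "1", "t", "yes", "old"}:
        return True
    if key in {"false", "0", "f", "no", "new"}:
        return False
    raise TrialValidationError(f"row {row}: invalid boolean {token!r} in {column}")


def load_trials(path) -> list[TrialRecord]:
    """Read a trial table from CSV, validating every row.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`TrialValidationError` (with the offending row index) for invalid
    modality/length tokens or invariant violations.  Unknown columns are kept
    in ``TrialRecord.extra`` and survive a write/load round-trip.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
    known = set(TRIAL_COLUMNS) | {"condition_study"}
    extra_cols = [c for c in frame.columns if c not in known]
    records: list[TrialRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        try:
            cond = row_d.get("condition_study", "")
            records.append(
                TrialRecord(
                    participant_id=row_d["participant_id"],
                    movie_id=row_d["movie_id"],
                    clip_id=row_d["clip_id"],
                    clip_length=float(row_d["clip_length"]),
                    study_modality=Modality.parse(row_d["study_modality"]),
                    test_modality=Modality.parse(row_d["test_modality"]),
                    visual_quality=VisualQuality.parse(row_d["visual_quality"] or "normal"),
                    is_old=bool(_parse_bool(row_d["is_old"], "is_old", i)),
                    response_old=_parse_bool(row_d["response_old"], "response_old", i),
                    experiment_id=row_d["experiment_id"],
                    condition_study=Modality.parse(cond) if str(cond).strip() else None,
                    extra={c: row_d[c] for c in extra_cols},
                )
            )
        except TrialValidationError:
            raise
        except ValueError as exc:
            raise TrialValidationError(f"row {i}: {exc}") from exc
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(records):
        key = (rec.participant_id, rec.clip_id)
        if key in seen:
            raise TrialValidationError(
                f"row {i}: duplicate (participant_id, clip_id) pair {key}"
            )
        seen.add(key)
    return records


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame in the canonical CSV schema."""
    extra_cols: list[str] = []
    for t in trials:
        for c in t.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for t in trials:
        row = {
            "participant_id": t.participant_id,
            "movie_id": t.movie_id,
            "clip_id": t.clip_id,
            "clip_length": t.clip_length,
            "study_modality": t.study_modality.value,
            "test_modality": t.test_modality.value,
            "visual_quality": t.visual_quality.value,
            "is_old": t.is_old,
            "response_old": "" if t.response_old is None else t.response_old,
            "experiment_id": t.experiment_id,
            "condition_study": "" if t.condition_study is None else t.condition_study.value,
        }
        for c in extra_cols:
            row[c] = t.extra.get(c, "")
        rows.append(row)
    return pd.DataFrame(rows)


def write_trials(trials: Sequence[TrialRecord], path) -> None:
    """Write trial records to CSV (UTF-8, '.' decimal separator)."""
    trials_to_frame(trials).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aggregation


@dataclass(frozen=True)
class RecognitionCounts:
    """Old-trial totals and hit counts per modality, feeding the Bayesian model."""

    n_a: int
    y_a: int
    n_v: int
    y_v: int
    n_av: int
    y_av: int

    def __post_init__(self) -> None:
        for m in ("a", "v", "av"):
            n, y = self.n(m), self.y(m)
            if not 0 <= y <= n:
                raise ValueError(f"modality {m}: need 0 <= y ({y}) <= n ({n})")

    def n(self, modality: str) -> int:
        return getattr(self, f"n_{modality}")

    def y(self, modality: str) -> int:
        return getattr(self, f"y_{modality}")

    def hit_rate(self, modality: str) -> float:
        n = self.n(modality)
        return self.y(modality) / n if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "modality": ["a", "v", "av"],
                "n": [self.n_a, self.n_v, self.n_av],
                "y": [self.y_a, self.y_v, self.y_av],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RecognitionCounts":
        kwargs = {}
        for _, row in frame.iterrows():
            m = Modality.parse(row["modality"]).value
            kwargs[f"n_{m}"] = int(row["n"])
            kwargs[f"y_{m}"] = int(row["y"])
        return cls(**{k: kwargs.get(k, 0) for k in
                      ("n_a", "y_a", "n_v", "y_v", "n_av", "y_av")})


def aggregate_counts(
    trials: Iterable[TrialRecord], modality_of: str = "test"
) -> RecognitionCounts:
    """Tally old-trial totals and hits per modality; foils are ignored.

    ``modality_of`` selects whether trials are grouped by their study or their
    test modality (identical for study-test congruent designs).  Old trials
    with a missing response raise a ``ValueError`` naming the first offender.
    """
    if modality_of not in {"study", "test"}:
        raise ValueError("modality_of must be 'study' or 'test'")
    n = Counter()
    y = Counter()
    for t in trials:
        if not t.is_old:
            continue
        if t.response_old is None:
            raise ValueError(
                "old trial with missing response: "
                f"participant {t.participant_id}, clip {t.clip_id}"
            )
        m = (t.study_modality if modality_of == "study" else t.test_modality).value
        n[m] += 1
        y[m] += t.response_old
    return RecognitionCounts(
        n_a=n["a"], y_a=y["a"], n_v=n["v"], y_v=y["v"], n_av=n["av"], y_av=y["av"]
    )


def filter_familiar(
    trials: Iterable[TrialRecord],
    familiar_movies: Mapping[str, Iterable[str]],
) -> list[TrialRecord]:
    """Drop trials whose movie a given participant marked as familiar.

    Mirrors the post-test screening in which participants marked movies they
    had seen within the last five years.  Unknown movie ids in the familiar
    lists are ignored with a logged warning.
    """
    familiar = {p: set(ms) for p, ms in familiar_movies.items()}
    trials = list(trials)
    known_movies = {t.movie_id for t in trials}
    for p, ms in familiar.items():
        unknown = ms - known_movies
        if unknown:
            logger.warning(
                "participant %s: familiar movie ids not in the data: %s",
                p, sorted(unknown),
            )
    return [
        t for t in trials if t.movie_id not in familiar.get(t.participant_id, ())
    ]


@dataclass(frozen=True)
class SDTCell:
    """Per-participant, per-condition response counts for signal detection."""

    participant_id: str
    study_modality: Modality
    test_modality: Modality
    clip_length: float
    visual_quality: VisualQuality
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_old(self) -> int:
        return self.hits + self.misses

    @property
    def n_foil(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def condition(self) -> tuple[Modality, Modality, float, VisualQuality]:
        return (
            self.study_modality,
            self.test_modality,
            float(self.clip_length),
            self.visual_quality,
        )


def to_sdt_cells(trials: Iterable[TrialRecord]) -> list[SDTCell]:
    """Partition responded trials into per-participant condition cells.

    Foils carrying a ``condition_study`` label (everything produced by
    :func:`build_design`) are assigned to their yoked target's cell, so cell
    counts partition the trials exactly.  Foils without that label are shared
    across the study-modality levels of their (test modality, length, quality)
    stratum, the only attribution their labels support.
    """
    trials = list(trials)
    for t in trials:
        if t.response_old is None:
            raise ValueError(
                f"trial with missing response: participant {t.participant_id}, "
                f"clip {t.clip_id}"
            )
    old = [t for t in trials if t.is_old]
    foils = [t for t in trials if not t.is_old]
    tagged = all(t.condition_study is not None for t in foils)

    hits: Counter = Counter()
    misses: Counter = Counter()
    fas: Counter = Counter()
    crs: Counter = Counter()
    keys: list[tuple] = []
    seen: set[tuple] = set()

    def note(key):
        if key not in seen:
            seen.add(key)
            keys.append(key)

    for t in old:
        key = (t.participant_id, *t.condition)
        note(key)
        if t.response_old:
            hits[key] += 1
        else:
            misses[key] += 1
    if tagged:
        for t in foils:
            key = (t.participant_id, *t.condition)
            note(key)
            if t.response_old:
                fas[key] += 1
            else:
                crs[key] += 1
    cells = []
    for key in keys:
        pid, study, test, length, quality = key
        fa, cr = fas[key], crs[key]
        if not tagged:
            fa = sum(
                bool(t.response_old)
                for t in foils
                if t.participant_id == pid
                and t.test_modality == test
                and float(t.clip_length) == length
                and t.visual_quality == quality
            )
            cr = sum(
                not t.response_old
                for t in foils
                if t.participant_id == pid
                and t.test_modality == test
                and float(t.clip_length) == length
                and t.visual_quality == quality
            )
        cells.append(
            SDTCell(
                participant_id=pid,
                study_modality=study,
                test_modality=test,
                clip_length=length,
                visual_quality=quality,
                hits=hits[key],
                misses=misses[key],
                false_alarms=fa,
                correct_rejections=cr,
            )
        )
    return cells
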