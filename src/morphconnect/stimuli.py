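"""Stimulus-domain containers: morph schedules, rating datasets, regressors.

A stimulus is a 6-s continuous face morph followed by a 1-s still.  During
the morph, facial age moves linearly between a start and a target age and,
for half of the stimuli, facial gender crosses from one endpoint sex to the
other (androgyny passes through 0.5 mid-morph).  Regressors are nonnegative
series time-binned at the video frame rate (24 fps) and scaled to a relative
maximum of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AGE_MIN", "AGE_MAX", "MorphSchedule", "RatingDataset", "Regressor"]

AGE_MIN = 2.0
AGE_MAX = 81.0


@dataclass
class MorphSchedule:
    """Age/gender trajectory of one morph stimulus.

    ``age_at(t)`` interpolates linearly from ``start_age`` to ``target_age``
    over the morph and holds the target during the trailing still;
    ``morph_position(t)`` is the linear progress through the morph in [0, 1]
    (the physical androgyny coordinate for gender-transition morphs, with 1
    the anchor endpoint gender).
    """

    start_age: float
    target_age: float
    has_gender_transition: bool = False
    duration_s: float = 6.0
    still_s: float = 1.0
    fps: int = 24

    def __post_init__(self) -> None:
        for a in (self.start_age, self.target_age):
            if not (AGE_MIN <= a <= AGE_MAX):
                raise ValueError(f"age {a} outside [{AGE_MIN}, {AGE_MAX}] years")
        if self.duration_s <= 0 or self.still_s < 0:
            raise ValueError("invalid durations")

    @property
    def total_s(self) -> float:
        return self.duration_s + self.still_s

    @property
    def n_frames(self) -> int:
        """Frame count of the full stimulus (morph + still)."""
        return int(round(self.total_s * self.fps))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def age_at(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        frac = np.clip(t / self.duration_s, 0.0, 1.0)
        return self.start_age + frac * (self.target_age - self.start_age)

    def morph_position(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.clip(t / self.duration_s, 0.0, 1.0)


@dataclass
class RatingDataset:
    """Subjective magnitude ratings of morph stimuli.

    ``records`` has columns morph_id, subject_id, start_age, target_age,
    rating (arbitrary units, >= 0).  ``scale_max`` is the rating ceiling the
    visual-analogue scale was normalised to (3.0 a.u. for age-difference
    ratings).
    """

    records: pd.DataFrame
    scale_max: float = 3.0

    def __post_init__(self) -> None:
        required = {"morph_id", "subject_id", "start_age", "target_age", "rating"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"rating records missing columns {sorted(missing)}")
        if (self.records["rating"] < 0).any():
            raise ValueError("ratings must be nonnegative")
        if self.records.duplicated(["morph_id", "subject_id"]).any():
            raise ValueError("a morph may be rated at most once per subject")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scale_max: float = 3.0) -> "RatingDataset":
        return cls(pd.read_csv(path), scale_max=scale_max)


@dataclass
class Regressor:
    """A named, frame-rate-binned stimulus function.

    Values are nonnegative; after :meth:`normalize` the maximum is exactly 1
    (an all-zero regressor stays all-zero).
    """

    name: str
    values: np.ndarray
    fps: float = 24.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("regressor values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("regressor values must be nonnegative")
        if self.normalized and self.values.size and self.values.max() not in (0.0, 1.0):
            raise ValueError("normalized regressor must have max 1 (or be all-zero)")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def normalize(self) -> "Regressor":
        """Scale to a relative maximum of 1 (no-op on an all-zero series)."""
        peak = self.values.max() if self.values.size else 0.0
        vals = self.values / peak if peak > 0 else self.values.copy()
        return Regressor(self.name, vals, fps=self.fps, normalized=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_index": np.arange(self.n_frames), "time_s": self.times(), "value": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "Regressor":
        df = pd.read_csv(path)
        fps = 1.0 / np.median(np.diff(df["time_s"])) if len(df) > 1 else 24.0
        reg = cls(name or "regressor", df["value"].to_numpy(), fps=float(round(fps, 6)))
        return reg
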