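"""Core domain types shared across modules.

A day of CGM data lives on a fixed 288-slot grid (00:00-23:55 at 5-minute
spacing). Glucose is always mg/dL and is clipped to [40, 300] during
preprocessing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

GRID_SLOTS = 288
SLOT_MINUTES = 5
MINUTES_PER_DAY = GRID_SLOTS * SLOT_MINUTES  # 1440
GLUCOSE_MIN = 40.0
GLUCOSE_MAX = 300.0

HYPO_THRESHOLD = 70.0
HYPER_THRESHOLD = 180.0


@dataclass
class DayProfile:
    """One subject-day of glucose values on the 5-minute grid.

    ``values`` has length 288 with NaN at missing slots; ``present_mask``
    is True exactly where a value is defined.
    """

    subject_id: str
    date: dt.date
    values: np.ndarray
    present_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.present_mask = np.asarray(self.present_mask, dtype=bool)
        if self.values.shape != (GRID_SLOTS,) or self.present_mask.shape != (GRID_SLOTS,):
            raise ValueError(f"day profile must have exactly {GRID_SLOTS} slots")
        if np.any(np.isfinite(self.values) != self.present_mask):
            raise ValueError("present_mask must be True exactly where values are finite")
        pv = self.values[self.present_mask]
        if pv.size and (pv.min() < GLUCOSE_MIN or pv.max() > GLUCOSE_MAX):
            raise ValueError(
                f"present values must lie in [{GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}] mg/dL"
            )

    @property
    def n_present(self) -> int:
        return int(self.present_mask.sum())

    @staticmethod
    def slot_minutes() -> np.ndarray:
        """Minutes-of-day of each grid slot (0, 5, ..., 1435)."""
        return np.arange(GRID_SLOTS) * SLOT_MINUTES

    @classmethod
    def from_values(cls, subject_id: str, date: dt.date, values) -> "DayProfile":
        values = np.asarray(values, dtype=float)
        return cls(subject_id, date, values, np.isfinite(values))


@dataclass
class CGMRecord:
    """Time-ordered raw samples for one subject."""

    subject_id: str
    timestamps: list[dt.datetime]
    glucose: np.ndarray
    device_interval: float | None = None  # minutes

    def __post_init__(self):
        self.glucose = np.asarray(self.glucose, dtype=float)
        if len(self.timestamps) != self.glucose.size:
            raise ValueError("timestamps and glucose must have equal length")
        for a, b in zip(self.timestamps, self.timestamps[1:]):
            if b <= a:
                raise ValueError("timestamps must be strictly increasing")


@dataclass
class MealDescriptor:
    """Nutrition vector D = (H, C, P, F, B): kcal, carb g, protein g, fat g, fiber g."""

    kcal: float
    carb_g: float
    protein_g: float
    fat_g: float
    fiber_g: float = 0.0

    def __post_init__(self):
        if min(self.kcal, self.carb_g, self.protein_g, self.fat_g, self.fiber_g) < 0:
            raise ValueError("nutrition components must be nonnegative")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.kcal, self.carb_g, self.protein_g, self.fat_g, self.fiber_g], dtype=float
        )


@dataclass
class MealEvent:
    """A meal attached to a subject and timestamp."""

    subject_id: str
    timestamp: dt.datetime
    meal: MealDescriptor


@dataclass
class DayEmbedding:
    vector: np.ndarray
    subject_id: str
    date: dt.date | None = None
    checkpoint_id: str | None = None

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding components must be finite")


@dataclass
class SampleEmbedding:
    vector: np.ndarray
    subject_id: str
    n_days: int = 1
    checkpoint_id: str | None = None

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding components must be finite")
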