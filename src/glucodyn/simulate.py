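"""Synthetic CGM cohort generator.

Produces subject-days on the standard 288-slot grid with a circadian
baseline, gamma-kernel meal excursions, AR(1) sensor noise, and
configurable missingness; plus archetype labels and a meal log. Three
archetypes are provided (``normal``, ``igr_like``, ``t2d_like``) whose
default parameters make them separable but overlapping, which is what the
downstream classification and subtyping tests rely on.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    GRID_SLOTS,
    MINUTES_PER_DAY,
    SLOT_MINUTES,
    DayProfile,
    MealDescriptor,
    MealEvent,
)

__all__ = [
    "ArchetypeParams",
    "SimulatedCohort",
    "ARCHETYPES",
    "meal_response_kernel",
    "simulate_day",
    "simulate_cohort",
    "write_cohort",
]

_EPOCH = dt.date(2024, 1, 1)
DEFAULT_MEAL_TIMES = (450, 750, 1110)  # 07:30, 12:30, 18:30 in minutes-of-day
KCAL_PER_G = {"carb": 4.0, "protein": 4.0, "fat": 9.0}


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters for one glycemic archetype."""

    name: str
    basal_mean: float          # mg/dL
    basal_amplitude: float     # mg/dL, circadian sinusoid amplitude
    meal_peak_mean: float      # mg/dL, mean excursion height
    meal_peak_sd: float        # mg/dL
    decay_halflife: float      # minutes
    noise_sd: float            # mg/dL, AR(1) innovation SD
    noise_phi: float           # in [0, 1)
    missing_rate: float        # in [0, 0.5]

    def __post_init__(self):
        if not (60.0 <= self.basal_mean <= 250.0):
            raise ValueError("basal_mean must lie in [60, 250] mg/dL")
        if self.meal_peak_mean < 0:
            raise ValueError("meal_peak_mean must be nonnegative")
        if not (0.0 <= self.noise_phi < 1.0):
            raise ValueError("noise_phi must lie in [0, 1)")
        if not (0.0 <= self.missing_rate <= 0.5):
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if self.decay_halflife <= 0:
            raise ValueError("decay_halflife must be positive")
        if self.noise_sd < 0 or self.meal_peak_sd < 0 or self.basal_amplitude < 0:
            raise ValueError("scale parameters must be nonnegative")


ARCHETYPES: dict[str, ArchetypeParams] = {
    "normal": ArchetypeParams("normal", 95.0, 8.0, 45.0, 8.0, 20.0, 4.0, 0.6, 0.02),
    "igr_like": ArchetypeParams("igr_like", 130.0, 10.0, 70.0, 12.0, 32.0, 6.0, 0.6, 0.02),
    "t2d_like": ArchetypeParams("t2d_like", 180.0, 12.0, 85.0, 16.0, 48.0, 9.0, 0.65, 0.02),
}


@dataclass
class SimulatedCohort:
    days: list[DayProfile]
    labels: dict[str, str]
    meal_log: list[MealEvent]
    seed: int


def meal_response_kernel(minutes_since_meal: np.ndarray, decay_halflife: float) -> np.ndarray:
    """Peak-normalized gamma-shaped (shape 2) meal response.

    k(x) = (x / tau) * exp(1 - x / tau) with tau = decay_halflife / ln 2,
    so the tail halves every ``decay_halflife`` minutes and the response
    peaks at x = tau (~30-70 min for the default archetypes).
    """
    tau = decay_halflife / math.log(2.0)
    x = np.asarray(minutes_since_meal, dtype=float)
    out = np.where(x > 0, (x / tau) * np.exp(1.0 - x / tau), 0.0)
    return out


def _draw_meal(rng: np.random.Generator) -> MealDescriptor:
    kcal = rng.uniform(300.0, 900.0)
    ratios = np.array([rng.uniform(0.35, 0.65), rng.uniform(0.10, 0.30), 0.0])
    ratios[2] = 1.0 - ratios[0] - ratios[1]
    jitter = rng.uniform(0.9, 1.1, size=3)  # macronutrients consistent with kcal +-10%
    carb = kcal * ratios[0] / KCAL_PER_G["carb"] * jitter[0]
    protein = kcal * ratios[1] / KCAL_PER_G["protein"] * jitter[1]
    fat = kcal * ratios[2] / KCAL_PER_G["fat"] * jitter[2]
    fiber = rng.uniform(0.0, 12.0)
    return MealDescriptor(kcal, carb, protein, fat, fiber)


def simulate_day(
    params: ArchetypeParams,
    meal_times: list[float],
    rng: np.random.Generator,
    subject_id: str = "sim",
    date: dt.date = _EPOCH,
    contiguous_gap: bool = False,
) -> tuple[DayProfile, list[MealDescriptor]]:
    """Simulate one subject-day; returns the profile and its meal descriptors.

    glucose(t) = basal + circadian sinusoid + sum of meal excursions + AR(1)
    noise, sampled on the 288-slot grid and clipped to [40, 300] mg/dL.
    """
    meal_times = list(meal_times)
    for m in meal_times:
        if not (0 <= m < MINUTES_PER_DAY):
            raise ValueError(f"meal time {m} outside [0, {MINUTES_PER_DAY}) minutes-of-day")
    if any(b <= a for a, b in zip(meal_times, meal_times[1:])):
        raise ValueError("meal times must be strictly increasing")

    t = np.arange(GRID_SLOTS, dtype=float) * SLOT_MINUTES
    # circadian trough in the early morning (t0 chosen so the sinusoid dips ~03:00)
    g = params.basal_mean + params.basal_amplitude * np.sin(
        2.0 * math.pi * (t - 540.0) / MINUTES_PER_DAY
    )

    meals: list[MealDescriptor] = []
    for m in meal_times:
        peak = max(0.0, rng.normal(params.meal_peak_mean, params.meal_peak_sd))
        g = g + peak * meal_response_kernel(t - m, params.decay_halflife)
        meals.append(_draw_meal(rng))

    if params.noise_sd > 0:
        innov = rng.normal(0.0, params.noise_sd, size=GRID_SLOTS)
        noise = np.empty(GRID_SLOTS)
        # stationary start
        noise[0] = innov[0] / math.sqrt(1.0 - params.noise_phi**2)
        for i in range(1, GRID_SLOTS):
            noise[i] = params.noise_phi * noise[i - 1] + innov[i]
        g = g + noise

    g = np.clip(g, GLUCOSE_MIN, GLUCOSE_MAX)

    present = np.ones(GRID_SLOTS, dtype=bool)
    if params.missing_rate > 0:
        present &= rng.random(GRID_SLOTS) >= params.missing_rate
    if contiguous_gap:
        gap_len = int(rng.integers(6, 19))  # 30-90 minutes
        start = int(rng.integers(0, GRID_SLOTS - gap_len))
        present[start:start + gap_len] = False
    values = np.where(present, g, np.nan)
    return DayProfile(subject_id, date, values, present), meals


def _subject_params(base: ArchetypeParams, rng: np.random.Generator) -> ArchetypeParams:
    """Per-subject draw around the archetype means."""
    basal = float(np.clip(rng.normal(base.basal_mean, 7.0), 60.0, 250.0))
    peak = max(5.0, rng.normal(base.meal_peak_mean, base.meal_peak_sd))
    return replace(base, basal_mean=basal, meal_peak_mean=peak)


def simulate_cohort(
    n_subjects: int,
    days_per_subject: int,
    seed: int,
    archetypes: tuple[str, ...] = ("normal", "igr_like", "t2d_like"),
    contiguous_gap: bool = False,
) -> SimulatedCohort:
    """Simulate ``n_subjects`` per archetype, deterministic given ``seed``."""
    if n_subjects < 1 or days_per_subject < 1:
        raise ValueError("n_subjects and days_per_subject must be >= 1")
    rng = np.random.default_rng(seed)
    days: list[DayProfile] = []
    labels: dict[str, str] = {}
    meal_log: list[MealEvent] = []
    for arch in archetypes:
        base = ARCHETYPES[arch]
        for i in range(n_subjects):
            sid = f"{arch}_{i:04d}"
            labels[sid] = arch
            params = _subject_params(base, rng)
            for d in range(days_per_subject):
                date = _EPOCH + dt.timedelta(days=d)
                meal_times = sorted(
                    float(np.clip(m + rng.uniform(-30, 30), 0, MINUTES_PER_DAY - 1))
                    for m in DEFAULT_MEAL_TIMES
                )
                day, meals = simulate_day(
                    params, meal_times, rng, subject_id=sid, date=date,
                    contiguous_gap=contiguous_gap,
                )
                days.append(day)
                for m, when in zip(meals, meal_times):
                    ts = dt.datetime.combine(date, dt.time()) + dt.timedelta(minutes=when)
                    meal_log.append(MealEvent(sid, ts, m))
    return SimulatedCohort(days, labels, meal_log, seed)


def write_cohort(cohort: SimulatedCohort, cgm_path, labels_path=None, meals_path=None) -> None:
    """Write a cohort in the package CSV dialects (see :mod:`glucodyn.io`)."""
    with open(cgm_path, "w", encoding="utf-8") as fh:
        fh.write("subject_id,timestamp,glucose_mg_dl\n")
        for day in cohort.days:
            midnight = dt.datetime.combine(day.date, dt.time())
            for slot in np.flatnonzero(day.present_mask):
                ts = midnight + dt.timedelta(minutes=int(slot) * SLOT_MINUTES)
                fh.write(f"{day.subject_id},{ts.isoformat()},{float(day.values[slot])!r}\n")
    if labels_path is not None:
        with open(labels_path, "w", encoding="utf-8") as fh:
            fh.write("subject_id,label\n")
            for sid, lab in cohort.labels.items():
                fh.write(f"{sid},{lab}\n")
    if meals_path is not None:
        with open(meals_path, "w", encoding="utf-8") as fh:
            fh.write("subject_id,timestamp,kcal,carb_g,protein_g,fat_g,fiber_g\n")
            for ev in cohort.meal_log:
                m = ev.meal
                fh.write(
                    f"{ev.subject_id},{ev.timestamp.isoformat()},{float(m.kcal)!r},"
                    f"{float(m.carb_g)!r},{float(m.protein_g)!r},{float(m.fat_g)!r},{float(m.fiber_g)!r}\n"
                )
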