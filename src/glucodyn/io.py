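"""Parsing of CGM / label / meal CSVs and day-splitting onto the 5-minute grid.

CSV dialects:

* CGM: ``subject_id,timestamp,glucose_mg_dl`` — ISO-8601 timestamps, one
  row per measurement.
* Labels: ``subject_id,label``.
* Meals: ``subject_id,timestamp,kcal,carb_g,protein_g,fat_g,fiber_g``.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .types import (
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    GRID_SLOTS,
    SLOT_MINUTES,
    CGMRecord,
    DayProfile,
    MealDescriptor,
    MealEvent,
)

__all__ = [
    "parse_cgm_csv",
    "parse_labels_csv",
    "parse_meal_csv",
    "split_days",
    "downsample",
]

log = logging.getLogger(__name__)

_CGM_COLUMNS = ["subject_id", "timestamp", "glucose_mg_dl"]


class CGMParseError(ValueError):
    pass


def parse_cgm_csv(path) -> list[CGMRecord]:
    """Parse a CGM CSV into one time-sorted record per subject.

    Duplicate timestamps within a subject are collapsed by mean; unknown
    columns are ignored with a warning; malformed rows raise
    :class:`CGMParseError` naming the offending line.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _CGM_COLUMNS if c not in df.columns]
    if missing:
        raise CGMParseError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in _CGM_COLUMNS]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", path, extra)

    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError):
        # locate the first bad row for the error message
        parsed = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise CGMParseError(
            f"{path}: malformed timestamp {df['timestamp'].iloc[bad]!r} on data line {bad + 2}"
        ) from None
    glucose = pd.to_numeric(df["glucose_mg_dl"], errors="coerce")
    if glucose.isna().any():
        bad = int(np.flatnonzero(glucose.isna().to_numpy())[0])
        raise CGMParseError(
            f"{path}: malformed glucose value {df['glucose_mg_dl'].iloc[bad]!r} "
            f"on data line {bad + 2}"
        )
    df["glucose_mg_dl"] = glucose

    records = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = (
            grp.groupby("timestamp", as_index=False)["glucose_mg_dl"].mean()
            .sort_values("timestamp")
        )
        ts = [t.to_pydatetime() for t in grp["timestamp"]]
        interval = None
        if len(ts) > 1:
            deltas = np.diff([t.timestamp() for t in ts]) / 60.0
            interval = float(np.median(deltas))
        records.append(CGMRecord(str(sid), ts, grp["glucose_mg_dl"].to_numpy(), interval))
    return records


def parse_labels_csv(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if not {"subject_id", "label"}.issubset(df.columns):
        raise CGMParseError(f"{path}: expected header subject_id,label")
    return dict(zip(df["subject_id"], df["label"]))


def parse_meal_csv(path) -> list[MealEvent]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    need = ["subject_id", "timestamp", "kcal", "carb_g", "protein_g", "fat_g", "fiber_g"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise CGMParseError(f"{path}: missing required column(s) {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            MealEvent(
                row.subject_id,
                row.timestamp.to_pydatetime(),
                MealDescriptor(row.kcal, row.carb_g, row.protein_g, row.fat_g, row.fiber_g),
            )
        )
    return events


def _snap_slot(timestamp: dt.datetime) -> int:
    """Nearest 5-minute slot; ties (2.5 min) go to the earlier slot."""
    minutes = timestamp.hour * 60 + timestamp.minute + timestamp.second / 60.0
    slot = int(np.floor(minutes / SLOT_MINUTES + 0.5))
    if minutes / SLOT_MINUTES + 0.5 == slot and slot * SLOT_MINUTES > minutes:
        slot -= 1  # exact tie: earlier slot
    return min(slot, GRID_SLOTS - 1)


def split_days(record: CGMRecord, drop_edge_days: bool = True) -> list[DayProfile]:
    """Split a record into calendar-day profiles on the 5-minute grid.

    The first and last calendar days are dropped (incomplete-day rule);
    values are clipped to [40, 300] mg/dL; slots with several samples are
    averaged; slots without a sample are masked missing. A record spanning
    fewer than 3 calendar days yields an empty list.
    """
    if not record.timestamps:
        raise ValueError("record is empty")
    dates = sorted({ts.date() for ts in record.timestamps})
    if drop_edge_days:
        if len(dates) < 3:
            log.info("record %s spans %d day(s); no interior days", record.subject_id, len(dates))
            return []
        keep = set(dates[1:-1])
    else:
        keep = set(dates)

    sums: dict[dt.date, np.ndarray] = {d: np.zeros(GRID_SLOTS) for d in keep}
    counts: dict[dt.date, np.ndarray] = {d: np.zeros(GRID_SLOTS) for d in keep}
    for ts, g in zip(record.timestamps, record.glucose):
        d = ts.date()
        if d not in keep:
            continue
        slot = _snap_slot(ts)
        sums[d][slot] += g
        counts[d][slot] += 1

    out = []
    for d in sorted(keep):
        c = counts[d]
        with np.errstate(invalid="ignore"):
            vals = np.where(c > 0, sums[d] / np.maximum(c, 1), np.nan)
        vals = np.where(c > 0, np.clip(vals, GLUCOSE_MIN, GLUCOSE_MAX), np.nan)
        out.append(DayProfile(record.subject_id, d, vals, c > 0))
    return out


def downsample(day: DayProfile, interval: float) -> DayProfile:
    """Keep every (interval/5)-th slot; mask the rest. Grid length stays 288."""
    if interval <= 0 or interval % SLOT_MINUTES != 0:
        raise ValueError("interval must be a positive multiple of 5 minutes")
    step = int(interval // SLOT_MINUTES)
    mask = np.zeros(GRID_SLOTS, dtype=bool)
    mask[::step] = True
    mask &= day.present_mask
    values = np.where(mask, day.values, np.nan)
    return DayProfile(day.subject_id, day.date, values, mask)
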