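"""Glycemic metrics derived from day profiles.

Core panel: mean, SD, CV, TIR/TAR/TBR (fractions of present time in
[70, 180] / >180 / <70 mg/dL), MAGE (classical 1-SD turning-point
algorithm), eA1C = (mean + 46.7) / 28.7, HBGI (Kovatchev risk transform),
fasting-window SD, postprandial glycemic rate (max over meals of
(peak - pre-meal) / time-to-peak), and trapezoidal AUC. Plus a
high-variance flag over a cohort and autoregressive order selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .types import (
    GRID_SLOTS,
    HYPER_THRESHOLD,
    HYPO_THRESHOLD,
    SLOT_MINUTES,
    DayProfile,
)

__all__ = [
    "MetricPanel",
    "MetricWindows",
    "HVFlag",
    "compute_metrics",
    "mage",
    "flag_hv",
    "ar_order_selection",
]

log = logging.getLogger(__name__)

DEFAULT_FASTING_WINDOW = (0, 360)            # 00:00-06:00, minutes-of-day
DEFAULT_MEAL_MINUTES = (450, 750, 1110)      # 07:30 / 12:30 / 18:30
POSTPRANDIAL_MINUTES = 120


@dataclass(frozen=True)
class MetricWindows:
    fasting: tuple[int, int] = DEFAULT_FASTING_WINDOW
    meal_minutes: tuple[float, ...] = DEFAULT_MEAL_MINUTES
    postprandial_minutes: int = POSTPRANDIAL_MINUTES


@dataclass
class MetricPanel:
    mean: float
    sd: float
    cv: float
    tir: float
    tar: float
    tbr: float
    mage: float
    ea1c: float
    hbgi: float
    fasting_sd: float
    postprandial_rate: float
    auc: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class HVFlag:
    subject_id: str
    is_hv: bool
    fasting_sd_percentile: float
    postprandial_rate_percentile: float


def mage(values: np.ndarray) -> float:
    """Mean absolute amplitude of excursions exceeding 1 SD between
    consecutive turning points (classical algorithm, both directions)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        return 0.0
    sd = v.std(ddof=0)
    if sd == 0:
        return 0.0
    # turning points: first point, sign changes of the difference, last point
    diffs = np.diff(v)
    nz = diffs != 0
    idx = [0]
    last_sign = 0
    for i, d in enumerate(diffs):
        if d == 0:
            continue
        s = 1 if d > 0 else -1
        if last_sign != 0 and s != last_sign:
            idx.append(i)
        last_sign = s
    idx.append(v.size - 1)
    turning = v[np.unique(idx)]
    amplitudes = np.abs(np.diff(turning))
    qualified = amplitudes[amplitudes > sd]
    return float(qualified.mean()) if qualified.size else 0.0


def _hbgi(values: np.ndarray) -> float:
    f = 1.509 * (np.log(values) ** 1.084 - 5.381)
    risk = 10.0 * np.square(np.maximum(f, 0.0))
    return float(risk.mean())


def compute_metrics(
    day: DayProfile,
    windows: MetricWindows | None = None,
    min_coverage: float = 0.10,
) -> MetricPanel:
    windows = windows or MetricWindows()
    present = day.present_mask
    coverage = present.mean()
    if coverage < min_coverage:
        raise ValueError(
            f"insufficient data: {present.sum()}/{GRID_SLOTS} slots present "
            f"({coverage:.1%} < {min_coverage:.0%})"
        )
    v = day.values[present]
    minutes = day.slot_minutes()[present]

    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    cv = sd / mean if mean else 0.0
    tbr = float((v < HYPO_THRESHOLD).mean())
    tar = float((v > HYPER_THRESHOLD).mean())
    tir = 1.0 - tbr - tar

    ea1c = (mean + 46.7) / 28.7
    hbgi = _hbgi(v)

    lo, hi = windows.fasting
    fasting = v[(minutes >= lo) & (minutes < hi)]
    fasting_sd = float(fasting.std(ddof=0)) if fasting.size >= 2 else float("nan")

    rate = float("nan")
    rates = []
    for m in windows.meal_minutes:
        pre = v[minutes <= m]
        post_sel = (minutes > m) & (minutes <= m + windows.postprandial_minutes)
        post = v[post_sel]
        post_minutes = minutes[post_sel]
        if pre.size == 0 or post.size == 0:
            continue
        pre_value = pre[-1]
        k = int(np.argmax(post))
        dt_min = post_minutes[k] - m
        if dt_min > 0:
            rates.append((post[k] - pre_value) / dt_min)
    if rates:
        rate = float(max(rates))

    auc = float(np.trapezoid(v, minutes)) if v.size >= 2 else 0.0

    return MetricPanel(mean, sd, cv, tir, tar, tbr, mage(day.values), ea1c, hbgi,
                       fasting_sd, rate, auc)


def flag_hv(
    subject_metrics: dict[str, list[MetricPanel]],
    fasting_sd_percentile: float = 75.0,
    rate_percentile: float = 75.0,
) -> list[HVFlag]:
    """Flag subjects whose mean fasting SD AND mean postprandial rate both
    strictly exceed the cohort percentile thresholds."""
    if len(subject_metrics) < 10:
        raise ValueError("need at least 10 subjects for cohort percentiles")
    subjects = sorted(subject_metrics)
    f_sd = np.array([
        np.nanmean([m.fasting_sd for m in subject_metrics[s]]) for s in subjects
    ])
    p_rate = np.array([
        np.nanmean([m.postprandial_rate for m in subject_metrics[s]]) for s in subjects
    ])
    f_thr = np.nanpercentile(f_sd, fasting_sd_percentile)
    r_thr = np.nanpercentile(p_rate, rate_percentile)

    from scipy.stats import rankdata

    f_pct = 100.0 * (rankdata(f_sd) - 1) / max(len(subjects) - 1, 1)
    r_pct = 100.0 * (rankdata(p_rate) - 1) / max(len(subjects) - 1, 1)
    return [
        HVFlag(s, bool(f_sd[i] > f_thr and p_rate[i] > r_thr),
               float(f_pct[i]), float(r_pct[i]))
        for i, s in enumerate(subjects)
    ]


def ar_order_selection(
    day: DayProfile | np.ndarray,
    max_order: int = 72,
    ic: str = "bic",
) -> tuple[int, float]:
    """Select an AR order for the 5-minute series by information criterion.

    Missing interior slots are linearly interpolated first. Returns
    (order, order in hours); order 36 corresponds to 3 hours on the
    5-minute grid. A constant series selects order 0 with a warning.
    """
    if max_order > 72:
        raise ValueError("max_order must be <= 72")
    if isinstance(day, DayProfile):
        if day.present_mask.sum() < 2:
            raise ValueError("need at least 2 present values")
        x = np.arange(GRID_SLOTS)
        series = np.interp(x, x[day.present_mask], day.values[day.present_mask])
    else:
        series = np.asarray(day, dtype=float)
    n = series.size
    if np.allclose(series, series[0]):
        warnings.warn("constant series: AR order 0 selected")
        return 0, 0.0

    from statsmodels.tsa.ar_model import AutoReg

    best_order, best_crit = 1, np.inf
    for order in range(1, max_order + 1):
        if n - max_order <= order + 2:
            break
        # hold_back fixes the estimation sample across orders so the
        # information criteria are comparable
        res = AutoReg(series, lags=order, hold_back=max_order, old_names=False).fit()
        k = order + 2  # AR coefficients + intercept + innovation variance
        nobs = res.nobs
        if ic == "aicc":
            crit = res.aic + 2.0 * k * (k + 1) / max(nobs - k - 1, 1)
        elif ic == "aic":
            crit = res.aic
        elif ic == "bic":
            crit = res.bic
        else:
            raise ValueError(f"unknown information criterion {ic!r}")
        if crit < best_crit:
            best_crit, best_order = crit, order
    return best_order, best_order * SLOT_MINUTES / 60.0
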