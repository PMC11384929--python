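"""Phase segmentation, normalization, production rates and dose comparison.

A multi-feed BMP assay produces one cumulative methane curve per reactor,
punctuated by feed events.  This module cuts the curve into per-phase
segments (half-open windows [feed_i, feed_{i+1}), the last closed at the
horizon), re-zeroes each segment at its feed instant, normalizes by the
grams of volatile solids fed, derives smoothed production-rate series in
mL/hr, extracts rate peaks, and computes the pairwise relative-increase
statistic used to compare biochar doses:

    RI(low, high) = (high - low) / high * 100   [%]

with the higher-dose value always in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

__all__ = [
    "GasSeries",
    "RatePeak",
    "RelativeIncreaseMatrix",
    "segment",
    "normalize_per_vs",
    "production_rate",
    "find_peaks",
    "relative_increase",
    "relative_increase_matrix",
]

#: Cumulative dips up to this many mL are treated as meter jitter.
MONOTONE_TOLERANCE_ML = 0.01


@dataclass
class GasSeries:
    """One reactor's cumulative CH4 series plus assay metadata.

    times
        Days from experiment start, strictly increasing (15-min grid in a
        standard AMPTS export).
    cumulative_ml
        Nondecreasing cumulative CH4 volume (normalized gas, mL).
    feed_events
        Sequence of ``(day, g VS fed)`` pairs.
    ph_track
        Optional ``(day, pH)`` observations; carried, never computed on.
    """

    times: np.ndarray
    cumulative_ml: np.ndarray
    reactor_id: str = ""
    biochar_dose_g_per_l: float = 0.0
    feed_events: tuple[tuple[float, float], ...] = ()
    ph_track: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_ml = np.asarray(self.cumulative_ml, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.cumulative_ml.shape:
            raise ValueError("times and cumulative_ml must be equal-length 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.biochar_dose_g_per_l < 0:
            raise ValueError("biochar dose must be nonnegative")
        dips = np.diff(self.cumulative_ml)
        if dips.size and dips.min() < -MONOTONE_TOLERANCE_ML:
            i = int(np.argmin(dips))
            raise ValueError(
                f"cumulative volume decreases by {-dips.min():.4f} mL at index {i + 1}"
            )
        self.feed_events = tuple((float(d), float(m)) for d, m in self.feed_events)

    @property
    def final_ml(self) -> float:
        return float(self.cumulative_ml[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "reactor_id": self.reactor_id,
                "cumulative_ml": self.cumulative_ml,
            }
        )


@dataclass(frozen=True)
class RatePeak:
    """A local maximum of the production-rate series."""

    day: float
    rate_ml_per_hr: float
    phase_index: int = 0


@dataclass(frozen=True)
class RelativeIncreaseMatrix:
    """Lower-triangular pairwise relative increases between dose levels."""

    doses: tuple[float, ...]
    values: pd.DataFrame  # rows: high dose; columns: low dose; % entries
    basis: str

    def at(self, high_dose: float, low_dose: float) -> float:
        return float(self.values.loc[high_dose, low_dose])


def segment(series: GasSeries, horizon: float) -> list[GasSeries]:
    """Split a cumulative series into per-phase series re-zeroed at feeds.

    Window *i* spans [feed_i, feed_{i+1}) and the last window is closed at
    ``horizon``.  Each phase's cumulative is re-zeroed to the volume
    already produced before its feed instant, so the per-phase finals sum
    to the whole-series final (volume conservation).
    """
    if not series.feed_events:
        raise ValueError("series has no feed events")
    feed_days = [d for d, _ in series.feed_events]
    if feed_days[0] != 0.0:
        raise ValueError("first feed must be at day 0")
    if any(d >= horizon for d in feed_days):
        raise ValueError("feed event beyond the horizon")
    bounds = feed_days + [float(horizon)]

    phases = []
    for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        last = i == len(feed_days) - 1
        if last:
            mask = (series.times >= lo) & (series.times <= hi)
        else:
            mask = (series.times >= lo) & (series.times < hi)
        t = series.times[mask]
        before = series.cumulative_ml[series.times < lo]
        baseline = float(before[-1]) if before.size else 0.0
        c = np.maximum(series.cumulative_ml[mask] - baseline, 0.0)
        phases.append(
            GasSeries(
                times=t,
                cumulative_ml=c,
                reactor_id=series.reactor_id,
                biochar_dose_g_per_l=series.biochar_dose_g_per_l,
                feed_events=(series.feed_events[i],),
                ph_track=series.ph_track,
            )
        )
    return phases


def normalize_per_vs(phase: GasSeries, vs_fed: float) -> pd.Series:
    """Per-g-VS cumulative curve (mL/g-VS) of a phase, indexed by day."""
    if vs_fed <= 0:
        raise ValueError("vs_fed must be positive")
    return pd.Series(
        phase.cumulative_ml / vs_fed,
        index=pd.Index(phase.times, name="time_days"),
        name=f"{phase.reactor_id}_bmp_ml_per_gvs",
    )


def production_rate(series: GasSeries, window_hr: float = 1.0) -> pd.Series:
    """Smoothed production-rate series in mL/hr.

    Finite differences of the cumulative volume are converted to mL/hr
    (increment x 4 on the standard 15-min grid) and smoothed with a
    centered moving average spanning ``window_hr`` hours.
    """
    if series.times.size < 2:
        raise ValueError("need at least 2 points for a rate")
    dt_hr = np.diff(series.times) * 24.0
    rate = np.diff(series.cumulative_ml) / dt_hr
    t_mid = series.times[1:]
    out = pd.Series(rate, index=pd.Index(t_mid, name="time_days"), name="rate_ml_per_hr")
    if window_hr > 0:
        n_win = max(int(round(window_hr / float(np.median(dt_hr)))), 1)
        out = out.rolling(n_win, center=True, min_periods=1).mean()
    return out


def find_peaks(
    rate: pd.Series,
    min_prominence: float = 0.5,
    min_separation_days: float = 0.5,
    phase_index: int = 0,
) -> list[RatePeak]:
    """Local maxima of a rate series with prominence and separation gates.

    Boundary samples are never reported as peaks.  An empty list is a
    valid outcome (e.g. an all-zero or monotone rate series).
    """
    if rate.empty:
        raise ValueError("rate series is empty")
    values = rate.to_numpy(dtype=float)
    times = rate.index.to_numpy(dtype=float)
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    distance = max(int(round(min_separation_days / dt)), 1)
    idx, _ = _scipy_find_peaks(values, prominence=min_prominence, distance=distance)
    return [
        RatePeak(day=float(times[i]), rate_ml_per_hr=float(values[i]), phase_index=phase_index)
        for i in idx
    ]


def relative_increase(low_value: float, high_value: float) -> float:
    """Relative increase in % with the higher-dose value as denominator.

    >>> round(relative_increase(334.71, 390.33), 2)
    14.25
    """
    if high_value <= 0:
        raise ValueError("high_value must be positive")
    return (high_value - low_value) / high_value * 100.0


def relative_increase_matrix(
    values_by_dose: Mapping[float, float], basis: str = "phase4_bmp"
) -> RelativeIncreaseMatrix:
    """Pairwise relative increases for every ordered low→high dose pair.

    ``values_by_dose`` maps biochar dose (g/L) to the yield being compared
    (60-day cumulative BMY in mL, or final-phase BMP in mL/g-VS).  The
    result is lower-triangular: row = higher dose, column = lower dose.
    """
    doses = sorted(values_by_dose)
    if len(doses) < 2:
        raise ValueError("need at least 2 doses")
    if len(doses) != len(values_by_dose):
        raise ValueError("duplicate dose labels")
    mat = pd.DataFrame(np.nan, index=doses, columns=doses, dtype=float)
    for i, hi in enumerate(doses):
        mat.loc[hi, hi] = 0.0
        for lo in doses[:i]:
            mat.loc[hi, lo] = relative_increase(values_by_dose[lo], values_by_dose[hi])
    mat.index.name = "high_dose_g_per_l"
    mat.columns.name = "low_dose_g_per_l"
    return RelativeIncreaseMatrix(doses=tuple(doses), values=mat, basis=basis)
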