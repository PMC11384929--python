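"""First-order inoculum-carbon depletion and multi-feed assay design.

Residual organics in an anaerobic inoculum produce background methane that
confounds substrate-only BMP estimates.  The background follows first-order
kinetics,

    BMY(t) = uBMY * (1 - exp(-k * t)),

so the day by which a target fraction of the inoculum's ultimate yield has
been produced is known in closed form, and a feeding plan can place the
final ("isolated-substrate") feed after that day plus a settling margin.
With the inoculum anchor values uBMY = 3089.74 mL and k = 0.13 1/d, 99 %
depletion is reached after 36 whole days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FirstOrderModel",
    "FeedingPlan",
    "bmy_at",
    "fraction_achieved",
    "time_to_fraction",
    "design_plan",
    "refeed_ready",
]


@dataclass(frozen=True)
class FirstOrderModel:
    """First-order cumulative-yield model: asymptote and rate constant."""

    ubmy_ml: float
    k_per_day: float

    def __post_init__(self) -> None:
        if self.k_per_day <= 0:
            raise ValueError("k_per_day must be positive")
        if self.ubmy_ml < 0:
            raise ValueError("ubmy_ml must be nonnegative")

    def bmy_at(self, t):
        return bmy_at(self, t)


@dataclass(frozen=True)
class FeedingPlan:
    """Multi-feed assay design with the isolated-substrate phase marked.

    ``phase_windows`` are half-open day intervals [feed_i, feed_{i+1}),
    the last closed at the horizon; together they partition [0, horizon].
    ``isolated_phase_index`` points at the phase in which the inoculum
    background is considered depleted.
    """

    feed_days: tuple[float, ...]
    feed_masses_gvs: tuple[float, ...]
    phase_windows: tuple[tuple[float, float], ...]
    depletion_day: int
    settle_days: float
    isolated_phase_index: int
    refeed_rate_threshold: float = 0.1  # mL CH4/hr

    @property
    def isolated_window(self) -> tuple[float, float]:
        return self.phase_windows[self.isolated_phase_index]


def bmy_at(model: FirstOrderModel, t) -> np.ndarray | float:
    """Cumulative first-order yield uBMY*(1 - e^(-k t)) at day(s) ``t``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = model.ubmy_ml * (1.0 - np.exp(-model.k_per_day * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def fraction_achieved(k_per_day: float, t) -> np.ndarray | float:
    """Fraction of the ultimate yield produced by day ``t``: 1 - e^(-k t)."""
    if k_per_day <= 0:
        raise ValueError("k_per_day must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = 1.0 - np.exp(-k_per_day * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def time_to_fraction(k_per_day: float, target: float) -> tuple[float, int]:
    """Days to reach a target fraction of the ultimate yield.

    Returns ``(real_days, whole_day)`` where ``real_days`` solves
    1 - e^(-k t) = target and ``whole_day`` is its ceiling — conservative
    whole-day reporting guarantees the fraction is met.

    >>> time_to_fraction(0.13, 0.99)
    (35.42..., 36)
    """
    if k_per_day <= 0:
        raise ValueError("k_per_day must be positive")
    if not (0.0 < target < 1.0):
        raise ValueError("target fraction must be in (0, 1); the asymptote is never reached")
    real_days = -math.log(1.0 - target) / k_per_day
    return real_days, math.ceil(real_days)


def design_plan(
    inoculum: FirstOrderModel,
    target: float = 0.99,
    settle_days: float = 14.0,
    horizon: float = 60.0,
    feed_days: Sequence[float] = (0.0, 8.0, 21.0, 44.0),
    feed_masses_gvs: Sequence[float] | float = 2.6,
    refeed_rate_threshold: float = 0.1,
) -> FeedingPlan:
    """Design a multi-feed plan that isolates the substrate-only phase.

    The inoculum background is considered depleted on ``depletion_day``
    (whole-day solution of :func:`time_to_fraction`).  The isolated phase
    starts at the first feed on or after that day and must last at least
    ``settle_days`` before the horizon, so background carry-over has
    settled out of the final window.

    Feed masses default to equal g VS per feed; pass a sequence for
    per-feed loads.
    """
    feeds = tuple(float(d) for d in feed_days)
    if not feeds:
        raise ValueError("feed_days must be nonempty")
    if feeds[0] != 0.0:
        raise ValueError("first feed must be at day 0")
    if any(b <= a for a, b in zip(feeds, feeds[1:])):
        raise ValueError("feed_days must be strictly increasing")
    if feeds[-1] >= horizon:
        raise ValueError("last feed must precede the horizon")

    if np.isscalar(feed_masses_gvs):
        masses = (float(feed_masses_gvs),) * len(feeds)
    else:
        masses = tuple(float(m) for m in feed_masses_gvs)
        if len(masses) != len(feeds):
            raise ValueError("feed_masses_gvs length must match feed_days")

    _, depletion_day = time_to_fraction(inoculum.k_per_day, target)

    isolated_idx = next(
        (i for i, d in enumerate(feeds) if d >= depletion_day), None
    )
    if isolated_idx is None:
        raise ValueError(
            f"no feed on or after depletion day {depletion_day}; "
            f"add a feed at day >= {depletion_day}"
        )
    required = feeds[isolated_idx] + settle_days
    if horizon < required:
        raise ValueError(
            f"horizon {horizon} too short: isolated phase starting day "
            f"{feeds[isolated_idx]} needs at least {required} days"
        )

    bounds = feeds + (float(horizon),)
    windows = tuple((bounds[i], bounds[i + 1]) for i in range(len(feeds)))
    return FeedingPlan(
        feed_days=feeds,
        feed_masses_gvs=masses,
        phase_windows=windows,
        depletion_day=depletion_day,
        settle_days=float(settle_days),
        isolated_phase_index=isolated_idx,
        refeed_rate_threshold=refeed_rate_threshold,
    )


def refeed_ready(
    times_days: Sequence[float],
    rates_ml_per_hr: Sequence[float],
    threshold: float = 0.1,
    persistence_hr: float = 2.0,
) -> float | None:
    """Earliest time at which production stays below the re-feed threshold.

    Scans for the first time point from which the rate remains below
    ``threshold`` for at least ``persistence_hr`` hours (guards against
    momentary dips).  Returns that time in days, or ``None`` if the rate
    never settles below the threshold.
    """
    t = np.asarray(times_days, dtype=float)
    r = np.asarray(rates_ml_per_hr, dtype=float)
    if t.size == 0:
        raise ValueError("rate series is empty")
    if t.shape != r.shape:
        raise ValueError("times and rates must have equal length")

    below = r < threshold
    persistence_days = persistence_hr / 24.0
    n = t.size
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        # extent of this below-threshold run
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        run_spans_window = (t[j] - t[i]) >= persistence_days or j == n - 1
        if run_spans_window:
            return float(t[i])
        i = j + 1
    return None
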