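"""ARIMA modeling of whole-experiment cumulative methane yield.

Cumulative gas curves are smooth and integrated-looking, so a low-order
ARIMA(p, d, q) with d >= 1 captures them well.  The workflow here mirrors
common practice for instrumented assays: a chronological 70/20/10
train/validation/prediction split (no shuffling — leakage across time is
the failure mode), AIC-minimizing order selection over a bounded grid, and
one-step-ahead forecast metrics on the held-out segments.

Estimation is delegated to :class:`statsmodels.tsa.arima.model.ARIMA`
(Gaussian innovations, no seasonal terms, trend handled by differencing
only); this module owns the splitting, the grid search with its
tie-breaking, and the metric computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from statsmodels.tsa.arima.model import ARIMA, ARIMAResults

from .kinetics import FitDiagnostics, diagnostics

__all__ = [
    "ArimaOrder",
    "ArimaReport",
    "chronological_split",
    "fit_order",
    "select_order",
    "forecast_metrics",
]


@dataclass(frozen=True)
class ArimaOrder:
    """(p, d, q): autoregressive, differencing and moving-average orders."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be nonnegative")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass
class FittedArima:
    """A fitted model handle with its in-sample diagnostics."""

    order: ArimaOrder
    results: ARIMAResults
    in_sample: FitDiagnostics
    aic: float
    flagged: str | None = None  # non-stationary / non-invertible / convergence notes


@dataclass
class ArimaReport:
    """Order-selection outcome with per-segment forecast diagnostics."""

    order: ArimaOrder
    train: FitDiagnostics
    validation: FitDiagnostics | None
    prediction: FitDiagnostics | None
    selected_by: str
    n_train: int
    n_val: int
    n_test: int
    candidates: list[tuple[tuple[int, int, int], float]] = field(default_factory=list)


def chronological_split(
    series: Sequence[float], fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contiguous train/validation/prediction split, earliest first.

    Validation and prediction get ``floor(f * n)`` points each; the
    remainder goes to training, so the three segments concatenate back to
    the original series.  For n = 5760 this gives (4032, 1152, 576).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError(f"series too short to split: {n} < 10")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    return y[:n_train], y[n_train : n_train + n_val], y[n_train + n_val :]


def fit_order(series: Sequence[float], order: ArimaOrder) -> FittedArima:
    """Fit one ARIMA order by Gaussian maximum likelihood.

    Non-invertible or non-stationary solutions and convergence trouble are
    recorded on the ``flagged`` field rather than raised, so a grid search
    can keep going.
    """
    y = np.asarray(series, dtype=float)
    min_len = order.p + order.q + order.d + 2
    if y.size <= min_len:
        raise ValueError(f"series length {y.size} <= p+q+d+2 = {min_len}")
    notes = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = ARIMA(y, order=order.as_tuple())
        res = model.fit()
        for w in caught:
            msg = str(w.message)
            if any(k in msg.lower() for k in ("stationar", "invert", "converge")):
                notes.append(msg)
    pred = res.fittedvalues
    # skip the first d values: undefined under differencing
    d = order.d
    diag = diagnostics(y[d:], np.asarray(pred)[d:], n_params=order.p + order.q + 1)
    return FittedArima(
        order=order,
        results=res,
        in_sample=diag,
        aic=float(res.aic),
        flagged="; ".join(notes) or None,
    )


def select_order(
    series: Sequence[float],
    p_max: int = 8,
    q_max: int = 8,
    d_max: int = 2,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
) -> tuple[ArimaReport, FittedArima]:
    """Grid-search (p, d, q) by training-segment AIC and score all splits.

    Ties are broken by smaller p+q, then smaller d.  The default grid
    covers p, q in [0, 8] and d in [0, 2]; shrink it for long series —
    cost grows with the product of the grid size and the series length.
    """
    y = np.asarray(series, dtype=float)
    train, val, test = chronological_split(y, fractions)
    if float(np.var(train)) == 0.0:
        raise ValueError("constant training series: ARIMA selection is degenerate")

    candidates: list[tuple[tuple[int, int, int], float]] = []
    fits: dict[tuple[int, int, int], FittedArima] = {}
    failures: list[str] = []
    for p, d, q in product(range(p_max + 1), range(d_max + 1), range(q_max + 1)):
        order = ArimaOrder(p, d, q)
        try:
            fit = fit_order(train, order)
        except Exception as exc:  # noqa: BLE001 — grid member failure is data
            failures.append(f"{order.as_tuple()}: {exc}")
            continue
        fits[order.as_tuple()] = fit
        candidates.append((order.as_tuple(), fit.aic))
    if not fits:
        raise RuntimeError("all ARIMA fits failed: " + "; ".join(failures))

    best_key = min(fits, key=lambda k: (fits[k].aic, k[0] + k[2], k[1]))
    best = fits[best_key]

    val_diag = forecast_metrics(best, val) if val.size else None
    # prediction segment is forecast after train+val, params held fixed
    if test.size:
        extended = best.results.apply(np.concatenate([train, val]))
        handle = FittedArima(best.order, extended, best.in_sample, best.aic, best.flagged)
        test_diag = forecast_metrics(handle, test)
    else:
        test_diag = None
    report = ArimaReport(
        order=best.order,
        train=best.in_sample,
        validation=val_diag,
        prediction=test_diag,
        selected_by="aic",
        n_train=train.size,
        n_val=val.size,
        n_test=test.size,
        candidates=sorted(candidates, key=lambda c: c[1]),
    )
    return report, best


def forecast_metrics(fit: FittedArima, segment: Sequence[float]) -> FitDiagnostics:
    """One-step-ahead forecast diagnostics on a held-out segment.

    The fitted parameters are frozen; the model state is rolled through
    the segment so each point is predicted from everything before it.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        raise ValueError("segment is empty")
    extended = fit.results.extend(seg)
    pred = np.asarray(extended.fittedvalues)
    k = fit.order.p + fit.order.q + 1
    return diagnostics(seg, pred, n_params=k, converged=True)
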