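"""Modified-Gompertz and first-order kinetics for cumulative methane curves.

The modified Gompertz model describes a cumulative per-g-VS methane curve
with a plateau ``bBMP`` (mL CH4/g-VS), a maximum production rate ``Rmax``
(mL CH4/g-VS/day) and a lag phase ``lambda`` (days):

    BMP(t) = bBMP * exp(-exp(Rmax * e / bBMP * (lambda - t) + 1))

where e = exp(1).  Rmax is exactly the maximum slope of the curve, attained
at t = lambda + bBMP / (Rmax * e).  The first-order alternative
uBMY * (1 - exp(-k t)) has no lag and a single rate constant.

Both models are fitted by trust-region nonlinear least squares with
positivity bounds; diagnostics follow the conventions usual in BMP work:
RMSE = sqrt(RSS/n), R^2 = 1 - RSS/TSS, the Nash–Sutcliffe model efficiency
NSE (identical to R^2 about the observed mean), and a Gaussian-likelihood
AIC = n ln(RSS/n) + 2(K+1) counting the residual variance as a parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .scheduler import FirstOrderModel

__all__ = [
    "GompertzParams",
    "FitDiagnostics",
    "FirstOrderFit",
    "gompertz_bmp",
    "gompertz_rate",
    "fit_gompertz",
    "fit_first_order",
    "diagnostics",
]

_E = math.e


@dataclass(frozen=True)
class GompertzParams:
    """Modified-Gompertz parameter set (plateau, max rate, lag)."""

    bbmp: float  # mL CH4/g-VS
    rmax: float  # mL CH4/g-VS/day
    lag_days: float

    def __post_init__(self) -> None:
        if self.bbmp <= 0:
            raise ValueError("bbmp must be positive")
        if self.rmax <= 0:
            raise ValueError("rmax must be positive")
        if self.lag_days < 0:
            raise ValueError("lag_days must be nonnegative")


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary for a fitted curve."""

    rmse: float
    r_squared: float
    aic: float
    nse: float
    n_points: int
    converged: bool
    residual_sum_squares: float


@dataclass(frozen=True)
class FirstOrderFit:
    params: FirstOrderModel
    diagnostics: FitDiagnostics


def _check_series(times, values, min_points: int = 8):
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {t.size}")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.any(y > 0):
        raise ValueError("degenerate series: no positive values to fit")
    return t, y


def gompertz_bmp(params: GompertzParams, t) -> np.ndarray | float:
    """Evaluate the modified Gompertz curve at day(s) ``t``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    inner = params.rmax * _E / params.bbmp * (params.lag_days - t_arr) + 1.0
    out = params.bbmp * np.exp(-np.exp(inner))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def gompertz_rate(params: GompertzParams, t) -> np.ndarray | float:
    """Analytic production rate dBMP/dt (mL/g-VS/day) of the Gompertz curve.

    With u(t) = exp(Rmax e / bBMP (lambda - t) + 1) the rate is
    Rmax * e * u * exp(-u); its maximum over t equals Rmax (at u = 1).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    u = np.exp(params.rmax * _E / params.bbmp * (params.lag_days - t_arr) + 1.0)
    out = params.rmax * _E * u * np.exp(-u)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def diagnostics(observed, predicted, n_params: int, converged: bool = True) -> FitDiagnostics:
    """Fit diagnostics for a predicted curve against observations.

    ``n_params`` is the number of model parameters K; AIC adds one for the
    residual variance.  Zero-variance observations leave R^2/NSE as NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 points for diagnostics")
    rss = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    rmse = math.sqrt(rss / n)
    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        warnings.warn("zero-variance observations: R^2/NSE undefined", RuntimeWarning)
        r2 = math.nan
    # NSE shares the R^2-about-the-mean formula; kept as its own field
    # because BMP papers report it separately.
    nse = r2
    aic = n * math.log(rss / n) + 2.0 * (n_params + 1) if rss > 0 else -math.inf
    return FitDiagnostics(
        rmse=rmse,
        r_squared=r2,
        aic=aic,
        nse=nse,
        n_points=n,
        converged=converged,
        residual_sum_squares=rss,
    )


def _initial_gompertz(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Heuristic start: plateau from max, rate from smoothed differences,
    lag from the earliest time reaching 1 % of the plateau."""
    bbmp0 = float(y.max())
    dy = np.diff(y) / np.diff(t)
    if dy.size >= 5:
        kernel = np.ones(5) / 5.0
        dy = np.convolve(dy, kernel, mode="same")
    rmax0 = float(max(dy.max(), 1e-6)) if dy.size else 1e-6
    above = np.nonzero(y >= 0.01 * bbmp0)[0]
    lag0 = float(t[above[0]]) if above.size else 0.0
    return np.array([bbmp0, rmax0, lag0])


def fit_gompertz(
    times,
    values,
    init: GompertzParams | None = None,
) -> tuple[GompertzParams, FitDiagnostics]:
    """Least-squares fit of the modified Gompertz model to a cumulative curve.

    ``values`` is the per-g-VS cumulative methane curve of one phase,
    re-zeroed at the feed instant.  Non-convergence is reported through the
    diagnostics ``converged`` flag (best iterate returned, never raised).
    """
    t, y = _check_series(times, values)
    if init is not None:
        x0 = np.array([init.bbmp, init.rmax, init.lag_days])
    else:
        x0 = _initial_gompertz(t, y)
    x0 = np.maximum(x0, [1e-9, 1e-9, 0.0])

    def resid(x):
        b, r, lam = x
        inner = r * _E / b * (lam - t) + 1.0
        return b * np.exp(-np.exp(np.clip(inner, -700, 700))) - y

    sol = least_squares(
        resid,
        x0,
        bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=10_000,
    )
    params = GompertzParams(bbmp=sol.x[0], rmax=sol.x[1], lag_days=sol.x[2])
    pred = gompertz_bmp(params, t)
    diag = diagnostics(y, pred, n_params=3, converged=bool(sol.success))
    return params, diag


def fit_first_order(times, values) -> FirstOrderFit:
    """Least-squares fit of uBMY*(1 - e^(-k t)) to a cumulative curve."""
    t, y = _check_series(times, values)
    ubmy0 = float(y.max())
    # early-segment slope ~ uBMY * k
    k0 = 0.1
    nz = np.nonzero(y > 0.05 * ubmy0)[0]
    if nz.size and t[nz[0]] > 0:
        k0 = max(min(1.0 / t[nz[0]], 10.0), 1e-3)

    def resid(x):
        u, k = x
        return u * (1.0 - np.exp(-k * t)) - y

    sol = least_squares(
        resid,
        np.array([max(ubmy0, 1e-9), k0]),
        bounds=([1e-12, 1e-9], [np.inf, np.inf]),
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=10_000,
    )
    model = FirstOrderModel(ubmy_ml=float(sol.x[0]), k_per_day=float(sol.x[1]))
    pred = model.ubmy_ml * (1.0 - np.exp(-model.k_per_day * t))
    diag = diagnostics(y, pred, n_params=2, converged=bool(sol.success))
    return FirstOrderFit(params=model, diagnostics=diag)
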