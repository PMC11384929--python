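"""Synthetic AMPTS-style multi-reactor BMP experiments.

Generates cumulative methane curves with the statistical structure the
analysis pipeline assumes, so every stage is testable without instrument
data.  Each reactor's noiseless curve is

    C(t) = uBMY_inoc * (1 - e^(-k t))                       (background)
         + sum over feeds  m_f * G(t - t_f; dose params)    (pulses)

where G is the modified Gompertz curve per gram VS and m_f the grams VS
fed.  The default world: doses 0/2/4/6/8 g/L in triplicate, feeds at days
0/8/21/44 of 2.6 g VS each, a 60-day horizon on a 15-min grid (5760
samples per reactor), inoculum background uBMY = 3089.74 mL with
k = 0.13 1/d, and per-dose Gompertz parameters anchored on the final-phase
dose–response (bBMP rising 128.82 → 394.16 mL/g-VS from 0 to 8 g/L).

Noise is applied to *increments* (then cumulated) — that is how a gas
counter accumulates error — and truncated at zero so curves stay
nondecreasing.  Replicate parameters are jittered log-normally to stay
positive.  Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .kinetics import GompertzParams, gompertz_bmp
from .phases import GasSeries
from .scheduler import FirstOrderModel

__all__ = ["TABLE_DOSE_PARAMS", "SyntheticSpec", "generate", "ground_truth"]

#: Final-phase modified-Gompertz parameters per biochar dose (g/L):
#: (bBMP mL/g-VS, Rmax mL/g-VS/day, lag days) — the dose–response anchors.
TABLE_DOSE_PARAMS: dict[float, GompertzParams] = {
    0.0: GompertzParams(128.82, 26.32, 0.76),
    2.0: GompertzParams(225.04, 38.27, 0.42),
    4.0: GompertzParams(372.05, 47.39, 0.47),
    6.0: GompertzParams(381.13, 59.95, 0.51),
    8.0: GompertzParams(394.16, 90.97, 0.10),
}

#: pH anchor tracks per dose mimicking observed reactor behaviour
#: (visualization fixtures only; never used in computation).
_PH_ANCHORS: dict[float, tuple[tuple[float, float], ...]] = {
    0.0: ((0, 7.1), (10, 6.7), (20, 5.1), (60, 4.4)),
    2.0: ((0, 7.1), (10, 7.9), (40, 6.8), (60, 6.5)),
    4.0: ((0, 7.1), (10, 7.9), (40, 6.8), (45, 6.9), (60, 6.5)),
    6.0: ((0, 7.2), (10, 8.0), (45, 7.6), (50, 7.73), (60, 7.5)),
    8.0: ((0, 7.17), (10, 8.07), (60, 8.17)),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of a synthetic multi-reactor experiment."""

    doses: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    replicates: int = 3
    horizon_days: float = 60.0
    sample_interval_min: float = 15.0
    feed_days: tuple[float, ...] = (0.0, 8.0, 21.0, 44.0)
    feed_masses_gvs: tuple[float, ...] = (2.6, 2.6, 2.6, 2.6)
    inoculum: FirstOrderModel = field(
        default_factory=lambda: FirstOrderModel(ubmy_ml=3089.74, k_per_day=0.13)
    )
    phase_params: Mapping[float, GompertzParams] | None = None
    #: multipliers applied to the per-dose bBMP for feeds 1..n (adaptation
    #: phases reuse the final-phase response unscaled by default)
    phase_bbmp_multipliers: tuple[float, ...] | None = None
    increment_noise_sigma_ml: float = 0.5
    replicate_param_cv: float = 0.02
    include_ph: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.increment_noise_sigma_ml < 0 or self.replicate_param_cv < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not self.feed_days or self.feed_days[0] != 0.0:
            raise ValueError("feeds must start at day 0")
        if len(self.feed_masses_gvs) != len(self.feed_days):
            raise ValueError("one feed mass per feed day required")
        if self.horizon_days <= max(self.feed_days):
            raise ValueError("horizon must cover the last feed")
        if self.sample_interval_min <= 0:
            raise ValueError("sample interval must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.horizon_days * 24 * 60 / self.sample_interval_min))

    def dose_params(self, dose: float) -> GompertzParams:
        table = self.phase_params if self.phase_params is not None else TABLE_DOSE_PARAMS
        try:
            return table[dose]
        except KeyError:
            raise ValueError(f"no Gompertz parameters configured for dose {dose} g/L")

    def time_grid(self) -> np.ndarray:
        dt = self.sample_interval_min / (24 * 60)
        return np.arange(1, self.n_samples + 1) * dt


def _reactor_rng(spec: SyntheticSpec, reactor_index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), int(reactor_index)])


def _jitter(params: GompertzParams, cv: float, rng: np.random.Generator) -> GompertzParams:
    if cv == 0:
        return params
    sigma = np.sqrt(np.log1p(cv**2))  # log-normal with unit mean, given CV
    mu = -0.5 * sigma**2
    f = np.exp(rng.normal(mu, sigma, size=3))
    return GompertzParams(
        bbmp=params.bbmp * f[0],
        rmax=params.rmax * f[1],
        lag_days=max(params.lag_days * f[2], 0.0),
    )


def ground_truth(spec: SyntheticSpec) -> dict[str, dict]:
    """Noiseless per-reactor parameters behind :func:`generate`.

    Maps reactor id → ``{"dose", "inoculum", "feeds": [(day, gvs, GompertzParams), ...]}``.
    Deterministic in (spec, seed) and consistent with the generator because
    both draw the jitter from the same per-reactor substream.
    """
    truth: dict[str, dict] = {}
    idx = 0
    for dose in sorted(spec.doses):
        params = spec.dose_params(dose)
        mults = spec.phase_bbmp_multipliers or (1.0,) * len(spec.feed_days)
        for rep in range(spec.replicates):
            rng = _reactor_rng(spec, idx)
            jittered = _jitter(params, spec.replicate_param_cv, rng)
            feeds = [
                (day, gvs, replace(jittered, bbmp=jittered.bbmp * mult))
                for day, gvs, mult in zip(spec.feed_days, spec.feed_masses_gvs, mults)
            ]
            rid = f"D{dose:g}R{rep + 1}"
            truth[rid] = {"dose": dose, "inoculum": spec.inoculum, "feeds": feeds}
            idx += 1
    return truth


def _noiseless_curve(spec: SyntheticSpec, info: dict, t: np.ndarray) -> np.ndarray:
    inoc: FirstOrderModel = info["inoculum"]
    c = inoc.ubmy_ml * (1.0 - np.exp(-inoc.k_per_day * t))
    for day, gvs, params in info["feeds"]:
        tau = t - day
        mask = tau > 0
        pulse = np.zeros_like(t)
        pulse[mask] = gvs * gompertz_bmp(params, tau[mask])
        c = c + pulse
    return c


def _ph_track(dose: float) -> tuple[tuple[float, float], ...]:
    anchors = _PH_ANCHORS.get(dose, _PH_ANCHORS[8.0])
    days = np.arange(0.0, anchors[-1][0] + 1.0)
    xs = [a[0] for a in anchors]
    ys = [a[1] for a in anchors]
    return tuple(zip(days, np.interp(days, xs, ys)))


def generate(spec: SyntheticSpec) -> list[GasSeries]:
    """Generate the experiment: one :class:`GasSeries` per reactor.

    Reactors are ordered by ascending dose, replicates within dose.  With
    ``increment_noise_sigma_ml = 0`` and ``replicate_param_cv = 0`` the
    curves equal the deterministic forward model exactly.
    """
    t = spec.time_grid()
    truth = ground_truth(spec)
    series: list[GasSeries] = []
    for idx, (rid, info) in enumerate(truth.items()):
        rng = _reactor_rng(spec, idx)
        if spec.replicate_param_cv > 0:
            rng.normal(size=3)  # skip the jitter draws consumed by ground_truth
        clean = _noiseless_curve(spec, info, t)
        if spec.increment_noise_sigma_ml > 0:
            inc = np.diff(clean, prepend=0.0)
            inc = inc + rng.normal(0.0, spec.increment_noise_sigma_ml, size=inc.size)
            np.maximum(inc, 0.0, out=inc)  # a volumetric counter never runs backwards
            noisy = np.cumsum(inc)
        else:
            noisy = clean
        series.append(
            GasSeries(
                times=t,
                cumulative_ml=noisy,
                reactor_id=rid,
                biochar_dose_g_per_l=info["dose"],
                feed_events=tuple((d, g) for d, g, _ in info["feeds"]),
                ph_track=_ph_track(info["dose"]) if spec.include_ph else None,
            )
        )
    return series
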