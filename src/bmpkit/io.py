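"""Readers, writers, configuration and the end-to-end pipeline.

Series travel as plain CSV with columns ``time_days, reactor_id,
cumulative_ml`` plus a sidecar reactor table (``reactor_id,
dose_g_per_l, feed_day, vs_fed_g``, one row per feed event).  Experiment
configuration is TOML.  ``run_pipeline`` chains the stages: theoretical
potentials → depletion schedule → segmentation → per-g-VS normalization →
Gompertz/first-order fits on the isolated phase → ARIMA per reactor →
relative-increase matrices, and returns one JSON-serializable report.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinetics, phases, scheduler, stoichiometry, timeseries
from .phases import GasSeries

__all__ = [
    "SeriesFormatError",
    "MissingColumnError",
    "UnsortedTimeError",
    "DuplicateRowError",
    "ExperimentConfig",
    "read_series",
    "write_series",
    "read_config",
    "run_pipeline",
]

log = logging.getLogger("bmpkit")

REQUIRED_COLUMNS = ("time_days", "reactor_id", "cumulative_ml")


class SeriesFormatError(ValueError):
    """Base class for series-file validation failures."""


class MissingColumnError(SeriesFormatError):
    pass


class UnsortedTimeError(SeriesFormatError):
    pass


class DuplicateRowError(SeriesFormatError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    """Assay design + analysis options for the pipeline.

    ``compositions`` maps feedstock labels to their characterization;
    ``isr`` is the inoculum-to-substrate ratio on a VS basis.
    """

    compositions: Mapping[str, stoichiometry.ElementalComposition] = field(default_factory=dict)
    isr: float = 2.0
    reactor_volume_ml: float = 400.0
    doses_g_per_l: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    replicates: int = 3
    feed_days: tuple[float, ...] = (0.0, 8.0, 21.0, 44.0)
    feed_masses_gvs: tuple[float, ...] = (2.6, 2.6, 2.6, 2.6)
    horizon_days: float = 60.0
    inoculum_ubmy_ml: float = 3089.74
    inoculum_k_per_day: float = 0.13
    depletion_target: float = 0.99
    settle_days: float = 14.0
    molar_volume_ml: float = stoichiometry.MOLAR_VOLUME_STP_ML
    arima_grid: tuple[int, int, int] = (2, 1, 2)  # (p_max, d_max, q_max)
    rate_window_hr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isr <= 0:
            raise ValueError("ISR must be positive")
        if self.reactor_volume_ml <= 0:
            raise ValueError("reactor volume must be positive")


def read_series(path: str | Path, reactor_table: pd.DataFrame | None = None) -> list[GasSeries]:
    """Read cumulative series CSV into validated :class:`GasSeries`.

    ``reactor_table`` (columns ``reactor_id, dose_g_per_l, feed_day,
    vs_fed_g``) attaches doses and feed events.  Cumulative dips within
    the monotonicity tolerance (0.01 mL) are clamped and logged; larger
    dips are rejected with the offending row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")

    meta: dict[str, tuple[float, tuple[tuple[float, float], ...]]] = {}
    if reactor_table is not None:
        for rid, grp in reactor_table.groupby("reactor_id"):
            dose = float(grp["dose_g_per_l"].iloc[0])
            feeds = tuple(
                (float(r.feed_day), float(r.vs_fed_g))
                for r in grp.sort_values("feed_day").itertuples()
            )
            meta[str(rid)] = (dose, feeds)

    out = []
    for rid, grp in df.groupby("reactor_id", sort=True):
        t = grp["time_days"].to_numpy(dtype=float)
        dup = np.nonzero(np.diff(t) == 0)[0]
        if dup.size:
            row = grp.index[dup[0] + 1]
            raise DuplicateRowError(f"duplicate (reactor, time) at row {row} (reactor {rid})")
        bad = np.nonzero(np.diff(t) < 0)[0]
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise UnsortedTimeError(f"unsorted time at row {row} (reactor {rid})")
        c = grp["cumulative_ml"].to_numpy(dtype=float)
        dips = np.diff(c)
        small = (dips < 0) & (dips >= -phases.MONOTONE_TOLERANCE_ML)
        if small.any():
            log.info("reactor %s: clamped %d cumulative dips within tolerance", rid, small.sum())
            c = np.maximum.accumulate(c)
        dose, feeds = meta.get(str(rid), (0.0, ()))
        out.append(
            GasSeries(
                times=t,
                cumulative_ml=c,
                reactor_id=str(rid),
                biochar_dose_g_per_l=dose,
                feed_events=feeds,
            )
        )
    return out


def write_series(series: Sequence[GasSeries], path: str | Path) -> pd.DataFrame:
    """Write series to the standard CSV; returns the sidecar reactor table."""
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)
    rows = [
        {
            "reactor_id": s.reactor_id,
            "dose_g_per_l": s.biochar_dose_g_per_l,
            "feed_day": day,
            "vs_fed_g": gvs,
        }
        for s in series
        for day, gvs in s.feed_events
    ]
    return pd.DataFrame(rows)


def read_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from TOML.

    Feedstock tables live under ``[compositions.<label>]`` with keys
    matching :class:`~bmpkit.stoichiometry.ElementalComposition` fields;
    everything else sits under ``[design]`` and ``[analysis]``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    comps = {
        label: stoichiometry.ElementalComposition(label=label, **table)
        for label, table in raw.get("compositions", {}).items()
    }
    design = raw.get("design", {})
    analysis = raw.get("analysis", {})
    kwargs: dict = {}
    for src in (design, analysis):
        for key, val in src.items():
            kwargs[key] = tuple(val) if isinstance(val, list) else val
    return ExperimentConfig(compositions=comps, **kwargs)


def _diag_dict(d: kinetics.FitDiagnostics | None) -> dict | None:
    return dataclasses.asdict(d) if d is not None else None


def run_pipeline(
    config: ExperimentConfig,
    series: Sequence[GasSeries],
    run_arima: bool = True,
) -> dict:
    """Execute the full analysis chain and return a JSON-serializable report.

    Stages (each logged; a stage failure is reported under ``errors`` with
    the stage name, and partial results are preserved):

    1. theoretical potentials for every configured feedstock;
    2. depletion schedule check for the configured feed days;
    3. per-reactor segmentation at feed events and per-g-VS normalization;
    4. Gompertz + first-order fits on the isolated (final) phase;
    5. ARIMA order selection per reactor (grid from ``config.arima_grid``);
    6. relative-increase matrices on final-phase BMP and total BMY,
       averaged over replicates per dose.
    """
    report: dict = {"stages": [], "errors": {}}

    # 1 — stoichiometry
    try:
        stoich = {}
        for label, comp in config.compositions.items():
            res = stoichiometry.ultimate_potentials(
                comp, molar_volume_ml=config.molar_volume_ml, basis="vs"
            )
            stoich[label] = {
                "ubmp_ml_per_gvs": res.ubmp_ml_per_gvs,
                "biogas_ml_per_gvs": res.biogas_ml_per_gvs,
                "methane_fraction": res.methane_fraction,
                "warning": res.warning,
            }
        report["stoichiometry"] = stoich
        report["stages"].append("stoichiometry")
    except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
        report["errors"]["stoichiometry"] = str(exc)

    # 2 — schedule
    try:
        inoc = scheduler.FirstOrderModel(config.inoculum_ubmy_ml, config.inoculum_k_per_day)
        plan = scheduler.design_plan(
            inoc,
            target=config.depletion_target,
            settle_days=config.settle_days,
            horizon=config.horizon_days,
            feed_days=config.feed_days,
            feed_masses_gvs=config.feed_masses_gvs,
        )
        log.info("phase windows: %s; isolated phase %d", plan.phase_windows, plan.isolated_phase_index)
        report["schedule"] = {
            "depletion_day": plan.depletion_day,
            "phase_windows": [list(w) for w in plan.phase_windows],
            "isolated_phase_index": plan.isolated_phase_index,
        }
        report["stages"].append("schedule")
    except Exception as exc:  # noqa: BLE001
        report["errors"]["schedule"] = str(exc)
        plan = None

    # 3–5 — per reactor
    reactors: dict[str, dict] = {}
    per_dose_bmp: dict[float, list[float]] = {}
    per_dose_bmy: dict[float, list[float]] = {}
    for s in series:
        entry: dict = {"dose_g_per_l": s.biochar_dose_g_per_l, "final_bmy_ml": s.final_ml}
        try:
            if not s.feed_events:
                raise ValueError(f"reactor {s.reactor_id}: missing feed metadata")
            segs = phases.segment(s, horizon=config.horizon_days)
            entry["phase_final_ml"] = [p.final_ml for p in segs]
            iso = len(segs) - 1
            vs_fed = s.feed_events[iso][1]
            curve = phases.normalize_per_vs(segs[iso], vs_fed)
            tt = curve.index.to_numpy() - curve.index.to_numpy()[0]
            gp, gdiag = kinetics.fit_gompertz(tt, curve.to_numpy())
            fo = kinetics.fit_first_order(tt, curve.to_numpy())
            entry["gompertz"] = {
                "bbmp_ml_per_gvs": gp.bbmp,
                "rmax_ml_per_gvs_day": gp.rmax,
                "lag_days": gp.lag_days,
                "diagnostics": _diag_dict(gdiag),
            }
            entry["first_order"] = {
                "ubmy_ml_per_gvs": fo.params.ubmy_ml,
                "k_per_day": fo.params.k_per_day,
                "diagnostics": _diag_dict(fo.diagnostics),
            }
            per_dose_bmp.setdefault(s.biochar_dose_g_per_l, []).append(float(curve.iloc[-1]))
            per_dose_bmy.setdefault(s.biochar_dose_g_per_l, []).append(s.final_ml)
            if run_arima:
                p_max, d_max, q_max = config.arima_grid
                rep, _ = timeseries.select_order(
                    s.cumulative_ml, p_max=p_max, q_max=q_max, d_max=d_max
                )
                entry["arima"] = {
                    "order": rep.order.as_tuple(),
                    "train": _diag_dict(rep.train),
                    "validation": _diag_dict(rep.validation),
                    "prediction": _diag_dict(rep.prediction),
                    "n_train": rep.n_train,
                    "n_val": rep.n_val,
                    "n_test": rep.n_test,
                }
        except Exception as exc:  # noqa: BLE001
            report["errors"][f"reactor:{s.reactor_id}"] = str(exc)
        reactors[s.reactor_id] = entry
    report["reactors"] = reactors
    if reactors:
        report["stages"].append("reactors")

    # 6 — dose comparison on replicate means
    try:
        if len(per_dose_bmp) >= 2:
            bmp_means = {d: float(np.mean(v)) for d, v in per_dose_bmp.items()}
            bmy_means = {d: float(np.mean(v)) for d, v in per_dose_bmy.items()}
            ri_bmp = phases.relative_increase_matrix(bmp_means, basis="phase4_bmp")
            ri_bmy = phases.relative_increase_matrix(bmy_means, basis="total_bmy")
            report["relative_increase"] = {
                "phase4_bmp": ri_bmp.values.to_dict(),
                "total_bmy": ri_bmy.values.to_dict(),
            }
            report["stages"].append("relative_increase")
    except Exception as exc:  # noqa: BLE001
        report["errors"]["relative_increase"] = str(exc)

    return report


def mixture_theoretical_ubmy(
    config: ExperimentConfig,
    substrate_label: str,
    substrate_gvs: float,
    inoculum_label: str,
    inoculum_gvs: float | None = None,
) -> dict:
    """Theoretical uBMY chain for a substrate + inoculum mixture.

    If ``inoculum_gvs`` is omitted it follows from the ISR:
    inoculum VS = ISR × substrate VS.  Returns component and total uBMYs.
    """
    if inoculum_gvs is None:
        inoculum_gvs = config.isr * substrate_gvs
    parts = []
    for label, gvs in ((substrate_label, substrate_gvs), (inoculum_label, inoculum_gvs)):
        res = stoichiometry.ultimate_potentials(
            config.compositions[label], molar_volume_ml=config.molar_volume_ml, basis="vs"
        )
        parts.append(stoichiometry.ultimate_yield(res, gvs, source_label=label))
    return {
        "components": {p.source_label: p.ubmy_ml for p in parts},
        "total_ubmy_ml": stoichiometry.mixture_ubmy(parts),
    }
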