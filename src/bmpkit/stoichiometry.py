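"""Theoretical methane and biogas potentials from elemental composition.

The Buswell–Mueller balance converts an empirical CHONS formula of a
feedstock into stoichiometric CH4/CO2/NH3/H2S yields:

    CcHhOoNnSs + (c - h/4 - o/2 + 3n/4 + s/2) H2O ->
        (c/2 + h/8 - o/4 - 3n/8 - s/4) CH4
      + (c/2 - h/8 + o/4 + 3n/8 + s/4) CO2
      + n NH3 + s H2S

With the element shares expressed in mol per gram of volatile solids (VS),
multiplying the CH4 coefficient by a molar gas volume gives the ultimate
biomethane potential (uBMP, mL CH4/g-VS); CH4 + CO2 gives the biogas
potential.  The classic worked example: glucose C6H12O6 splits into
3 CH4 + 3 CO2, i.e. 6/180 mol gas per gram and 746.7 mL biogas/g-VS at
22.4 L/mol, half of it methane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "ATOMIC_MASSES_INTEGER",
    "ATOMIC_MASSES_IUPAC",
    "MOLAR_VOLUME_STP_ML",
    "ElementalComposition",
    "BuswellResult",
    "UltimateYield",
    "molar_shares",
    "shares_from_formula",
    "buswell_balance",
    "ultimate_potentials",
    "ultimate_yield",
    "mixture_ubmy",
]

#: Integer atomic masses (g/mol) — the convention that reproduces the
#: textbook glucose worked values.
ATOMIC_MASSES_INTEGER: dict[str, float] = {"C": 12.0, "H": 1.0, "O": 16.0, "N": 14.0, "S": 32.0}

#: IUPAC 2021 standard atomic weights, for users who want them.
ATOMIC_MASSES_IUPAC: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "S": 32.06,
}

#: Ideal-gas molar volume at 0 degC, 1 atm (mL/mol).
MOLAR_VOLUME_STP_ML: float = 22_400.0

_ELEMENTS = ("C", "H", "O", "N", "S")

#: Absolute tolerance (percentage points) for composition sum checks;
#: proximate/ultimate tables rarely sum exactly.
PCT_SUM_TOLERANCE: float = 0.5


@dataclass(frozen=True)
class ElementalComposition:
    """Proximate + ultimate characterization of a feedstock.

    All elemental percentages are mass % of total solids (TS), the usual
    reporting basis of CHNS analyzers.  ``vs_pct_ts`` is volatile solids as
    % of TS and converts per-TS potentials to a per-VS basis.
    """

    carbon_pct_ts: float
    hydrogen_pct_ts: float
    oxygen_pct_ts: float
    nitrogen_pct_ts: float = 0.0
    sulfur_pct_ts: float = 0.0
    vs_pct_ts: float = 100.0
    ts_pct: float = 100.0
    ash_pct_ts: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        pct_fields = {
            "carbon_pct_ts": self.carbon_pct_ts,
            "hydrogen_pct_ts": self.hydrogen_pct_ts,
            "oxygen_pct_ts": self.oxygen_pct_ts,
            "nitrogen_pct_ts": self.nitrogen_pct_ts,
            "sulfur_pct_ts": self.sulfur_pct_ts,
            "vs_pct_ts": self.vs_pct_ts,
            "ts_pct": self.ts_pct,
            "ash_pct_ts": self.ash_pct_ts,
        }
        for name, value in pct_fields.items():
            if not (0.0 <= value <= 100.0):
                raise ValueError(f"{name}={value!r} outside [0, 100]")
        if self.vs_pct_ts + self.ash_pct_ts > 100.0 + PCT_SUM_TOLERANCE:
            raise ValueError(
                f"VS + ash = {self.vs_pct_ts + self.ash_pct_ts:.2f} % TS exceeds 100"
            )
        elem_sum = (
            self.carbon_pct_ts
            + self.hydrogen_pct_ts
            + self.oxygen_pct_ts
            + self.nitrogen_pct_ts
            + self.sulfur_pct_ts
        )
        if elem_sum > 100.0 + PCT_SUM_TOLERANCE:
            raise ValueError(f"C+H+O+N+S = {elem_sum:.2f} % TS exceeds 100")

    @property
    def element_pcts(self) -> dict[str, float]:
        return {
            "C": self.carbon_pct_ts,
            "H": self.hydrogen_pct_ts,
            "O": self.oxygen_pct_ts,
            "N": self.nitrogen_pct_ts,
            "S": self.sulfur_pct_ts,
        }

    def with_oxygen_by_difference(self) -> "ElementalComposition":
        """Return a copy with O recomputed as 100 - C - H - N - S - ash."""
        o = 100.0 - (
            self.carbon_pct_ts
            + self.hydrogen_pct_ts
            + self.nitrogen_pct_ts
            + self.sulfur_pct_ts
            + self.ash_pct_ts
        )
        if o < 0:
            raise ValueError("oxygen by difference is negative")
        return replace(self, oxygen_pct_ts=o)


@dataclass(frozen=True)
class BuswellResult:
    """Balanced Buswell–Mueller coefficients and gas potentials.

    Coefficients are in the same per-unit basis as the element shares they
    were computed from (mol per formula unit, per g TS or per g VS).  A
    negative CH4 coefficient (over-oxidized substrate) is reported with a
    ``warning`` rather than raised, so screening arbitrary compositions can
    proceed.
    """

    water_coeff: float
    ch4_coeff: float
    co2_coeff: float
    nh3_coeff: float
    h2s_coeff: float
    ubmp_ml_per_gvs: float = math.nan
    biogas_ml_per_gvs: float = math.nan
    methane_fraction: float = math.nan
    molar_volume_ml: float = MOLAR_VOLUME_STP_ML
    warning: str | None = None


@dataclass(frozen=True)
class UltimateYield:
    """Absolute ultimate methane yield (uBMY) of a mass of substrate."""

    ubmy_ml: float
    mass_gvs: float
    source_label: str = ""


def molar_shares(
    comp: ElementalComposition,
    basis: str = "ts",
    atomic_masses: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Convert mass percentages to element shares in mol per gram.

    Parameters
    ----------
    comp
        Feedstock characterization; elemental values as % of TS.
    basis
        ``"ts"`` → mol per g of total solids; ``"vs"`` → mol per g of
        volatile solids (divides additionally by VS/TS).
    atomic_masses
        Mapping element → g/mol; defaults to integer masses.
    """
    if atomic_masses is None:
        atomic_masses = ATOMIC_MASSES_INTEGER
    basis = basis.lower()
    if basis not in ("ts", "vs"):
        raise ValueError(f"basis must be 'ts' or 'vs', got {basis!r}")
    if comp.carbon_pct_ts <= 0:
        raise ValueError("composition has no carbon; nothing to digest")
    if basis == "vs" and comp.vs_pct_ts <= 0:
        raise ValueError("per-VS basis requires vs_pct_ts > 0")
    scale = 1.0 if basis == "ts" else 100.0 / comp.vs_pct_ts
    return {
        el: comp.element_pcts[el] / 100.0 / atomic_masses[el] * scale for el in _ELEMENTS
    }


def shares_from_formula(
    formula: Mapping[str, float],
    atomic_masses: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Element shares (mol per gram) of a pure compound given atom counts.

    ``shares_from_formula({"C": 6, "H": 12, "O": 6})`` → glucose, C share
    6/180 mol/g with integer masses.
    """
    if atomic_masses is None:
        atomic_masses = ATOMIC_MASSES_INTEGER
    counts = {el: float(formula.get(el, 0.0)) for el in _ELEMENTS}
    if counts["C"] <= 0:
        raise ValueError("formula must contain carbon")
    mass = sum(counts[el] * atomic_masses[el] for el in _ELEMENTS)
    return {el: counts[el] / mass for el in _ELEMENTS}


def buswell_balance(
    shares: Mapping[str, float], include_ns: bool = True
) -> BuswellResult:
    """Balance the Buswell–Mueller reaction for the given element shares.

    ``shares`` maps C/H/O (and optionally N/S) to moles per chosen unit.
    With ``include_ns`` the full CHONS balance is used; otherwise N and S
    are ignored (the plain CHO form).  Coefficients come back in the same
    per-unit basis; gas volumes are left NaN (see :func:`ultimate_potentials`).
    """
    c = float(shares.get("C", 0.0))
    h = float(shares.get("H", 0.0))
    o = float(shares.get("O", 0.0))
    n = float(shares.get("N", 0.0)) if include_ns else 0.0
    s = float(shares.get("S", 0.0)) if include_ns else 0.0
    if c <= 0:
        raise ValueError("carbon share must be positive")

    water = c - h / 4.0 - o / 2.0 + 3.0 * n / 4.0 + s / 2.0
    ch4 = c / 2.0 + h / 8.0 - o / 4.0 - 3.0 * n / 8.0 - s / 4.0
    co2 = c / 2.0 - h / 8.0 + o / 4.0 + 3.0 * n / 8.0 + s / 4.0

    warning = None
    if ch4 < 0:
        warning = "negative CH4 coefficient: substrate is over-oxidized"
    total_gas = ch4 + co2
    methane_fraction = ch4 / total_gas if total_gas > 0 else math.nan
    return BuswellResult(
        water_coeff=water,
        ch4_coeff=ch4,
        co2_coeff=co2,
        nh3_coeff=n,
        h2s_coeff=s,
        methane_fraction=methane_fraction,
        warning=warning,
    )


def ultimate_potentials(
    comp: ElementalComposition | Mapping[str, float],
    molar_volume_ml: float = MOLAR_VOLUME_STP_ML,
    basis: str = "vs",
    include_ns: bool = True,
    atomic_masses: Mapping[str, float] | None = None,
) -> BuswellResult:
    """Ultimate methane (uBMP) and biogas potentials in mL per gram.

    ``comp`` is either an :class:`ElementalComposition` (converted to molar
    shares on ``basis``) or a ready mapping of element → mol per gram, e.g.
    from :func:`shares_from_formula`.

    >>> glc = shares_from_formula({"C": 6, "H": 12, "O": 6})
    >>> round(ultimate_potentials(glc).biogas_ml_per_gvs, 1)
    746.7
    """
    if isinstance(comp, ElementalComposition):
        shares = molar_shares(comp, basis=basis, atomic_masses=atomic_masses)
    else:
        shares = comp
    if molar_volume_ml <= 0:
        raise ValueError("molar volume must be positive")
    res = buswell_balance(shares, include_ns=include_ns)
    ubmp = res.ch4_coeff * molar_volume_ml
    biogas = (res.ch4_coeff + res.co2_coeff) * molar_volume_ml
    return replace(
        res,
        ubmp_ml_per_gvs=ubmp,
        biogas_ml_per_gvs=biogas,
        molar_volume_ml=molar_volume_ml,
    )


def ultimate_yield(
    result: BuswellResult | float, mass_gvs: float, source_label: str = ""
) -> UltimateYield:
    """Scale a per-g-VS potential to an absolute uBMY (mL CH4).

    Accepts either a :class:`BuswellResult` or a bare uBMP value in
    mL/g-VS, so printed literature potentials can be plugged in directly.
    """
    if mass_gvs < 0:
        raise ValueError("mass_gvs must be nonnegative")
    ubmp = result.ubmp_ml_per_gvs if isinstance(result, BuswellResult) else float(result)
    if math.isnan(ubmp):
        raise ValueError("result carries no uBMP (use ultimate_potentials)")
    return UltimateYield(ubmy_ml=ubmp * mass_gvs, mass_gvs=mass_gvs, source_label=source_label)


def mixture_ubmy(yields: list[UltimateYield]) -> float:
    """Total uBMY (mL CH4) of a mixture: the sum of component yields."""
    if not yields:
        raise ValueError("mixture_ubmy requires at least one component")
    return float(sum(y.ubmy_ml for y in yields))
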