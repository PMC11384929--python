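"""Theoretical gas potentials from elemental composition.

Applies the Buswell–Mueller balance to pure glucose and to a digestate
inoculum, then chains the per-g-VS potentials into the absolute ultimate
biomethane yield (uBMY) of the reactor mixture.
"""

from bmpkit.stoichiometry import (
    ElementalComposition,
    UltimateYield,
    mixture_ubmy,
    shares_from_formula,
    ultimate_potentials,
)

# --- pure glucose from its molecular formula -------------------------------
glc = ultimate_potentials(shares_from_formula({"C": 6, "H": 12, "O": 6}))
print(f"glucose biogas potential : {glc.biogas_ml_per_gvs:7.1f} mL/g-VS")
print(f"glucose uBMP             : {glc.ubmp_ml_per_gvs:7.1f} mL CH4/g-VS")
print(f"methane fraction         : {glc.methane_fraction:7.2f}")
# ~746.7 mL biogas per g VS, half of it methane: each mole of glucose
# splits into 3 CH4 + 3 CO2.

# --- an inoculum from its ultimate analysis (% of TS) ----------------------
inoc = ElementalComposition(
    carbon_pct_ts=36.76, hydrogen_pct_ts=5.00, oxygen_pct_ts=11.55,
    nitrogen_pct_ts=5.28, sulfur_pct_ts=1.85, vs_pct_ts=60.44,
    ash_pct_ts=39.56, label="inoculum",
)
res = ultimate_potentials(inoc, basis="vs")
print(f"inoculum uBMP (computed) : {res.ubmp_ml_per_gvs:7.1f} mL CH4/g-VS")

# --- absolute yield chain for a 2.6 g VS glucose + 5.2 g VS inoculum mix ---
# (printed literature potentials can be plugged in directly as floats)
parts = [
    UltimateYield(982.6, 2.6, "glucose"),
    UltimateYield(3089.74, 5.2, "inoculum"),
]
total = mixture_ubmy(parts)
print(f"mixture uBMY             : {total:7.1f} mL CH4")
# ~4072.3 mL: the stoichiometric ceiling the assay can approach, used to
# decide when the inoculum's contribution is exhausted.
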