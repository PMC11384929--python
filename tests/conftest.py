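import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from bmpkit.kinetics import GompertzParams
from bmpkit.stoichiometry import ElementalComposition
from bmpkit.synthetic import SyntheticSpec, generate

#: Printed 60-day cumulative methane yields (mL) per biochar dose (g/L).
BMY_60D_BY_DOSE = {0.0: 1036.06, 2.0: 2360.55, 4.0: 2439.96, 6.0: 2590.20, 8.0: 2676.92}

#: Printed final-phase cumulative BMP (mL/g-VS) per biochar dose (g/L).
BMP_PHASE4_BY_DOSE = {0.0: 135.06, 2.0: 229.76, 4.0: 302.56, 6.0: 334.71, 8.0: 390.33}


@pytest.fixture
def inoculum_composition():
    """Digestate inoculum characterization (ultimate analysis, % TS)."""
    return ElementalComposition(
        carbon_pct_ts=36.76,
        hydrogen_pct_ts=5.00,
        oxygen_pct_ts=11.55,
        nitrogen_pct_ts=5.28,
        sulfur_pct_ts=1.85,
        vs_pct_ts=60.44,
        ts_pct=4.01,
        ash_pct_ts=39.56,
        label="inoculum",
    )


@pytest.fixture
def dose8_params():
    """Final-phase Gompertz parameters of the highest (8 g/L) dose."""
    return GompertzParams(bbmp=394.16, rmax=90.97, lag_days=0.10)


@pytest.fixture(scope="session")
def small_experiment():
    """Scaled-down synthetic experiment: hourly grid, one replicate per dose."""
    spec = SyntheticSpec(seed=11, sample_interval_min=60, replicates=1)
    return spec, generate(spec)


@pytest.fixture(scope="session")
def clean_reactor():
    """A single noise-free, jitter-free reactor at the 8 g/L dose."""
    spec = SyntheticSpec(
        seed=0,
        doses=(8.0,),
        replicates=1,
        increment_noise_sigma_ml=0.0,
        replicate_param_cv=0.0,
    )
    return spec, generate(spec)[0]
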