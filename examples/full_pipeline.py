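"""The whole analysis chain on a synthetic multi-reactor experiment.

Generates a scaled-down assay (five doses, one replicate each, hourly
grid), writes/reads the standard CSV interchange files, and runs the
pipeline: stoichiometry -> schedule -> segmentation -> kinetics -> ARIMA
-> dose comparison.
"""

import tempfile
from pathlib import Path

import pandas as pd

from bmpkit.io import ExperimentConfig, read_series, run_pipeline, write_series
from bmpkit.synthetic import SyntheticSpec, generate

spec = SyntheticSpec(seed=11, sample_interval_min=60, replicates=1)
series = generate(spec)

with tempfile.TemporaryDirectory() as d:
    csv = Path(d) / "series.csv"
    reactors = write_series(series, csv)
    series = read_series(csv, reactors)  # round-trip through the CSV dialect

config = ExperimentConfig(arima_grid=(1, 1, 1))
report = run_pipeline(config, series)

print(f"stages completed: {report['stages']}; errors: {report['errors'] or 'none'}")
print(f"depletion day {report['schedule']['depletion_day']}, "
      f"isolated phase index {report['schedule']['isolated_phase_index']}")
print("\nreactor   dose   bBMP(mL/g-VS)  Rmax    lag(d)  ARIMA order")
for rid, e in report["reactors"].items():
    g = e["gompertz"]
    print(f"{rid:8s} {e['dose_g_per_l']:5.0f} {g['bbmp_ml_per_gvs']:12.1f} "
          f"{g['rmax_ml_per_gvs_day']:7.1f} {g['lag_days']:7.2f}   {tuple(e['arima']['order'])}")

ri = pd.DataFrame(report["relative_increase"]["phase4_bmp"])
print("\nfinal-phase relative increase (%) [column = high dose, row = low dose]:")
print(ri.round(2).fillna("").to_string())
# Plateaus rise with dose and the relative-increase matrix quantifies the
# separation between dose levels once the inoculum background is depleted.
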