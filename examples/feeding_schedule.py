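"""Designing a multi-feed assay that isolates the substrate-only phase.

Residual inoculum organics produce background methane with first-order
kinetics; the plan places the final feed after the background has decayed
to a target fraction, so the last phase reflects the substrate alone.
"""

from bmpkit.scheduler import FirstOrderModel, bmy_at, design_plan, time_to_fraction

inoculum = FirstOrderModel(ubmy_ml=3089.74, k_per_day=0.13)

real, whole = time_to_fraction(inoculum.k_per_day, 0.99)
print(f"99 % of inoculum uBMY reached after {real:.2f} d -> whole day {whole}")
# 35.42 d, reported conservatively as day 36.

plan = design_plan(
    inoculum, target=0.99, settle_days=14, horizon=60, feed_days=[0, 8, 21, 44]
)
print(f"phase windows            : {plan.phase_windows}")
print(f"isolated-substrate phase : window {plan.isolated_window}")
# The feed at day 44 is the first on/after depletion day 36 and its 16-day
# window exceeds the 14-day settling requirement.

print("\n day   cumulative BMY (mL)   fraction of uBMY")
for day in (0, 8, 21, 36, 44, 60):
    bmy = bmy_at(inoculum, day)
    print(f"{day:4d}   {bmy:12.1f}          {bmy / inoculum.ubmy_ml:8.4f}")
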