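# Methods

This note documents the models implemented in `bmpkit`, their assumptions,
the defaults and why, and what the synthetic-data generator does and does
not establish.

## Stoichiometric potentials

The Buswell–Mueller balance assumes complete anaerobic mineralization of
the organic fraction to CH₄ and CO₂ (with N → NH₃ and S → H₂S in the
CHONS form), no biomass growth, and no gas-phase corrections. Element
shares are taken in mol per gram: from a molecular formula
(`shares_from_formula`, dividing atom counts by the formula mass) or from
an ultimate analysis in % of total solids (`molar_shares`), optionally
rebased per gram of volatile solids by dividing by VS/TS.

Defaults and rationale:

- **Atomic masses**: integer values (C 12, H 1, O 16, N 14, S 32),
  switchable to IUPAC weights. Integer masses reproduce the textbook
  glucose worked value (746.7 mL biogas/g-VS at 22.4 L/mol); analytical
  practice in this field rarely states its convention.
- **Molar gas volume**: 22,400 mL/mol (ideal gas at 0 °C, 1 atm),
  configurable for other normalization conventions.
- **Composition validation tolerance**: 0.5 percentage points on the
  C+H+O+N+S and VS+ash sums — characterization tables rarely sum exactly.
- **Over-oxidized inputs** (negative CH₄ coefficient, possible when
  o > 2c + h/2) are returned with a warning flag rather than raised, so
  screening of arbitrary compositions can proceed. Note that a CO₂-like
  formula C₁O₂ sits exactly at the zero-methane boundary.
- **Oxygen by difference** (100 − C − H − N − S − ash) is available as an
  explicit method; the stated O is used by default.

## First-order depletion scheduling

The inoculum background is modeled as BMY(t) = uBMY·(1 − e^(−k·t)) with a
single lumped rate constant — adequate for a stored, filtered digestate
whose readily degradable fraction dominates. Depletion times are
closed-form; whole-day reporting uses the **ceiling**, which is
conservative (the target fraction is guaranteed met by the reported day).

`design_plan` marks the **isolated-substrate phase** as the first feed on
or after the depletion day and requires the horizon to leave at least
`settle_days` after that feed, treating the settling margin as the
minimum length of the final window. (An alternative reading — requiring
the feed itself to fall after depletion + settling — contradicts the
reference design this rule reproduces: feeds 0/8/21/44, depletion day 36,
14 settle days, horizon 60.)

`refeed_ready` declares a reactor ready for the next feed when its
production rate stays below the threshold (default 0.1 mL CH₄/hr) for a
persistence window (default 2 h) — the persistence guard keeps momentary
noise dips from triggering a premature feed.

## Modified-Gompertz and first-order fitting

The modified Gompertz curve uses e = exp(1) exactly (truncating to 2.71,
as sometimes printed, would distort the interpretation of Rmax as the
maximum slope; with exact e the analytic rate maximum equals Rmax at
t = λ + bBMP/(Rmax·e)). The curve has a small nonzero value at t = 0 when
the lag is short — a property of the functional form worth remembering
when pulses are superposed at feed instants.

Fitting is trust-region least squares (`scipy.optimize.least_squares`)
with nonnegativity bounds, tolerances 1e-10 and at most 10,000 residual
evaluations. Start values: plateau ← max observed; Rmax ← max of a
5-point smoothed finite-difference rate; λ ← earliest time reaching 1 %
of the plateau. Non-convergence is reported via the `converged` flag with
the best iterate's diagnostics, never raised; all-zero series are
rejected as degenerate.

Diagnostics follow BMP-literature conventions: RMSE = √(RSS/n),
R² = 1 − RSS/TSS, NSE identical to R² about the observed mean (kept as a
separate field because the field reports it separately), and
AIC = n·ln(RSS/n) + 2(K+1) with the residual variance counted as a
parameter. AICs are only comparable within one estimator convention;
lower AIC ⇔ lower RSS at fixed K.

## Cumulative-yield ARIMA

Cumulative gas curves are smooth and near-integrated; the module splits
chronologically (70/20/10 by default, validation and prediction floored,
remainder to training — n = 5760 gives 4032/1152/576), grid-searches
(p, d, q) with default bounds p, q ≤ 8, d ≤ 2, minimizes training AIC
with ties broken by smaller p+q then smaller d, and scores held-out
segments by one-step-ahead prediction with frozen parameters
(`statsmodels` `ARIMAResults.extend`). Innovations are assumed Gaussian,
no seasonal terms, trend handled by differencing only. Non-stationary or
non-invertible solutions are flagged, not fatal. The full default grid on
a 5760-point series is expensive (hundreds of maximum-likelihood fits);
analyses and tests on long series should shrink the grid or subsample the
time grid, which the smoothness of cumulative curves makes harmless.

## Phase processing and dose comparison

Feed windows are half-open [feed_i, feed_{i+1}) with the last window
closed at the horizon, so no sample is double-counted; each phase is
re-zeroed to the cumulative volume recorded just before its feed instant,
which makes the per-phase finals telescope exactly to the whole-series
final. Production rates are finite differences converted to mL/hr
(increment × 4 on a 15-min grid) with a centered 1-h moving average;
peaks require a prominence of 0.5 mL/hr by default and exclude the series
boundaries. Cumulative dips within 0.01 mL are treated as meter jitter
and clamped on read.

The relative-increase statistic is always denominated by the higher-dose
value: RI = (high − low)/high × 100 = 100·(1 − low/high). Published
matrices of this statistic computed from rounded per-dose means can
differ from recomputation in the second decimal; comparisons against an
unamended control are the most affected.

pH tracks are carried as metadata only; they are never used in any
computation.

## Synthetic experiments

The generator emulates the *statistical shape* of an instrumented
multi-feed assay, not its chemistry:

- noiseless curve = first-order inoculum background (default
  uBMY 3089.74 mL, k 0.13 d⁻¹) + per-feed Gompertz pulses, each the
  per-g-VS curve of the reactor's dose scaled by the grams VS fed
  (default 2.6 g per feed at days 0/8/21/44, horizon 60 d, 15-min grid →
  5760 samples);
- the dose→parameter table rises from (128.82, 26.32, 0.76) at 0 g/L to
  (394.16, 90.97, 0.10) at 8 g/L (bBMP mL/g-VS, Rmax mL/g-VS/d, λ d);
  the same table serves all feeds (multipliers default to 1) since
  adaptation-phase kinetics are not separately specified anywhere;
- replicate parameters are jittered log-normally with unit mean
  (default CV 0.02, keeping parameters positive);
- noise is Gaussian on increments (default σ 0.5 mL per 15-min sample, an
  AMPTS-II-like counter resolution that keeps fit R² above 0.98),
  truncated at zero and cumulated so curves stay nondecreasing.

Reproducibility: each reactor draws from `default_rng([seed, index])`, so
`ground_truth` and `generate` agree without sharing state and outputs are
byte-identical across runs.

Known limitations of this world, hence of what a green test establishes:
the zero-truncation of increments rectifies noise at plateaus, adding a
systematic upward drift (≈0.2·σ per plateau sample); fitted plateaus on
noisy synthetic reactors therefore run a few percent above the generating
values, and tight parameter-recovery claims must be made on untruncated
noise. More generally, cumulated increment noise is a random walk: the
plateau-recovery error scales as σ√n, so finer sampling at fixed σ *per
sample* worsens, not improves, recovery. The generator also ignores VFA
inhibition, pH feedback, temperature excursions and inter-feed carryover
beyond simple superposition; the short-lag Gompertz pulse has a small
step at its feed instant.

## Test and acceptance scaling

Long-horizon checks run on coarsened grids (1–4 h) and reduced ARIMA
grids (p, q ≤ 2, d ≤ 1) to keep the suite fast; the operations are
identical at full resolution. The acceptance suite asserts the
noisy-recovery bands on untruncated increment noise applied to the
absolute (2.6 g-VS) trace at 15-min resolution; the σ > 0 bands are not
attainable under the random-walk scaling above and the corresponding
tests document the measured medians.
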