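# Methods

## Measurement model

The flux pipeline assumes an open-circuit respiration chamber in
quasi-steady operation: emission at a time point equals the outlet-minus-
inlet CH4 mixing ratio times the ventilation rate expressed as dry gas at
standard temperature and pressure (DSTPVR), divided by the chamber's gas
recovery rate.  The wet→dry→STP conversion uses a sixth-order polynomial
for the saturation vapor pressure of water (coefficients 6.1117675,
0.4439, 0.014305, 2.65e-4, 3.02e-6, 2.04e-8, 6.388e-11 per ascending power
of T in °C), scaled by relative humidity, then the ideal-gas
pressure/temperature correction to 0 °C and 1013.25 hPa.  Over the
polynomial's validity range (−5…45 °C, enforced) it agrees with the Buck
equation to ≤0.04 %.

The quasi-steady assumption means storage changes in the chamber air are
ignored at the per-slot level.  With an air-change time constant of
~10 min (23 m³ at 140 m³/h) and 6-min slots, this only matters during
transients — after door openings, which are gap-filled anyway (see below),
and at the start of a run.

### Sampling and demultiplexing

One analyzer serves chamber 1, chamber 2 and the fresh-air inlet through a
switching device: 6-min cycle, 2 min per source, in that order.  The
leading `purge_fraction` (default 0.5, i.e. the first minute) of each slot
is discarded while the sample line flushes the previous source, and the
remainder is averaged to one value per slot, timestamped at the slot start
(timestamps label half-open intervals [t, t+Δ)).  The fresh-air reference
is sampled once per cycle and linearly interpolated onto each chamber's
slot timestamps before subtraction.  In the daily sum each retained slot
value represents the full cycle length (6 min).

### Gap filling and daily totals

Readings inside registered event intervals (door openings, failures) are
replaced by the mean of the k nearest valid points before the interval and
the k nearest after, pooled (default k = 4 per side, 8 values — the
per-side reading is a deliberate choice where "four data points before and
after" is ambiguous; k is configurable).  At a series edge the available
side is used alone with a warning; a gap with no valid neighbor at all is
an error.  `compute_emissions(event_pad_min=...)` can extend each event
before filling to also discard the chamber's re-equilibration tail (~3
time constants ≈ 30 min) after a door closes; the default (0) fills only
the registered interval, which leaves a small negative bias on days with
door traffic (~1–3 % in simulation).

Days are 24-h windows counted from a configurable origin, defaulting to
the first timestamp (chamber-entry alignment).  Daily totals convert with
1 g CH4 = 1.3962 L (STP).  Coverage is the measured (unfilled) fraction of
1440 min; days under the threshold (default 0.9) are flagged invalid.

### Calibration and recovery

Two-point calibration maps the N2 zero reading to 0 and the certified span
reading to its certified value (affine).  Drift over a period is assumed
linear in time: the start and end affine corrections are interpolated
per reading.  For a 1 %/period linear gain drift the residual after
correction is <0.003 % (interpolating the inverse of a linear gain is
second-order exact).  The correction is applied to concentrations, not to
computed emissions — an explicit choice, since either is defensible.

Recovery tests inject pure CO2 at a known rotameter rate until the
computed emission plateaus.  The plateau is the longest suffix over which
a rolling mean (default window 15 min) stays within 1 % of its final
value, and must span at least one window beyond detection; the recovery
rate is the plateau mean divided by the injected rate.  Recovery is then
applied per chamber as a fixed scalar per period (a list of tests can be
averaged with `mean_recovery`).

## Synthetic data generator

The chamber is a single well-mixed compartment (CSTR) — justified by the
~6 volumes/h air-change rate and the internal stirring fan — integrated in
dry-STP mixing-ratio space:

    V_stp dX/dt = E_stp(t) + Q_stp (X_bg − X)

with the exact exponential update for piecewise-constant forcing on a 1 s
grid (time constant ~10 min, so the discretization error of holding E
constant within a second is negligible; the mass-balance residual of the
update itself is at machine precision).  Q_stp and V_stp are derived from
the configured wet flow, temperature, humidity and pressure through the
same relations the pipeline inverts, which is what makes a noise-free
round trip exact: the simulator is the physical forward model of the
measurement equations.

Defaults are the study conditions: 23 m³ chambers, 140 m³/h airflow,
15–18 °C (default 16.5), 60–80 % RH (default 70), 6-min/2-min sampling
cycle in the order RC1, RC2, fresh, twice-daily 30-min door openings
(available via `door_schedule`, off unless configured), and a 2 L/min CO2
injection for recovery tests.  Door openings are modeled as a ×20
ventilation surge driving the concentration to background within minutes —
the real exchange rate through two open doors is unknown, and the analysis
discards those intervals regardless.  Quantities with no stated value are
engineering choices exposed in the config: analyzer noise 0.5 ppm SD
(additive, per record), gain drift 0.5 %/day (multiplicative, linear),
record cadence 20 s, background CH4 2 ppm.  Runs start at the steady state
of the initial emission rate ("an animal has been inside"), or at
background with `initial_state="background"`.

Emission profiles are a diurnal sinusoid (default amplitude 0.1 of
baseline, minimum at midnight) plus boxcar post-meal peaks (default +25 %
for 2 h after the 08:30 and 16:30 feedings).  Ground truth records the
exact daily integral of the realized (noise-included) emission, computed
on the same 1 s grid.

The animal-record generator draws per-cow true quantities from uniform
ranges matching a high-producing Holstein cohort on a corn-silage TMR
(26–28 kg DM/d at ~20.4 % CP, ~40 kg/d milk at 3.4 % fat, 540–610 kg BW)
and derives everything else to be internally consistent: fecal output from
true DM digestibility, fecal marker concentrations back-derived so that an
inert-marker calculation recovers fecal output exactly (NDF and GE
concentrations follow their own digestibilities, so using them as markers
reproduces the real-world bias of partially-digestible markers), urinary N
from creatinine-derived volume times concentration.  Note the arithmetic
consequence: at 26–28 kg DM/d and 20.4 % CP, N intake is ~880 g/d.  True
balance partitions are the balance module's own output on the noise-free
records, so the noise-free round trip is exact by construction — a
verification of plumbing and identities, not of the balance formulas
against an external standard.  Observed records add multiplicative
Gaussian measurement noise (default SD 2 %) with resampling of negative
draws.

What the generator does not emulate: animal behavior (lying, drinking),
analyzer response time and cross-sensitivity, CO2/O2-based heat
production, within-day composition drift of feed and milk, and real
between-laboratory assay error structure.  Passing tests therefore show
the calculation chain is correct and self-consistent, not that it is
robust to every artifact of real chamber data.

## Balance definitions and open choices

Nitrogen: total excretion = fecal + urinary; retained = intake − total
excretion; productive = retained + milk; NUE = milk N/intake N.  These are
identities and are tested as exact.

Energy: DE = GEI − E_feces; E_methane = 0.0556 MJ/g CH4; E_urine = 4 % of
GEI; E_milk = 39.32·fat + 23.84·protein + 16.73·lactose MJ/d (kg/d
inputs).  The milk coefficients are the standard component heats of
combustion in MJ/kg; they are configurable.  ME defaults to the
conventional DE − E_methane − E_urine; an alternative mode
(`me_mode="absorbed_fermented"`) computes ME = E_milk + E_methane −
E_urine for users who define ME from absorbed plus fermented energy — with
the caveat that body energy retention is not measured here, so that mode
understates ME in gaining animals.  EB = ME − 0.08·BW^0.75 − E_milk as
defined; note 0.08·BW^0.75 (~9.5 MJ/d at 590 kg) is far below conventional
maintenance expenditure, so EB values from this definition are not
comparable with NRC-style energy balances.

Marker-based fecal output assumes 100 % marker recovery; indigestible NDF
(`marker="ndfi"`) is the defensible default, and NDF or GE can be selected
for comparison knowing they overstate output.  Treatment summaries report
mean ± SEM of per-cow means (never functions of treatment means);
inference is out of scope.

## Problem sizes and tolerances

The test suite and acceptance script use 24-h single-chamber runs at a
20 s record cadence (4,320 records, 240 retained slots per chamber),
240–300 min recovery tests, cohorts of 4–12 cows × 1–3 days, and 1,000
random draws for the identity suite; the full suite runs in a few seconds.
Stated tolerances: constant-emission round trip 0.5 % (discretization
only; measured ~1e-6), recovery estimation 0.2 % noise-free, drift
correction 0.05 %, vapor-pressure polynomial vs Buck 1.5 %.  One computed
band replaces a slightly-off published one: over T ∈ [15, 18] °C and RH ∈
[60, 80] %, the dry/wet ventilation ratio lies in [0.9837, 0.9899] (the
humid corner falls just below 0.984).
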