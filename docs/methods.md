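# Methods

## The box model

The cabin is modelled as a single well-mixed compartment of volume
*V* [m³] exchanging air with the outdoors at a first-order rate
λ [h⁻¹] while its occupants add CO₂ at a constant volumetric rate
expressed as a concentration rise rate *K*gen [ppm/h]:

    dC/dt = K_gen − λ (C − C₀)

with *C₀* the outdoor baseline (~400 ppm).  The closed-form solution

    C(t) = C₀ + (K_gen/λ)(1 − e^{−λt}) + C_i e^{−λt}

(where *C*ᵢ is the concentration above baseline at *t* = 0) is the single
primitive everything else is built on: the forward simulator applies it
piecewise over intervals of constant (λ, *K*gen), the calibration stage
fits it to measured growth segments, and the threshold-crossing times of
the air-quality predictions invert it analytically.  At λ = 0 the exact
linear limit *C₀* + *K*gen·t + *C*ᵢ is used; near zero, `expm1` keeps the
general branch continuous with that limit to machine precision, verified
against brute-force numeric integration of the mass balance (agreement
within 0.01 ppm over random parameter draws, and 0.1 ppm across a full
multi-cycle controller run).

Assumptions inherited from the model: instantaneous perfect mixing (no
spatial gradients), constant outdoor baseline, generation independent of
the CO₂ level, and a single effective exchange rate per ventilation
state.

## Metabolic conversion chain

A fitted *K*gen converts to the occupant's volumetric CO₂ production at
standard temperature, pressure, dry (STPD):

    VCO₂ [mL/min] = K_gen·10⁻⁶ · V[mL] · CF_STPD / 60
    CF_STPD = ((P_bar − P_H₂O)/760) · (273/(T + 273))

and then to energy expenditure through the Weir equation of indirect
calorimetry,

    EE [kcal/day] = 1.44 (3.941·VCO₂/RQ + 1.11·VCO₂),

whose coefficient at the mixed-diet respiratory quotient RQ = 0.85 is
8.27492 kcal/day per mL/min — the value usually printed rounded as
8.273.  The package always computes the coefficient from the full
equation rather than hard-coding the rounded constant, so EE↔VCO₂ and
*K*gen↔VCO₂ round-trip to 10⁻⁹ relative.  When measured conditions are
available, P_H₂O is derived from the trace's mean temperature and
relative humidity via the Magnus saturation-pressure approximation
(within 1% of tabulated values over 0–50 °C); in pure simulations the
ambient defaults to the STPD reference so CF = 1.

## Calibration

Parked (0 MPH) recordings have negligible leakage, so CO₂ rises linearly
and *K*gen is the ordinary least-squares slope of CO₂ against time, with
the usual slope standard error (validated against a Monte-Carlo SD over
200 synthetic traces).  With *K*gen known, each at-speed growth segment
is fitted by bounded nonlinear least squares for (λ, *C*ᵢ) with the
baseline fixed: initialisation λ₀ = 1 h⁻¹ and *C*ᵢ₀ = first reading −
baseline, bounds λ ∈ [0, 50] h⁻¹, and a restart schedule
λ₀ ∈ {1, 0.1, 0.5, 2, 5, 10} of which the lowest-SSR converged fit wins.
A fit ending at the λ = 0 bound is annotated "negligible exchange".
R² is 1 − SS_res/SS_tot about the trace mean, clipped to [0, 1].

Fixing *K*gen matters: on a short (≤10 min) low-λ segment the growth and
exchange terms are nearly collinear, and freeing *K*gen inflates SE(λ)
by about a factor of 4 (the design's variance-inflation factor, which
approaches 4 as λT → 0).  The joint fit is exposed for diagnostics only.

Per-speed λ estimates feed a piecewise λ(speed) model: an OLS line for
speeds above a threshold (default 17.5 MPH, splitting the 17-vs-18 MPH
ambiguity in how the two regimes are reported; configurable), and a
constant negligible floor of 0.05 h⁻¹ at or below it.  Line predictions
are clipped from below at the floor so fitted coefficients can never
produce a negative rate near the threshold.  Continuity at the threshold
is deliberately not imposed — the two regimes are physically distinct
(static leakage vs motion-induced pressure differential).  Mean driving
speed over a cycle is the time-weighted (trapezoidal) mean of the
possibly irregular speed log.

## Energy expenditure from intermittent recirculation

Under the intermittent protocol the recirculation (RC) mode holds until
cabin CO₂ reaches a trigger (~1100 ppm), then a fixed-length purge
(default 5 min) vents the cabin, and the cycle repeats.  Each RC-on
growth interval is one estimation unit:

1. **Segmentation.** With a known RC schedule, cycles are the RC-on
   intervals with the first 15 s discarded as a mixing transient
   (configurable).  Without one, a detector finds local minima→maxima
   runs on a 30 s centered moving average (sensor noise is fast against
   the 5–12 min cycle scale), filtered by prominence (100 ppm), minimum
   duration (120 s) and net growth (50 ppm).
2. **Per-cycle fit.** λ is *fixed* from the λ(speed) model at the
   cycle's mean speed; the solution is then linear in (*K*gen, *C*ᵢ),
   so the fit is exact linear least squares — no optimizer, no starting
   values.  *C*ᵢ is re-estimated per cycle because purges do not return
   fully to baseline; the baseline itself is the session's outdoor
   reading (default 400 ppm).
3. **Aggregation.** Per-cycle EE values (Weir at RQ = 0.85 by default)
   are summarised as mean, sample SD (n−1) and CV%.  A single cycle
   yields NaN SD/CV (undefined, not zero).  Multi-occupant sessions
   report total EE divided by the occupant count, flagged as a
   per-occupant average: individual EE is not identifiable from one
   shared cabin.

## Forward simulator

A `Scenario` holds cabin, ambient, occupant list (generation scales
linearly with occupancy), and exactly one of an explicit λ or a driving
speed mapped through the λ(speed) model.  Open-loop runs evaluate the
closed form on a regular grid (default 1 s, mirroring the sensor).
Closed-loop runs alternate growth at the RC-on λ with purges at the
RC-off λ (default 22 h⁻¹, the top of the swept range — the purge rate is
not separately measured; configurable): the switch fires at the first
sample at or above the trigger, bounding overshoot by one time step of
growth, and the cycle boundaries are annotated for direct reuse by the
metabolic pipeline.  `time_to_threshold` inverts the closed form,
returning infinity when the steady state *C₀* + *K*gen/λ never reaches
the threshold.

Default simulation conditions: 3.1 m³ cabin (the stated spec-sheet
volume, not the 3.115 m³ implied by 110 ft³), 400 ppm baseline,
λ = 1 h⁻¹, EE = 1700 kcal/day per occupant, RQ = 0.85, CF = 1.  Under
these, a lone driver crosses 1000 ppm in 9.8 min; sweeping EE gives
6.5 min (2500 kcal/day) and 13.2 min (1300 kcal/day) to 1000 ppm and
26.7 min to 2500 ppm for the high-EE driver.  Published figures for the
EE sweep are ~4% longer (6.8 / 13.7 min); the rounding convention behind
them (volume, correction factor) is unstated, so both volume and CF are
exposed as parameters.

## Synthetic data generator

The generator stands in for real drive recordings: it runs the simulator
and corrupts the output with additive Gaussian noise (default SD 15 ppm —
plausible scatter for a consumer NDIR sensor against the ~600 ppm cycle
amplitude), optional linear drift (default 0, available to stress-test
fitting bias), and quantization to 1 ppm (integer sensor output).  Speed
logs are a stationary AR(1) fluctuation (coefficient 0.9, marginal SD
3 MPH) around the nominal speed, clipped at zero; a parked log is
identically zero.  Everything is reproducible from (parameters, seed),
and each artifact ships a ground-truth record sufficient to compute
expected pipeline outputs analytically.

What the generator does *not* emulate — and hence what green tests do
not establish about field data: exhaust-intrusion spikes from nearby
traffic, sensor drift/recalibration over months, humidity-dependent
sensor response, imperfect mixing after an RC switch beyond the fixed
settling margin, and within-trip metabolic drift.  Recovery results on
synthetic sessions are therefore statements about estimator correctness
under the model, not about sensor hardware.

## Numerical and design notes

- Units: hours and ppm internally; volume m³ at the interface (mL inside
  the VCO₂ conversion); VCO₂ mL/min; EE kcal/day — the units every
  governing equation is written in.
- Readings above the 3000 ppm calibrated sensor span are flagged, never
  rejected.
- Degenerate inputs: empty cycle lists are legal segmentation output;
  aggregation of zero cycles raises; a constant trace fits *K*gen = 0
  with R² defined as 1 when total variance is zero.
- Problem sizes in the shipped tests (session counts, seed counts per
  grid point, trace durations) were chosen as the smallest giving stable
  Monte-Carlo statements: 100 seeds per λ grid point for 2·SE coverage,
  200 traces for the SE-vs-Monte-Carlo check, 4–5 sessions for the
  end-to-end envelope.

## Known limitations

- Wind speed and outdoor CO₂ variability are not covariates of λ.
- The λ(speed) model is vehicle-specific; coefficients shipped as
  defaults describe one closed-window mid-size sedan.
- EE estimation assumes a metabolically stable, seated occupant; it is
  an average over a growth cycle, not an instantaneous rate.
- The controller model is idealised (sharp trigger, fixed purge length,
  two discrete λ states).
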