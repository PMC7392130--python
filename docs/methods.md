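# Methods

## Scope and data model

The pipeline consumes a `WaveformRecording`: distal coronary pressure
(mmHg) and Doppler flow velocity (cm/s) on a uniform grid (≥ 50 Hz),
plus protocol annotations (vasodilator boluses, balloon-ramp interval,
rest windows).  Flow velocity is used as the flow surrogate throughout,
on the usual assumption that vasomotor diameter changes occur in the
microcirculation downstream of the sensor so velocity and volumetric
flow change proportionally.  All indices are computed on *beat means*:
the mean of a signal over one foot-to-foot cardiac cycle.

## Beat segmentation

Beats are delimited at the diastolic feet of the **pressure** trace:
local pressure minima with prominence at least
`max(0.25 × peak-to-peak, 1 mmHg)`, separated by a refractory period of
`0.6 × (60 / expected_rate)` s.  Pressure rather than velocity is the
gating signal because pressure pulsatility persists during balloon
inflation while velocity pulsatility collapses on the ischemic limb;
the refractory factor suppresses dicrotic-notch double counts.  A
constant trace has no feet and yields an empty series.  ECG gating and
arrhythmia/artifact rejection are out of scope.  Window membership is
whole-containment: a beat belongs to `[start, end]` iff it starts at or
after `start`, starts before `end`, and ends at or before `end`.

## Hyperemia indices

* baseline flow = mean beat velocity of the **last 5** beats wholly
  before the bolus onset (the window closest to the event, least
  affected by slow drift);
* hyperemic flow = maximal mean over all windows of 3 consecutive
  post-bolus beats, searched within 60 s of onset (configurable) and
  capped at the next annotated event so replicates never overlap; ties
  resolve to the earliest window;
* hyperemic pressure = mean beat pressure over the same 3-beat window;
* `CFR = F_hyp / F_base`; `HMR = P_hyp / F_hyp`;
* classification uses strict inequalities (CFR > 3.0 normal, < 2.0
  pathological, boundaries intermediate).

Replicates of one drug are reported individually and aggregated as the
arithmetic mean of per-replicate indices (mean of ratios, not ratio of
means — the two differ, and the per-measurement average is the
convention for repeated clinical index measurements).

## Autoregulation breakpoint

Beat coordinates inside the ramp window are pooled into half-open
5-mmHg pressure bins `[k·w, (k+1)·w)` anchored at multiples of the bin
width; each non-empty bin contributes its members' mean pressure (the
regression abscissa — the curve averages *coordinates*, not bin
centers), mean flow, and count.  For every contiguous split of the
ascending bins into a low segment (ischemic relation) and a high
segment (plateau), each with ≥ 3 bins, both segments are fitted by
ordinary least squares, unweighted by default (count-weighted fits are
available as an option).

**Split selection.**  The selected pair of lines is the best-fitted
one in the pooled sense: minimal total residual sum of squares across
both segments, reported as the global two-segment
R² `= 1 − SSE/SST` (`score`).  Selecting instead by the *sum of the two
per-segment R² values* is unstable here: the autoregulatory plateau is
nearly flat, so its per-segment variance is noise-dominated and its own
R² is essentially random; under realistic beat noise that criterion
frequently prefers splits that lump the knee into the "plateau",
producing wildly out-of-range intersections.  The pooled-residual
criterion compares all splits on one scale, reduces to the same answer
in the noise-free case (both per-segment R² = 1, zero residual), and in
the Monte-Carlo study below recovers the breakpoint with sub-mmHg
median error.  Ties resolve to the lower split index.

The **breakpoint** is the intersection of the two selected lines;
parallel lines (|slope difference| ≤ 1e-9) are an error.  An
intersection outside the observed bin-pressure range is reported with
`in_range = false` plus a warning rather than rejected, since no
validity rule is part of the procedure.  The minimum segment size of 3
exists because a 2-point line has R² = 1 vacuously.  A zero-variance
ordinate with zero residual is scored R² = 1 (a perfect flat plateau is
an exactly explained line).  Degenerate inputs (fewer than 6 bins,
identical abscissas) raise errors naming the shortfall.

## Synthetic generator

The generator separates pulsatility from physiology:

* **Intra-beat template.**  Pressure: half-sinusoid systole (first 35%
  of the cycle) truncated at a dicrotic notch, exponential diastolic
  run-off (time constant 0.18 cycle); scaled so foot-to-peak equals
  `pulse_pressure` and the closed-form cycle mean is zero.  Velocity: a
  systolic dip of depth `velocity_pulsatility` (coronary inflow is
  diastolic-dominant) normalized to unit cycle mean.  Downstream
  analysis consumes beat means only, so these shapes affect results
  only through sub-0.5% template-averaging residue.
* **Hyperemia.**  Velocity envelope
  `F_base × (1 + (gain−1)·g(t))` with a gamma-variate
  `g(t) = (t/tp)^α exp(α(1−t/tp))`, `α = tp/τ`, peaking at 1 at
  `tp = 8 s` and relaxing with `τ = 15 s`; mean pressure dips by
  `hyperemic_pressure_drop × g(t)` (resistance collapse lowers distal
  pressure).  Writing the dip in terms of `g` keeps gain = 1 (a blank
  bolus) well-defined.
* **Balloon ramp.**  Mean pressure declines linearly from 89 to
  25 mmHg over 180 s (a stepwise mode with 5-mmHg steps and 20 s dwell
  is provided for fidelity checks); each beat's velocity is the
  steady-state autoregulation model evaluated at that beat's (noisy)
  pressure: a near-flat plateau
  (`slope 0.02 (cm/s)/mmHg`) above the breakpoint and a straight
  ischemic limb through a zero-flow pressure of 10 mmHg below it,
  continuous at the knot and clipped at zero.  The zero-flow pressure
  and plateau slope are modelling choices constrained only by
  physiological plausibility (positive intercept well below the
  breakpoint; slightly positive plateau).
* **Noise.**  Independent per-beat Gaussian perturbations of beat-mean
  velocity (SD 1.5 cm/s) and pressure (SD 2 mmHg) — beat level is the
  scale at which the analysis operates, so that is where noise belongs.
* **Protocol.**  Rest (30 s), 3 adenosine + 3 bradykinin boluses (60 s
  each, onset at 15 s so every replicate carries its own
  return-to-baseline window), then the ramp.  Segment noise streams are
  spawned from a single seed: the annotation schedule is
  deterministic, and identical config + seed reproduces the recording
  bit for bit.

Default values (85 bpm, 89 mmHg mean pressure, 19.1 cm/s baseline
velocity, gain 3.0, ≈ 61 mmHg hyperemic pressure, 49 mmHg breakpoint)
describe a healthy adolescent pig under balanced anesthesia; pulse
pressure defaults to 40 mmHg, a typical arterial excursion consistent
with that mean.

### What the generator does *not* emulate

Respiratory and autonomic variability, drift, ectopy and arrhythmia,
catheter artifacts, drug pharmacokinetics beyond the velocity envelope,
systemic hemodynamics, and vasospasm.  Passing tests therefore
demonstrate the correctness and statistical behaviour of the *analysis
rules* under controlled conditions, not robustness to every failure
mode of real catheter-lab signals.

## Verification strategy and problem sizes

* Closed-form hand examples and brute-force oracles for every beat
  rule and regression step (window search by enumeration, OLS by
  normal equations and against an independent library implementation,
  split selection by exhaustive enumeration on random data).
* Exactness in the noise-free limit: two-line data with the knot at a
  bin boundary recover the knot with zero error and both R² = 1.
* Monte-Carlo recovery at the default study conditions: 100 ramps
  with true breakpoints uniform on 42–55 mmHg (median absolute error
  ≈ 0.9 mmHg, all estimates in range), and 33 boluses per gain in
  {2.0, 2.5, 3.0} (mean CFR bias < 0.05).  These sizes keep the whole
  suite and the acceptance script in the seconds range while leaving
  Monte-Carlo standard errors well below the tolerances tested.

## Known limitations

* Foot detection assumes a recognizable diastolic foot; pathological
  waveforms (severe damping, pulsus alternans) are not handled.
* The breakpoint estimator assumes a single knee inside the observed
  pressure range; sigmoid fits, the upper autoregulation limit, and
  inflation/deflation hysteresis are out of scope.
* Unweighted bin regression ignores unequal bin occupancy; the
  count-weighted option exists but is off by default to match the
  pooled-and-averaged curve convention.
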