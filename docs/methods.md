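# Methods

This note documents the models inside `nirsbf`: what is simulated, how the
signal processing recovers the cerebral signal and heart rate, how the
training game is specified, and where the package makes choices that the
underlying method leaves open.

## Subject physiology (`nirsbf.hemodynamics`)

A simulated trainee is a `SubjectModel`. Hemoglobin concentrations are
*changes* relative to rest, in arbitrary µM-equivalent units: with a single
810 nm isosbestic wavelength only total hemoglobin is resolvable and
absolute quantitation is not attempted, so the unit scale is free and all
downstream mathematics is invariant to it.

- **Cortical response.** The cerebral concentration deviation follows
  first-order relaxation toward an effort-dependent set-point,
  `dc/dt = (g·u − c)/τ`, with gain `g = brain_response_gain` (default 1.0
  units), time constant `τ = response_time_constant` (default 5 s, the
  timescale of a slow hemodynamic response), and effort `u ∈ [−1, 1]`
  (`raise` = +1, `lower` = −1, `rest` = 0). The discrete update is the
  exact exponential integrator, so a step of effort reproduces
  `g·(1 − e^{−t/τ})` to machine precision at the sample times.
- **Heart rate.** Same first-order law toward
  `baseline_hr + hr_response_gain·u` (defaults 70 and 12 beats/min — a
  voluntary sustained change of ~12 beats/min is at the upper end of what
  slow-breathing/arousal strategies achieve), plus an Ornstein–Uhlenbeck
  fluctuation with stationary SD `hr_variability_sd` (default 2 beats/min,
  correlation time 10 s). The rate is clamped to the 48–180 /min pulse
  standard, so simulated inter-beat intervals always respect the device's
  validity range.
- **Beats.** Cardiac phase is integrated continuously
  (`dφ/dt = hr/60`); a beat time is the interpolated integer crossing, so
  beats are *not* grid-locked and at constant rate `h` the spacing is
  exactly `60/h` s.
- **Skin compartment.** `c_skin` is the sum of a Mayer-wave sinusoid
  (0.1 Hz), a respiratory sinusoid (0.25 Hz, half amplitude) with
  subject-seeded phases, and an OU drift; overall amplitude
  `skin_fluctuation_amp` (default 0.2 units). It is independent of effort —
  which is exactly why it must be regressed out.

## Optics (`render_optics`)

The forward model is the Beer–Lambert attenuation of each channel:

    I_1cm = I0_1cm · exp(−ε · c_skin_total · l_1cm)
    I_3cm = I0_3cm · exp(−ε · (c_skin_total · l_skin_3cm + c_brain · l_brain_3cm))

Defaults: ε = 1, l_1cm = 1, l_skin_3cm = 1.2, l_brain_3cm = 0.8, unit
source intensities. In these arbitrary units the rest-calibration slope has
the known true value α = l_skin_3cm / l_1cm = 1.2, which the tests check.

Cardiac pulsation is added to the skin compartment before attenuation:
`pulse_amp · w(φ)`, where the waveform `w` is zero at the beat onset and
approaches it with finite slope on both sides — the sharp pulse "foot"
where the diastolic descent meets the systolic upstroke. The amplitude
default (0.3 units, 1.5× the slow skin fluctuation) makes the cardiac
component the dominant within-beat feature of the short channel, which is
the premise of reading heart rate off that channel at all. Because the
pulse rides on the skin compartment with the same path lengths, the
short-separation regression removes it from the cerebral estimate exactly.

Sensor noise is multiplicative log-normal on intensity with relative SD
`noise_sd` (default 0.5 %); positivity of intensities is guaranteed by
construction. The stated noiseless model is exactly invertible
(`invert_intensities`), which the tests use as an independent oracle.

Sampling is 10 Hz by default (the device rate) but configurable — 10 Hz
barely resolves 180 beats/min, and some tests use a finer grid.

## Skin removal (`nirsbf.processing`)

`x` and `y` are baseline-referenced optical densities of the 1 cm and 3 cm
channels (reference = mean intensity over the first 10 s unless explicit
reference intensities are given — a constant reference only shifts x and y
and is absorbed by the intercept). `calibrate_rest` fits `y = αx + β` by
OLS on the rest window (default first 30 s; ≥ 10 samples and non-zero
variance in x required), reporting R². `extract_brain` rescales the
residual:

    ĉ_brain(t) = (y(t) − α·x(t) − β) / (ε · l_brain_3cm)

Subtracting β means the estimate is the cerebral change *relative to the
rest window* — the natural zero of a ΔHb system. Calibration is per run
(per subject and session start), not pooled across subjects.

`cbf_feedback_signal` optionally smooths the estimate with a centred moving
average spanning `smooth_beats` current inter-beat intervals (cardiac-cycle
smoothing). This is the package's documented surrogate for the device's
display-side combination of the optical signal with HR, whose exact form is
not specified; `smooth_beats = 0` (the default) is the identity.

## Pulse detection (`nirsbf.pulse`)

The beat fiducial is the pulse minimum: sample *j* is a candidate when it
is the **strict** minimum of the five most recent samples, read as the
centred window {j−2 … j+2}, giving the detector an exact two-sample
latency. Strictness (rather than ≤) breaks ties on flat or constant
signals. Candidates whose interval from the last accepted beat falls
outside [60/180, 60/48] s are discarded; the previously accepted beat and
displayed rate are retained, and the beat clock is *not* advanced by a
rejected candidate. HR per accepted beat i > 0 is `60/(t_i − t_{i−1})`
(beats/min; `1/(t_i − t_{i−1})` per second); the first beat carries no
value.

Two consequences are worth knowing:

- **Quantization.** On a 10 Hz grid, detected intervals are multiples of
  0.1 s, so single-beat rates near 79 /min read as 75.0 or 85.7 /min. The
  one-sample bound on the rate error is `h²/(60·fs)`. The closed-loop game
  therefore displays an interval-averaged rate over the last 8 accepted
  beats, which collapses the quantization scatter by the window length.
- **Lock-in.** Because rejection never advances the clock, a missed beat
  at low rates (where `2×IBI` exceeds the 1.25 s ceiling) stalls the
  detector until a candidate happens to land inside the window. This is a
  faithful consequence of the retention rule as stated; the simulator's
  sharp pulse foot keeps misses rare, but the hazard is intrinsic to the
  rule and is visible in the rejected counts at 48–60 beats/min.

## The game (`nirsbf.game`)

Constants: 120-s sets, 10 sets/day, 15-s continuous retention, 10-s advice
trigger, all configurable via `RunConfig` but defaulting to the protocol
values. Timers are held as sample counts so the retention threshold is
exact on the grid; a set in which the cue is in band from the first sample
achieves at exactly t = 15.0 s.

- **Band.** Centred at `baseline + offset` (above for "increase"
  instructions, below for "decrease"); width
  `base_width · 0.9^(level−1)`, floored at 0.3 · base_width so high levels
  remain playable. CBF defaults: offset 0.6, base width 0.5 units —
  reaching the band requires a sustained effort of ~60 % of the maximal
  cortical response, so it is genuinely unreachable by noise alone. HR
  defaults: offset 8, base width 10 beats/min against a maximal voluntary
  change of 12.
- **Score.** Success: `((remaining + 15) + (maintain − 15)·0.5)/120·100`;
  failure: `(maintain·0.5)/120·100`; clamped to [0, 100]. The success
  formula is parenthesized so that the half weight applies to the in-band
  time *beyond* the required 15 s: instant success then scores exactly
  100, matching the stated perfect-score behaviour, whereas the
  alternative literal reading would give 106.25. `maintain` counts all
  in-band time during the set, not only the final run. Failure scores are
  algebraically below 50.
- **Level.** `level = ⌊avg/10⌋ + 1` over the last 100 set scores, capped
  at 10; fewer than 100 sets counts as an average of 0 (level 1). Reaching
  the band within the first 10 s suppresses the advice message only; the
  persistent level comes solely from the rolling average.
- **Closed loop** (`run_session`). Each day: a 30-s rest calibrates the
  regression and fixes the cue baseline (CBF: mean extracted signal; HR:
  interval-averaged rest rate), then 10 sets run with 5-s inter-set rests.
  Effort is updated once per second — a human reaction time — as
  feedforward toward the band centre plus a proportional correction of the
  latest cue error and small motor noise; with probability
  `1 − control_skill` the update lapses to rest. Physiology, optics,
  extraction and the set state machine all advance at `fs` between effort
  updates. Everything is driven by three child RNG streams spawned from
  (session seed, subject seed), so runs are bit-reproducible.

## What the generator does and does not emulate

The synthetic subject reproduces the features the method depends on:
separate skin and cortical compartments with the skin common to both
channels, pulsation confined to the skin, first-order voluntary control,
heart-rate variability, and sensor noise. It does **not** emulate motion
artifacts, probe-coupling drifts, heterogeneous path lengths across
subjects, fatigue or learning within a session, or any neurovascular
detail beyond the first-order response. Passing tests therefore
demonstrate the internal consistency and correct implementation of the
processing and game rules under the stated model — not clinical efficacy,
and not robustness to artifact classes the generator omits.

## Numerical choices and degenerate inputs

- OLS via `numpy.polyfit`; a rest window with < 10 samples or zero
  variance in x raises rather than fitting a degenerate line.
- The exponential-integrator updates make the simulator exact for
  piecewise-constant effort; no ODE solver tolerance is involved.
- Strict minima mean constant signals yield no candidates; signals shorter
  than 5 samples yield an empty result with a warning.
- Problem sizes used by the test and acceptance suites are desk-scale by
  design: 60–150 s simulations at 10 Hz, sessions of 10 × ≤ 120 s sets,
  and a 9-skill × 20-seed sweep (~180 sessions, a few seconds of compute).

## Known limitations

- The interval-rejection rule's lock-in at low heart rates (above).
- 10 Hz sampling quantizes single-beat rates coarsely; the displayed rate
  is averaged over beats to compensate, but instantaneous per-beat values
  retain the grid scatter.
- Concentrations are relative; comparisons across subjects or sessions in
  absolute units are out of scope by construction.
- The device's exact on-screen combination of optical signal and HR is not
  public; the cardiac-cycle smoothing here is a surrogate and is flagged
  as such wherever it appears.
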