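# Methods

## Model

The HCL model couples three processes:

1. **Sleep homeostat.** Sleep pressure `H` relaxes exponentially with time
   constant `chi` (45 h) towards the asymptote `mu` during wake and
   towards 0 during sleep. Because the rise rate during wake is
   `(mu - H)/chi`, `mu` controls sleep duration: a larger `mu` means
   faster pressure build-up, earlier threshold crossing, and (because the
   nightly fall must balance the daily rise on a periodic solution) longer
   sleep. On any entrained periodic solution the ratio of the mean rise
   rate to the mean fall rate equals sleep/wake duration exactly — 1/2 for
   8 h sleep / 16 h wake — since the net change of `H` over a period is
   zero.
2. **Switching thresholds.** Wake→sleep at `H = H0bar + Delta/2 + ca*C`,
   sleep→wake at `H = H0bar - Delta/2 + ca*C`. The circadian amplitude
   `ca` (default 1.72) is large relative to the threshold gap `Delta` (1),
   so timing is dominated by the circadian modulation; near the maximum of
   `C` the upper threshold can exceed `mu` unless
   `mu > ca + H0bar + Delta/2`, which is the model's physiological
   admissibility condition (without it there are circadian phases at which
   spontaneous sleep onset is impossible no matter how long the person has
   been awake — a hard "wake-maintenance zone").
3. **Light-forced pacemaker.** A weakly nonlinear van der Pol oscillator
   `(x, y)` with time scale `kappa = 24*3600/(2*pi)` s — the hour-based
   Kronauer pacemaker rewritten in seconds — forced by a photic drive
   built from a saturating photoreceptor pool `n`. The photoreceptor
   kinetics use `alpha0 = 0.16/60 s^-1` and `beta = 0.013/60 s^-1`; the
   dimensionless drive `Bhat = G * (60*alpha0) * (I/I0)^p * (1-n)` uses
   the activation rate on the per-minute scale on which the gain
   `G = 19.9` is defined (on the per-second scale the drive would be 60×
   too weak to entrain the oscillator, which contradicts every documented
   behaviour of this parameter set). Sleep gates light: `I_tilde =
   (1-S)*I`. The phase of the pacemaker is the unwrapped angle
   `atan2(y, x)`, which increases by `2*pi` per cycle; `y` plays the role
   of the circadian activity variable, with its minimum at the circadian
   (core body temperature) minimum.

### Period correction factor `f`

`f` is defined so that the unforced oscillator has period exactly `tauc`.
`calibrate_f` root-finds it from limit-cycle zero crossings (20 transient
cycles discarded, 10 averaged, DOP853 at rtol 1e-11; period reproducible
to < 1e-6 h). For `tauc = 24.2 h`, `gamma = 0.23` the exact root is
0.9966765; the shipped default keeps the conventional printed value
0.99669, which equals the first-order van der Pol asymptotic
`1 - gamma^2/16` and puts the unforced period 1.2 s above 24.2 h — an
entirely negligible difference for simulation, but the distinction matters
when verifying `calibrate_f` to five decimals.

## Calibration of the wake-propensity waveform

The coefficients of the quadratic form `C(x, y)` are not free parameters:
they are produced by `hclsleep.calibration.calibrate_defaults` and frozen
in `hclsleep.defaults`. The procedure is:

1. Entrain the free-running (`S = 0`) light-circadian subsystem to the
   default two-level profile and sample one day of the cycle `(x(t),
   y(t))`.
2. Fit the quadratic form by least squares to an asymmetric wake-propensity
   template — a time-warped cosine with its maximum in the late evening
   and its minimum 6.75 h later in the second half of the night, the shape
   of the circadian wakefulness drive measured in forced-desynchrony
   protocols.
3. Alternate (a) root-finding the template's phase offset so that the full
   model with all-default parameters converges to a mean mid-sleep of
   03:16 under the default profile, and (b) rescaling/recentring the
   coefficients so that `C` over the converged entrained cycle has
   peak-to-peak amplitude exactly 2 and zero mean. The loop is a
   contraction and stops when both hold to 0.02.

Two remarks. First, the quadratic form in the near-sinusoidal `(x, y)`
cycle can carry only the fundamental and second harmonic, so the fitted
`C` is a smoothed version of the asymmetric template: its maximum lands in
the mid-evening (~18:40 on the default entrained cycle, several hours
before sleep onset at ~23:30) rather than immediately before bedtime,
while the minimum (~03:50) falls squarely in the second half of the night.
Second, the daytime level of the default profile is not independently
known; it was fixed once at 2000 lux because that value makes the
calibrated model reproduce three documented behaviours simultaneously —
mid-sleep 03:16 at 40 lux evening light, a delay of ~1 h when evening
light rises from 10 to 40 lux (we obtain 1.02 h), and loss of entrainment
just above `tauc = 24.3 h` at 40 lux evening light (we obtain 24.37 h).
Dawn is 06:00, dusk 18:00 (equinox photoperiod), with logistic transitions
of 30 min width.

## Simulation

The four ODEs are integrated with scipy's LSODA (stiff-capable) at
relative and absolute tolerances 1e-4, with `max_step` 1800 s so threshold
crossings cannot be stepped over; switching instants are located by the
solver's event machinery (sign change + root polish), and the state at the
located root seeds the next segment. Recorded light is linearly
interpolated between its minute samples; synthetic profiles are evaluated
from a 1-min lookup table. Default initial conditions are `H = H0bar`,
`n = 0`, and `(x, y)` on the unforced limit cycle at the phase where `C`
crosses its mean downwards (between the evening maximum and the late-night
minimum — the cycle's subjective midnight); transients are then removed by
`simulate_to_convergence`, which repeats integer-day passes of the light
record, chaining the final state into the next pass, until mean sleep
duration and mean mid-sleep change by under 1 min between passes (50
passes maximum).

**Entrainment** is declared when the convergence loop has converged and
the regression slope of mid-sleep clock deviation against day number over
the final 7 days is below 5 min/day, with no multi-day gaps. The slope
criterion (rather than consecutive-night differences) is deliberate:
day-to-day light jitter produces several minutes of night-to-night
mid-sleep variation on perfectly entrained solutions. Non-convergence is a
reported state (`entrained=False`), not an exception. Clock-time
statistics (onset, offset, mid-sleep) are computed in the noon-anchored
window [12, 36) so that times either side of midnight average correctly;
mid-sleep differences in the fit residual are taken on the shortest arc.

## Fitting

`fit_mu_tauc` alternates two bracketed 1-D root solves: `mu` against mean
duration, then `tauc` against mean mid-sleep, each using expansion from
the current value followed by safeguarded regula falsi (Illinois) on
stored endpoint values. Endpoint values are never re-evaluated because
evaluations are warm-started (the previous converged state seeds the next
convergence run, cutting passes per evaluation from ~8 to 2–3) and a
re-evaluation near the entrainment edge could return a slightly different
value. Loss of entrainment inside the `tauc` bracket is mapped to "very
late mid-sleep", shrinking the bracket from above. The component
tolerances (0.012 h on duration, 0.018 h on mid-sleep) combine to below
the 0.03 h (< 2 min) residual threshold; bounds are `mu` in
`[H0bar + Delta/2 + 0.5, 30]` and `tauc` in `[23.5, 24.6]`, and an
unreachable target (no sign change within bounds) raises a descriptive
error. `fit_mu_ca` minimises the squared residual over `(mu, ca)` by
Nelder–Mead with one perturbed restart; non-entrained or degenerate
evaluations receive a large penalty, and results are flagged
non-converged (residual ≥ 0.03 h) or non-physiological rather than
raising, since amplitude saturation genuinely prevents late-enough sleep
timing for some light patterns.

## Light metrics

The five standard metrics are computed per day window (midnight-anchored
by default; a 04:00 anchor is available for late-sleeping populations):
hours with lux > 500; mean lux; geometric mean `10^mean(log10(lux+1))`;
and the clock times at which the piecewise-linear cumulative curves of lux
and of `log10(lux+1)` reach half their daily total (continuous time, not
snapped to samples).

The biological-effect metric integrates the `S = 0` light-circadian
subsystem for exactly 24 h from a fixed reference state — the pacemaker
state at midnight of an entrained reference person with mid-sleep 04:30
and sleep duration 8.22 h under the default profile, obtained by fitting
`(mu, tauc)` to those targets and frozen in `hclsleep.defaults` — and
returns `(cycles - 1) * 1440` minutes, where `cycles` is the unwrapped
phase advance over `2*pi`. `S = 0` throughout is intentional: the metric
scores the light pattern itself, not its interaction with a particular
sleep schedule, and the same reference state is used for every day and
every participant so values are comparable across both. An all-dark day
scores ≈ `(24/24.2 - 1)*1440 = -11.9` min (small spread from the
non-uniform angular velocity around the limit cycle); integration uses
rtol 1e-7 so the metric is stable to ±0.5 min under 0.1 % light changes.

## Synthetic participants

The generator emulates the structure of a 7–14-day field recording:
minute-resolution lux built from the two-level profile with one log-normal
intensity multiplier per day (sigma 0.3), 1–3 zero-dropout runs of
10–60 min per day during model-wake (exercising wake-zero imputation,
which replaces each wake zero by the median of all raw samples within
±30 min of clock time pooled across days), and a diary whose nights are
the model's converged sleep episodes perturbed by Gaussian noise. The
noise magnitudes default to the values observed in older adults in the
field — mid-sleep SD 0:34 h:mm and duration SD 1.01 h — and are applied to
mid-sleep and duration independently (equivalent to correlated
onset/offset noise; independent onset/offset noise cannot reproduce both
SDs at once, since it forces the duration SD to be twice the mid-sleep
SD). All randomness descends from a single seed via spawned
sub-sequences. Cohorts draw `mu` uniformly from [17, 19] and `tauc` from a
clipped normal with SD 0.135 h (the width of fitted-period
distributions); the cohort template uses the 10-lux evening level, which
keeps the whole `tauc` range inside the entrainment region and away from
the steep near-edge response of the 40-lux template.

What passing tests on these fixtures do show: the estimator recovers known
parameters through the full pipeline (generation → dropout → imputation →
fitting) and the statistics layer behaves correctly on data with known
variance components. What they do not show: performance on real sensor
artefacts (saturation, wear-time gaps, position-dependent attenuation),
deterministic-model limits on night-to-night variability (the model's
intrinsic night-to-night SD is ~0.1 h, far below the behavioural 0.5–1 h,
so diary noise is additive by construction), or the cohort-specific
correlation structure of any real population.

## Statistics

ICC uses the REML random-intercept fit (statsmodels MixedLM), with a
one-way ANOVA method-of-moments fallback (negative between-participant
components truncated at zero) for degenerate or non-converging cases.
Spearman p-values use the t approximation for n ≥ 10 and an exact
permutation null below; family-wise significance uses Benjamini–Hochberg
step-up at FDR 5 %. The mid-sleep general linear model is OLS of
noon-anchored mid-sleep on the biological effect of light (hours) and
`tauc - 24.2`, reporting the small-sample adjusted R².

## Problem sizes and numerical choices

Default convergence runs use 7-day passes for periodic profiles and the
integer-day-truncated record for measured light; the recovery suite uses
10 noise-free participants of 7 days each; the entrainment boundary is
bisected to ±0.005 h. The acceptance script's three quantities are
deterministic; the `--seed` argument pins any incidental randomness.
Degenerate inputs are defined errors: empty days, all-zero imputation
windows (value left at 0, logged), non-overlapping intervention windows
(warned no-op), empty episode lists, and targets outside the achievable
range.

## Known limitations

- The wake-propensity coefficients are a calibrated reconstruction, not
  measured values; any coefficient set with the same entrained waveform
  phase and amplitude is observationally equivalent in this pipeline, and
  the quadratic form cannot place its maximum immediately before sleep
  onset (see above).
- The model is deterministic: it reproduces average sleep timing and
  duration, not night-to-night variability.
- Lux is used as the light input; melanopic weighting is out of scope.
- Naps, imposed wake schedules ("wake effort") and social constraints are
  not modelled; the simulator produces exactly one threshold-driven sleep
  episode per circadian cycle under ordinary parameters.
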