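# Methods

This note records the models, numerical choices and open design
decisions behind `ftcdlat`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the synthetic cohort does
and does not establish about real recordings.

## Signal model of the simulator

Each simulated channel is a multiplicative composition

    V(t) = V0 · (1 + m(t)/100) · c(t) + V0 · σ · ε(t)

with `V0` the subject's baseline velocity (uniform in 45–65 cm/s per
channel), `c(t)` the pulsatile cardiac carrier (unit mean), `m(t)` the
task-locked hemodynamic modulation in percent, `σ` the noise standard
deviation as a fraction of baseline (default 3 %), and `ε` white
standard normal noise. Multiplicative composition makes the pipeline's
percent normalization exact in expectation: the cycle mean of `V` is
`V0 · (1 + m/100)` whenever `m` varies slowly within a cycle.

**Cardiac carrier.** Within each cycle the shape is a piecewise raised
cosine: a systolic upstroke over the first quarter of the cycle and a
slower diastolic decay over the remaining three quarters. Each
half-cosine segment averages 0.5 over its support, so the cycle mean
equals the baseline exactly, independent of the rise fraction; the
peak-to-trough swing is `pulsatility_fraction` (default 0.5) of the
baseline. A pure sinusoid would make systole/diastole indistinguishable
and cycle detection degenerate; the asymmetric shape gives the detector
real work. Heart rate (uniform 55–85 bpm per subject) drifts
sinusoidally by ±5 % with a 120 s period within each session, so cycle
lengths are not constant. Physiologically the carrier omits respiratory
modulation and CO₂ reactivity; it is a carrier for the slow hemodynamics,
not a cardiovascular model.

**Hemodynamic response.** The per-epoch response in percent is zero
before onset, a half-raised-cosine ramp from 0 to the peak amplitude at
`hrf_peak_delay_s` (default 6 s), then a Gaussian settle (scale
`hrf_width_s`, default 4 s) from the peak to a sustained plateau of
`hrf_plateau_fraction` (default 0.8) of the peak, and a Gaussian return
to baseline after the target interval ends. This shape was chosen over a
kernel-convolution construction because it pins the peak time and peak
value exactly — properties the recovery tests rely on — while keeping
the phenomenology of task-evoked CBFV responses: onset ramp, peak at
5–7 s, sustained elevation for the rest of the interval. An optional
small bilateral initial dip (`initial_dip_pct`, off by default) can be
added; it is presentation-layer phenomenology, not part of the method.

**Lateralization trait.** Per task, the left/right response amplitudes
are `effect ± trait/2`, so the injected left-minus-right amplitude is
`(effect_left − effect_right) + trait`. The trait for the first task is
`s·z` and for the second `s·(ρ·z + √(1−ρ²)·e)` with `z, e` independent
standard normals per subject, `s = trait_sd_pct` (default 2.5 %) and
`ρ = trait_cross_task_correlation` (default 0.75), so the population
correlation of the injected amplitudes equals `ρ` by construction and
reaches ±1 exactly at the endpoints. Default task effects are
word generation left/right 5/2 % (left-dominant, true ΔV +3 %) and
knapping 2/6 % (right-dominant, true ΔV −4 %), chosen once to emulate a
cohort in which the language task lateralizes left by roughly +2.5 % in
the sustained window and the manual task lateralizes right by a
comparable amount.

**Artifacts.** Square velocity pulses with random sign, amplitude 60 %
of baseline, duration uniform in 1.2–2.0 s, injected per target epoch
with probability 0.05, on one randomly chosen channel. The lower
duration bound exceeds the longest physiological cardiac cycle the
simulator can produce (≈1.15 s), so at least one full cycle lies inside
every pulse and the pulse survives cycle-mean integration at full
amplitude — guaranteeing it trips the ±30 % rejection rule. Shorter
pulses can be diluted below threshold by cycle averaging, which is why
the duration floor is not lower.

**Event schedule.** Control/target intervals strictly alternate,
starting and ending with a control, targets uniform in 25–35 s and
controls in 15–25 s, 20 targets per session by default; every target
thus has a full 5 s pre-onset baseline inside a control interval.

## Preprocessing choices

- **Detection channel.** Cycle boundaries are detected on the left
  channel and applied to both: the two arteries share one heart, and
  identical integration windows are implicitly assumed by the later
  left-minus-right subtraction. Peaks are found with a 0.3 s minimum
  spacing (200 bpm) and a prominence floor of one quarter of the robust
  (5th–95th percentile) signal range; boundaries are the velocity minima
  between successive peaks.
- **Cycle validity.** Detected cycles outside 0.3–2.0 s (200–30 bpm) —
  typically spurious peaks or merged cycles around large artifacts — are
  flagged invalid and skipped by the integration stage rather than
  failing the session; fewer than five valid cycles raises a
  no-cardiac-signal error.
- **Integration method.** Per-cycle means are placed at cycle midpoints,
  linearly interpolated between midpoints, and held constant outside the
  first/last midpoint. The resampling scheme is not standardized in the
  fTCD literature; linear interpolation of cycle means is the simplest
  scheme that is exact for locally linear velocity trends.
- **Epoch window.** [−5, +25] s around target onset: covers the 5 s
  baseline and the longest analysis extents used downstream (the 2–18 s
  LI window and moving windows out to [15, 20) s) with margin.
- **Artifact rule scope.** The ±30 % test applies to baseline-normalized
  dV over the full epoch window including the baseline span, both
  channels, strict inequality (a sample at exactly 30 % is kept).
  Whether the original instrumentation applied the rule to raw or
  normalized velocity, and over which sub-window, is not documented;
  this package's convention is fixed here.
- **QC boundary.** A subject is excluded only when some condition has
  *strictly fewer* than 80 % good epochs; exactly 16/20 is retained.
- **Filtering.** Averaging precedes filtering (the filter is applied to
  the epoch-averaged trace). The filter is an order-2 Butterworth
  low-pass at 1 Hz applied forward and backward; two passes give unit DC
  gain and amplitude 1/2 at the cutoff. Edges are handled by 5 s of
  reflective padding plus Gustafsson initial conditions, which make the
  forward-backward and backward-forward results identical, so
  time-reversal symmetry holds to machine precision on the short epoch
  traces.

## Lateralization and group statistics

- **LI integration.** The LI is the *integral* (trapezoidal) mean of ΔV
  over the 2 s window centred at the peak, not the arithmetic mean of
  the grid samples: the defining quantity is a time integral, and the
  trapezoid rule evaluates it exactly for piecewise-linear traces while
  agreeing with the sample mean to O(Δt²) for smooth ones. Ties at the
  peak go to the earliest sample; when the peak lies within 1 s of the
  trace edge the window is clipped to the trace rather than shifted,
  preserving "centred at the peak" as nearly as possible.
- **Moving windows.** Window means are arithmetic means over the
  half-open sample interval [start, start + 5 s), evaluated at start
  offsets from −5 to +15 s in steps of one sample (0.04 s). Correlation
  p-values use the t transform with n − 2 degrees of freedom, two-sided,
  uncorrected across window offsets — deliberately matching the
  uncorrected-threshold convention of the moving-window display, and
  therefore anticonservative if read as a family of tests. Windows with
  zero between-subject variance yield missing (NaN) correlations, never
  zero.
- **Critical r.** `critical_r(n, α) = t/√(n−2+t²)` with `t` the
  two-sided α quantile of Student's t with n − 2 df; at n = 10, α = 0.05
  this is 0.632.

## What the synthetic cohort does and does not show

The simulator provides exact ground truth (injected amplitudes, trait
correlation, artifact placement), so passing tests establish that the
chain recovers what was injected: percent normalization is scale-free,
noise-free recovery of injected responses is within 2 % absolute and of
injected LIs within 10 % relative, injected cross-task correlations are
recovered by the moving-window statistic, and the null rejection rate at
the uncorrected threshold is consistent with its nominal 5 % level
(verified against the exact null distribution of Pearson's r).
It does *not* establish performance under real-world failure modes the
generator omits: probe displacement and slow drift, respiratory and
vasomotor oscillations, arrhythmia, asymmetric insonation quality
between probes, or hemodynamic response shapes that differ between
hemispheres or across epochs. Results on real recordings depend on those
factors; the package's contribution there is that every processing rule
(rejection threshold, QC fraction, filter, windows) is explicit and
configurable.

## Problem sizes and runtime

Default sessions are ≈1000 s at 25 Hz (~25,000 samples, ~1100 cardiac
cycles) and preprocess in ~20 ms each. The statistical calibration tests
use 100 replicate 10-subject cohorts for correlation recovery and 400
for type-I calibration — the 400 keeps the binomial Monte-Carlo error of
the estimated rejection rate (~0.011) well inside the ±0.02 band being
checked. The full test suite runs in about five minutes on one CPU; the
acceptance script simulates and analyses one 10-subject cohort in a few
seconds.
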