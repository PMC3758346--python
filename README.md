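# ftcdlat

Functional transcranial Doppler (fTCD) lateralization analysis in Python:
from raw bilateral cerebral blood-flow-velocity (CBFV) envelopes to
epoch-averaged hemodynamic responses, lateralization indices, and
cross-task moving-window correlations — together with a synthetic
bilateral-CBFV cohort simulator with known ground truth.

## The problem

Dual-probe fTCD measures blood flow velocity in the left and right
middle cerebral arteries (MCAs) at 25 Hz while a subject alternates
between *target* intervals (performing a task, 25–35 s) and *control*
intervals (matched baseline activity, 15–25 s), typically 20 target
epochs per block. Because each MCA supplies most of one hemisphere's
lateral cortex, a task that engages one hemisphere more than the other
produces a small, reliable left–right velocity asymmetry. fTCD tolerates
vigorous subject motion, which makes it one of very few techniques able
to image cerebral lateralization during physically active tasks and to
compare it, within the same subjects, against the clinical-standard cued
word generation language task.

The analysis chain is standard in the fTCD literature:

1. **Cardiac cycle integration.** Each channel is reduced to per-cycle
   mean velocities (cycle boundaries detected at systolic onsets on the
   left channel and applied to both) and interpolated back onto the
   25 Hz grid, removing pulsatility while preserving slow hemodynamics.
2. **Epoch segmentation and normalization.** Each target onset yields a
   [−5, +25] s epoch. With V_b the mean velocity over the 5 s preceding
   the onset, each channel becomes a percent change
   dV(t) = 100 · (V(t) − V_b) / V_b.
3. **Artifact screening.** Epochs with physiologically implausible
   changes (|dV| > 30 % on either channel) are rejected; subjects with
   fewer than 80 % good epochs in any condition are excluded.
4. **Averaging and filtering.** Good epochs are averaged pointwise and
   the averages are low-pass filtered with a second-order zero-phase
   (forward–backward) Butterworth filter, cutoff 1 Hz.
5. **Lateralization.** ΔV(t) is the left-minus-right difference of the
   averaged traces. The lateralization index LI is the mean of ΔV over a
   t_int = 2 s window centred at the time t_max of peak |ΔV| within an
   activation window (default 2–18 s after onset); LI > 0 indicates
   left-hemisphere dominance.
6. **Group analysis.** Mean ΔV traces with SEM bands; Pearson
   correlation of the two tasks' LIs across subjects; and the Pearson
   correlation, across subjects, of the two tasks' ΔV means over a
   moving 5 s window whose start slides from −5 to +15 s relative to
   onset, against the uncorrected two-sided threshold
   r_crit = t_crit / √(n − 2 + t²crit).

Because bilateral fTCD recordings of this kind are rarely shared, the
package includes a first-class simulator (`ftcdlat.synthetic`): a
pulsatile cardiac carrier (asymmetric systolic/diastolic shape, slow
heart-rate drift) on a subject-specific baseline, task-locked
hemodynamic responses whose left-minus-right amplitude carries a
subject-level lateralization trait shared between two tasks with
configurable correlation, white measurement noise, and occasional large
square-pulse artifacts. The simulator returns the injected ground truth
so every downstream estimator can be validated against it.

## Worked example

```python
import numpy as np
from ftcdlat import (SimulationConfig, simulate_cohort, preprocess_session,
                     delta_v, lateralization_index, li_correlation, critical_r)

config = SimulationConfig(n_subjects=10, seed=1)
sessions, truth = simulate_cohort(config)

li = {}
for session in sessions:
    epochs, response = preprocess_session(session)
    res = lateralization_index(delta_v(response))
    li[(session.subject_id, session.task_label)] = res

subjects = sorted({s for s, _ in li})
word = np.array([li[(s, "word_generation")].li_pct for s in subjects])
knap = np.array([li[(s, "knapping")].li_pct for s in subjects])
corr = li_correlation(word, knap)
print(f"cross-task LI correlation: r = {corr.r:.3f}, p = {corr.p:.4f} (n = {corr.n})")
print(f"uncorrected threshold at n = 10: |r| > {critical_r(10, 0.05):.3f}")
```

prints

```
cross-task LI correlation: r = 0.734, p = 0.0156 (n = 10)
uncorrected threshold at n = 10: |r| > 0.632
```

For the first simulated subject the two sessions give
`word_generation LI = +1.37 %` (peak |ΔV| at 15.36 s, 18/20 good epochs)
and `knapping LI = −4.86 %` (peak at 6.80 s, 17/20 good epochs): this
subject lateralizes language to the left and the manual task to the
right, while the cohort-level correlation shows that subjects with
stronger left-lateralized language also shift further toward the left
(relative to the task mean) during the second task — the signature of a
shared lateralized substrate.

## Command line

```sh
ftcdlat run --config pipeline.yaml --out results/       # end to end
ftcdlat simulate --config pipeline.yaml --out signals/
ftcdlat preprocess --signals signals/ --out responses/
ftcdlat li --responses responses/ --out li_results.csv
ftcdlat correlate --li li_results.csv --responses responses/ --out results/
ftcdlat report --results results/ --out figures/
```

`pipeline.yaml` is a flat `key: value` file mirroring `SimulationConfig`
(any subset of keys; the rest take defaults). `run` writes per-session
signal/event CSVs, per-subject response traces, a QC report, LI results,
group traces, the moving-window correlation series, and a JSON manifest
recording seeds, outputs and exclusions. Identical configs give
byte-identical outputs.

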