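# Methods

## The problem

A pedometer on the leg of a grazing sheep sees more than footfalls.  Two
behaviors in particular corrupt naive peak counting of the acceleration
signal:

* **Running.** At a sampling rate of 32 Hz a running sheep takes several
  steps per second; the waveform never falls back to baseline between
  footfalls, individual step peaks merge, and peak counting *undercounts*.
* **Leg shaking.** A scratching motion performed while standing or lying
  produces trains of step-like peaks that are not locomotion at all, so
  peak counting *overcounts*.

The pipeline therefore recognizes these two behaviors explicitly and
counts steps per behavior:

    total steps = peak count
                − peaks inside running windows + running steps R
                − peaks inside leg-shake windows

Fast (brisk) walking shares the acceleration envelope of leg shaking but
is genuine locomotion; it is separated from shaking by the variance of
the x-axis angular velocity and its peaks count as ordinary steps.

## Signal model and preprocessing

The input is a six-axis trace (tri-axis acceleration in m/s², tri-axis
gyro in rad/s) at fs = 32 Hz.  Because the device rotates with the leg,
the per-axis signals are orientation-dependent; all detection runs on the
combined acceleration `acc = sqrt(acc_x² + acc_y² + acc_z²)` (the signal
magnitude vector).

The magnitude is low-pass filtered with a zero-phase second-order
Butterworth at 5 Hz (both parameters configurable).  The cutoff is a
design choice: walking cadence is ~1.1 Hz (one step per 29 samples),
running cadence ~2.3 Hz, and the pulse shapes put their energy below
~5 Hz, so the pass band keeps every gait component while removing sensor
noise.  Zero-phase (forward-backward) filtering is used so that peak
sample indices are not lagged — the running-step formula does arithmetic
on raw sample indices, which a causal filter would shift.  The pipeline
order is fixed: combine axes first, then filter the magnitude
(`low_pass` also accepts single axes for diagnostics).

Input is treated as uniformly sampled.  If timestamps are present and a
gap exceeds 2/fs, the trace is split at the gap with a warning and each
contiguous segment is processed independently; counts are summed.

## Peak and valley detection

Index *i* is a **peak** iff the signal rises strictly through its n left
neighbors and falls strictly through its n right neighbors, and
`acc_i > thr`:

    acc_{i-n} < … < acc_{i-1} < acc_i > acc_{i+1} > … > acc_{i+n},  acc_i > thr

with defaults n = 4 and thr = 12 m/s².  Valleys use the mirrored
condition with n = 2 and no threshold.  Inequalities are strict, so
plateaus yield no extremum; indices within n of either boundary are
excluded rather than padded (the condition needs n real neighbors per
side).  One peak above threshold is one regular walking step.

Downstream rules compare peak k with "its" valley.  The pairing rule:
peak k is paired with the first detected valley after it that precedes
peak k+1; if no detected valley falls in that span, the fallback is the
minimum sample strictly between the two peaks (or to the end of the
trace for the last peak).  The rule is isolated in `pair_extrema` so it
can be swapped.

## Behavior windows

**Running** (`detect_running`): a window opens at the first peak above
thr1 = 30 m/s² and closes at the first subsequent peak below thr2 = 20
(the closing test is implemented as the disjunction `peak < thr2 or
peak < thr3`, which is equivalent), or — when the raw signal is available
(`close_on_sample`, default on) — at the first raw sample below
thr3 = 12, whichever comes first.  The raw-sample test matters because
the pipeline's peak stream is thresholded at 12: a standstill produces no
peaks at all, and without it a window could stay open across one.  A
window still open at the end of the trace is closed at the final sample
and flagged truncated.  A closed window is *labeled* running iff its
interior peak-valley pairs keep their valleys above thr4 = 20 — the
algebraic reduction of "peak − valley < peak − thr4".  The quantifier is
ALL pairs by default (config-switchable to ANY).  Only pairs whose
valley lies inside the window count: the terminating dip under thr3 is
the window's exit, not part of the behavior, and would otherwise fail
the test for every window.

Running steps are estimated from the window size W (in samples, closing
index minus opening index): **R = round(W·K/L)** with L = 29 samples per
normal step and scale factor K = 2.1, chosen as the argmin-MSE over a
1.5–2.5 sweep against manual counts (`sweep_k` reproduces that
calibration).  Rounding is to the nearest integer, halves away from
zero, switchable to floor.

**Leg-shake candidates** (`detect_leg_shake_candidates`): a window opens
at a peak above thr5 = 12 and closes when the signal drops under
thr3 = 12.  It is a candidate iff every enclosed peak stays below the
regional restriction thr8 = 39 m/s² (higher peaks mean running), its
pairs keep valleys above thr7 = 12, and it encloses at least
`min_candidate_pairs = 1` peak-valley pair.  The pair minimum is a
deliberate addition: since thr5 equals the step threshold, every
isolated walking pulse opens a trivial window containing zero pairs,
which would vacuously pass an "all pairs" test; requiring one enclosed
pair restricts candidacy to sustained oscillations, which is what
shaking is.  Candidates overlapping a running-labeled window are
discarded (running is detected first and takes precedence in the
30–39 m/s² amplitude overlap), and the scan resumes after the running
window so a shake bout immediately following a run is still found.

**Shake vs. fast walk** (`classify_candidate`): a candidate is labeled
leg-shake iff the population variance of gyro-x over the window strictly
exceeds var_cut = 10 (in the squared units of the gyro column; rad²/s²
for the supported CSV dialect), else fast-walk.  The variance convention
is a config flag (population by default, since the threshold's
convention is not fixed by its source).  The feature analysis that
motivated this cut — mean/var/std/kurt/skew of gyro-x windows, k-means
with 3 clusters — ships as `extract_features`/`cluster_behaviors` for
exploration; it is not in the runtime counting path.  Kurtosis is
reported as excess kurtosis (Gaussian → 0).

## Evaluation arithmetic

Per-trial accuracy is the relative error |pred − true|/true × 100
(non-negative by convention).  Summary means follow the convention of
the bundled field-trial tables: per-row errors are rounded to 2 decimals
first and the mean of the rounded rows is reported at 3 decimals — the
published means (17.556 / 6.244 / 19.543 / 7.228) are reproducible only
under this convention (full-precision rows give 17.557 / 6.245 / 19.544).
`mean_relative_error(..., rounded_rows=False)` gives the full-precision
mean.

The K calibration summaries use MSE = Σe²/(n−1), RMSE = √MSE and
MAE = Σ|e|/(n−1).  The n−1 divisor in MSE *and* MAE is nonstandard but
forced by the published summaries (the K = 2 row has |e|-sum 8 over 8
windows yet MAE 1.14 = 8/7); `bessel=False` switches both to the
standard 1/n.  The leg-shake detection error rate is SER = errors /
detections, NaN when nothing was detected.  Display rounding is 2
decimals for rows and 3 for means, halves away from zero; internal
values keep full precision.

The bundled calibration error rows are internally inconsistent with any
single integer window size per calibration window (no W reproduces all
11 rows under nearest/floor/ceiling rounding, checked exhaustively to
W = 1200), so the error rows themselves — not reconstructed windows —
are the authoritative input to the summary arithmetic.

## Synthetic traces

`ovistep.simulate` generates labeled six-axis traces because no public
recordings of leg-worn sheep IMUs exist.  Regimes and their defaults:

| behavior   | waveform                                   | gyro-x sd |
|------------|--------------------------------------------|-----------|
| stationary | 9.8 m/s² baseline                          | 0.05      |
| walk       | one raised-cosine pulse (peak U(14,18), width 11 samples) per 29 samples on the 9.8 baseline | 0.5 |
| run        | cosine oscillation, valleys 23 / peaks 33.5, cadence 2.1 steps per 29 samples | 3.0 |
| leg_shake  | cosine oscillation, valleys 14 / peaks 18, 2.5 Hz | √30 |
| fast_walk  | same acceleration as leg_shake             | √2        |

Noise is additive i.i.d. Gaussian per axis before combination (default
0.2 m/s²); only gyro-x carries behavior signal.  Pulse shape is
swappable (raised cosine, triangle, Gaussian); the walking pulse width
is odd so the sampled pulse has a unique maximum — an even width puts
two equal samples at the top, which the strict monotonicity rule
correctly rejects.  Amplitudes are validated against the defining
thresholds at construction (a "run" spec whose peaks cannot cross 30 is
an error).  Ground truth records per-segment step counts; leg-shake
segments contribute zero steps (their peak count is kept separately).

What the generator does *not* emulate: biomechanically realistic
quadruped gait, stride-to-stride cadence variability, posture
transitions, grazing head-bob crosstalk, sensor-mount slip, drift or
saturation.  Passing tests therefore demonstrate that the rules
implement their definitions and recover truth under the stated regimes,
not field accuracy on real animals — the bundled field-trial tables are
the evidence for that, and only their arithmetic is reproducible here.

## Problem sizes and numerical choices

The recovery experiments use 20 mixed traces of ~55 s (8 behavior
segments, ~62 true steps each) plus walk-only traces of 25 steps;
desk-scale sizes that exercise every rule while keeping the whole suite
fast.  Observed on these conditions (recomputed by
`scripts/acceptance.py`): mean total-step relative error ≈ 2%, perfect
shake/fast-walk discrimination, exact walk-only recovery.

Degenerate inputs: traces shorter than the filter's padding length pass
through unfiltered with a warning; signals shorter than 2n+1 yield no
extrema (warning); behavior windows shorter than 2 samples classify as
fast-walk (variance undefined); constant feature windows report
skew = kurt = 0 with a warning; a zero true count or zero detections
make the corresponding ratio NaN rather than raising.  K-means uses
Lloyd's algorithm with 10 restarts and a fixed seed default.

## Known limitations

* Thresholds are calibrated for leg-worn sensors on sheep at 32 Hz;
  other species, mounts or rates need re-calibration (the config object
  exists for exactly that).
* The var_cut = 10 discriminator inherits the units of the gyro input
  column; feeding °/s instead of rad/s changes its meaning.
* Behavior windows are resolved greedily left-to-right; interleaved or
  overlapping behaviors (e.g. shaking that ramps into running) resolve
  by the running-first precedence rule, not by joint inference.
* The closing rule for running windows depends on the raw signal
  dropping below thr3; on traces where the animal transitions directly
  from running to fast walking the window closes at the first sub-thr2
  peak instead, slightly extending W.
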