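# Methods

`nirsfeed` is a hardware-free engine for real-time fNIRS neurofeedback: it
consumes a multiplexed sample stream (live via lab streaming layer, or from
the built-in simulator), runs causal sliding-window preprocessing, and maps
oxygenated-hemoglobin (HbO) deviations from an individually normalized rest
baseline onto a 10-bar thermometer display value. This note documents the
model, the parameters that matter, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Stream model

A two-wavelength NIRS device with *N* channels streams each sample as a
vector of `4N + 1` values: a frame counter, N raw light intensities per
wavelength, N HbO and N HbR concentration changes (μmol/L). A JSON device
descriptor maps every column to its role (see `docs/device_schema.md`); the
documented default dialect orders columns counter → raw@λ1 → raw@λ2 → HbO →
HbR, but any explicitly declared order is honoured. Column indices and
channel IDs are 1-based in all files and reports.

The sliding window holds the most recent `round(window_s · fs)` frames
(at the reference 10.17 Hz and 5 s window: 51 frames — the rounding rule is
ours; it gives the frame count closest to the nominal window length). The
window slides by one frame per incoming sample; no computation runs until
the first window has filled. A ring buffer bounds memory; every frame is
additionally mirrored into an append-only log so the session record is
complete even after eviction.

## Causal preprocessing (reference protocol `MovAvg_SS`)

Real-time operation forbids acausal filtering: output at time *t* may use
only samples at or before *t*. Per window, in fixed order:

1. **Short-separation regression.** Each long-channel window is regressed
   by ordinary least squares onto `[intercept, mean of the selected
   short-separation channels]`; the corrected window is residual +
   intercept, removing the scalp/systemic component while preserving the
   μmol/L level. Using the *mean* short channel (rather than a per-channel
   nearest-short mapping) is a design choice; the mapping is an extension
   point. Zero-variance short windows force the slope to 0 and skip the
   correction with a logged warning.
2. **Causal moving average** over the full window (trailing mean; early
   samples average the available prefix).
3. **Across-channel mean** of the selected neurofeedback channels. The last
   smoothed sample is the per-window output `meanHbOreg_i`.

A causal Gaussian low-pass (one-sided truncated kernel, renormalized to
unit sum over the available history) and a forward-only Butterworth
band-pass are provided as optional stages; the reference protocol does not
use them by default. Whether smoothing runs before or after the regression
is not fixed by any external constraint we know of; regress-then-smooth is
documented as this package's order. Only HbO is processed; HbR is recorded
but not filtered.

Every protocol implements the four-function lifecycle `requires` / `init` /
`process` / `finish`. `requires` checks modality, minimum channel counts
(≥ 1 neurofeedback and ≥ 1 short-separation channel, disjoint), the HbO
unit (μmol/L), and that the window length lies in the protocol's supported
range (2–30 s for `MovAvg_SS`; the bounds are our documented choice).

## Feedback computation

From the filtered across-channel mean of the **last 15 s of the first rest
phase** (~152 samples at 10.17 Hz; we take `round(15·fs)`), sorted
ascending: drop the 10 highest and 10 lowest values, then

    amplitude_rest     = |mean(top 25) − mean(bottom 25)| of the remainder
    correction_factor  = expected_amplitude / amplitude_rest

with `expected_amplitude = 0.1` μmol/L. The trim counts assume ~150
samples; at other sampling rates they scale proportionally (≈ 6.7% dropped
and ≈ 16.7% averaged per tail, floor 1). The correction factor is computed
once per session and normalizes feedback gain across participants and
brain regions; an opt-in per-run recomputation exists but is off by
default. A near-constant rest window would divide by ~0, so the amplitude
is floored at 1e−6 μmol/L (correction factor capped) with a warning.

For each window *i* of a regulation phase,

    feedback_i = (meanHbOreg_i − meanHbOrest) × correction_factor

where `meanHbOrest` is the trailing 5-s mean of the immediately preceding
rest phase (refreshed at each regulation onset; a shorter rest falls back
to its full mean with a warning). The thermometer value is the affine map
of the expected HbO range `[−0.4, 0.4]` μmol/L onto `[0, 1]`:

    r = (feedback − HbO_min) · (thermo_max − thermo_min)
        / (HbO_max − HbO_min) + thermo_min

clipped into the thermometer range (the unclipped feedback is still
recorded). Zero deviation therefore always reads mid-scale (0.5). The
display divides the range into 10 bars of 0.1; a bar counts as filled when
its lower edge is ≤ r (so r = 0.8 fills 9 bars, r = 0 fills 1). The
lower-edge convention is inferred from the single worked example available
for the display; it is applied with a 1e−9 tolerance on exact edges.

During rest phases the thermometer is pinned at the midline (0.5); during
the initial baseline and inter-run breaks no feedback is emitted, and the
session record stores NaN for those frames so "no feedback computed" and
"pinned at midline" stay distinguishable.

## Schedules and monitors

The example session builder emits one 5-s baseline epoch (marker 1), then
five runs of 30-s rest (marker 2) / regulation (marker 3) alternations with
[5, 6, 6, 6, 5] trials, every regulation preceded by its rest, and a 30-s
break (marker 1) between runs: 61 epochs, 28 regulation–rest repetitions,
1805 s total. (A nominal session length of 1800 s is sometimes quoted for
this design; the builder reports the computed sum and does not truncate.)
Epoch intervals are half-open `[start, end)`, which makes the epoch lookup
total and boundary-unambiguous. Feedback is visible only in runs 2–4;
the visibility flag governs display only — feedback is computed in all
runs.

Two monitors supervise real-time health once per second:

* **Delay** — `expected = floor(elapsed · fs)`, `lost = expected −
  acquired`, `delay = lost / fs`; unacceptable when strictly greater than
  1 s.
* **Protocol time** — mean and max of the per-window processing durations;
  exceeded when the mean is above one sample period (1/fs ≈ 98.3 ms at
  10.17 Hz).

## Synthetic data generator

The simulator defines the study conditions used throughout the tests:
10.17 Hz sampling, 18 long (3 cm) + 8 short-separation (8 mm) channels,
0.1 μmol/L HbO activation per regulation block. Long channels carry the
canonical hemodynamic response (double-gamma, default peak 5 s inside the
physiological 4–6 s range, 15% undershoot) convolved with the schedule's
regulation boxcar, plus systemic physiology shared with the short
channels — cardiac 1.1 Hz, respiration 0.25 Hz, Mayer waves 0.1 Hz, slow
linear drift — plus white noise; short channels carry systemic physiology
and noise only. Noise frequencies and amplitudes (0.02/0.03/0.04 μmol/L,
drift 0.0005 μmol/L/s, white SD 0.01 μmol/L) are our defaults chosen to
be physiologically plausible relative to the 0.1 μmol/L activation; all
are overridable. HbR is −0.3 × the activation plus independent noise.
Raw intensities are generated through the exact algebraic inverse of the
modified Beer–Lambert law with the fixed conversion constants of the
reference acquisition software (760 nm: ε_HbO 1.35, ε_HbR 3.57, DPF 6.30;
850 nm: ε_HbO 2.44, ε_HbR 1.59, DPF 5.23), concentrations converted
μmol/L → mmol/L to match the per-(mM·cm) coefficient scale, and a
configurable source–detector distance (that software's internal distance
assumption is not published, so it is a parameter, not a guessed
constant). An optional quiet lead-in (e.g. 120 s) emulates the acquisition
software's internal baseline before the schedule starts.

All randomness derives from a single seed via spawned per-channel
substreams; identical configs are bit-identical. The generator exports the
noise-free activation curve as ground truth, which is the oracle for the
regression-quality tests.

**What the simulator does not emulate:** motion artifacts, optode-coupling
changes, heteroscedastic or autocorrelated sensor noise, per-channel
hemodynamic variability, scalp-layered photon transport, or any
participant learning effect. Passing tests therefore demonstrate that the
engine behaves correctly under its stated signal model — not that the
feedback is physiologically valid for any particular participant or
montage.

## Problem sizes in the test suite

End-to-end tests and the parameter-recovery checks run a shortened
two-run schedule (2 trials per run, 275 s of simulated time) over 10 seeds
in accelerated time, which this package completes in a few seconds; the
full 61-epoch session is exercised for schedule construction, settings
round-trips, and counting checks. These sizes are the package's chosen
desk-scale defaults for deterministic, fast verification.

## Known limitations

* The live lab-streaming-layer transport is a thin optional adapter
  (requires the `lsl` extra) and is not covered by automated tests; the
  simulated transport shares its contract and carries all testing.
* The EEG device format is parsed, but no EEG processing protocol is
  defined.
* The graphical feedback window itself is out of scope; `render_summary`
  produces the end-of-run figure only.
* Kalman filtering, temporally embedded CCA, and wavelet denoising are
  deliberately absent: the first two are untested in real time, the last
  is too slow for per-sample sliding windows.
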