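# Methods

## Problem and pipeline

Bowel sounds (BS) are short acoustic bursts produced by gut peristalsis,
with energy concentrated roughly in 100–1000 Hz. Two indices computed from
a recording's BS events are used as motility markers: the **sound-to-sound
interval** (SSI, the gap from the end of one event to the start of the
next) and the **sound duration** (SD, total BS time per file). gutsound
detects BS events in smartphone-grade audio and computes these indices.

The pipeline is: mono WAV at 48 kHz → mel-spectrogram on a 100 ms frame /
25 ms hop grid (75% overlap, Hann window, FFT length = frame length = 4800
samples) → per-frame 3×11 feature patches → CNN (or LSTM) two-way
classification per frame → decoding of positive runs into event intervals,
with adjacent events ≤ 10 ms apart merged ("unification") → SSI/SD.

## Feature geometry

A frame grid with frame length `L = 100 ms` and hop `h = 25 ms` over a clip
of `N` samples yields `floor((N − L·fs)/(h·fs)) + 1` frames (2397 for 60 s
at 48 kHz). All frame arithmetic is done in integer samples so the count is
exact.

The classifier input is a `3 × 11` patch per frame: 3 frequency bands ×
11 consecutive frame columns centred on the target frame (±125 ms of
context). The bands average mel bins whose centres fall in
100–300 / 300–600 / 600–1000 Hz — the reported BS range. The published
description fixes only the 3×11 shape, not what the axes measure; this
band-aggregation reading is our design choice and both axes are
configurable. Other unstated featurization choices, all exposed as
parameters:

* `n_mels = 40` over 40–2000 Hz (smooth triangular filters at FFT length
  4800; 2000 Hz gives 2× headroom above the reported BS band; 40 Hz is the
  handset's lower audible limit).
* dB scale is absolute (`10·log10(power)`) floored 80 dB below the
  per-file maximum; silence maps to the floor, and doubling the waveform
  amplitude shifts every value by +6.02 dB.
* Per-patch standardization to zero mean / unit variance (constant patches
  → all zeros): robust to gain differences between phones; the classifier
  sees spectro-temporal shape, not absolute level.
* Edge frames use replicate padding, so every frame is classifiable.

## Label algebra

Intervals are half-open `[start, end)` seconds. Unification transitively
merges events separated by ≤ 10 ms; larger gaps keep events independent.
Multi-rater consensus rasterizes each rater's track at 1 ms, keeps cells
marked by ≥ `min_raters` raters (default 2, i.e. majority of 3; strict
unanimity is one flag away), converts runs back to intervals and re-unifies.

A frame inherits a positive label when BS intervals cover ≥ 50% of its
span. The 50% threshold is symmetric and makes intervals↔frames
approximately inverse; on a non-overlapping grid (hop = frame length) the
round trips are exact for boundary-aligned events. Supervision uses the
75%-overlap grid; the hop is configurable.

## Classifiers

**CNN** (default): three blocks of two same-padded 3×3 convolutions
(batch-norm + ReLU each) followed by a max-pool, channels 8/16/16, dropout
0.25 after block 3, then a fully connected softmax head. Pooling acts on
the time axis only (1×2): the input is 3 bands tall, and 2×2 pooling would
collapse the frequency axis before three blocks complete. Time width
follows 11 → 5 → 2 → 1.

**LSTM baseline**: the 11 patch columns are read as a length-11 sequence of
3-dimensional band vectors through 2 stacked layers of 64 hidden units;
the final hidden state feeds the same head. The original baseline's
architecture was never described; this is a documented stand-in.

Training minimizes two-class cross-entropy with Adam (lr 1e-3), mini-batch
32, seeded uniform fan-in initialization. Optimizer, learning rate, loss
and initialization were never published; these are standard defaults, all
configurable. Optional inverse-frequency class weighting is off by default.
The networks are implemented directly in numpy with hand-written
backprop — the inputs are tiny (3×11), so this is fast on one CPU and
bit-reproducible; gradient correctness is verified against finite
differences in the test suite. Everything is a pure function of
(config, data, seed): identical runs give identical weights.

The decision threshold is `p ≥ 0.5` (≥ convention). Batch-norm uses
running statistics at inference.

## Evaluation

Frame-level metrics: accuracy, precision, sensitivity, and F measure (the
harmonic mean of precision and sensitivity — preferred over accuracy here
because BS frames are a small fraction of each recording). Undefined 0/0
cases return an explicit `None`, never a silent 0 or NaN.

Splits are always **subject-grouped**: a fold plan partitions subjects into
k near-equal folds (sizes differ by ≤ 1) and every clip follows its
subject, so no identity leaks between train and test (asserted on every
split). Holdout evaluation fixes one split and repeats training with fresh
seeds (default 5); cross-validation rotates the test fold over all k folds;
both report mean ± SD. Metrics are pooled over test frames per split
(micro); per-clip macro averaging is available via a flag. The original
fold construction (nine folds of 15 subjects) is arithmetically
inconsistent with the usable 77-subject cohort and cannot be recovered, so
fold sizes are generic rather than hard-coded.

## Motility

SSI is computed on unified, disjoint tracks; overlapping input is an error
rather than a silent fix. Per-file truth-vs-prediction agreement uses
Pearson r on the per-file SSI reduction (mean by default, median
available) and on SD totals, with two-sided p from the t distribution on
n−2 degrees of freedom. Files with fewer than two events have no SSI and
are excluded pairwise with a logged count; fewer than three surviving pairs
is an error.

## Synthetic scenes

No study recordings were released, so the generator emulates the study
conditions: 60 s mono scenes at 48 kHz containing multi-peak bursts over
three noise classes, with exact ground-truth label tracks.

* **Bursts**: complexes of `n_peaks` Gaussian-windowed tones with carrier
  frequencies drawn in `f_center ± bandwidth/2` (validated to stay inside
  the handset's 40 Hz–16 kHz audible range), under an exponential decay
  envelope, peak-normalized to `amplitude`. Click envelopes are sized to
  the inter-click slot so the click train tiles the full labelled duration
  — the envelope dips to ~46% between peaks but never to silence, keeping
  every labelled frame acoustically present while preserving the
  multi-peak appearance.
* **Noise classes**: circuit = white Gaussian; biological = Gaussian-
  windowed ~40 Hz thumps repeating at a configurable period (heartbeat-
  like); background = pink-ish noise rolled off above ~150 Hz so most
  energy sits below 200 Hz. Levels are RMS in dB relative to full scale,
  and must be negative (the "clearly identifiable" regime that mirrors the
  usable subset of the original recordings).
* **Timing**: inter-event gaps are i.i.d. log-normal with configurable
  arithmetic mean/SD, defaulting to the reported fasting SSI of
  2.00 ± 7.92 s — the large SD implies heavy right skew, and log-normal is
  the simplest positive heavy-tailed choice. Gaps are clipped below at
  11 ms so ground-truth events stay independent under the 10 ms
  unification rule (negligible bias at realistic means).
* Mixing is linear; a final peak normalization triggers only if the mix
  exceeds full scale. Every operation is a pure function of (arguments,
  seed).
* **Simulated raters** derive imperfect annotation tracks from truth
  (boundary jitter, misses, false alarms) to exercise the consensus
  algebra.

What the generator does **not** model: abdominal transfer functions,
microphone frequency response, recording-device variation, or real
non-stationary environments. Passing tests therefore demonstrate that the
pipeline machinery recovers what it is designed to recover under
controlled conditions — not field performance on real abdominal audio.

## Synthetic cohort and problem sizes

The recovery benchmark generates 20 subjects × 8 × 60 s recordings
(matching the original per-subject recording count) with per-subject SSI
means drawn uniformly from 1–4 s (inter-individual motility variation,
needed for the per-file correlations to carry signal), within-file SSI SD
1.5 s, and all noise sources at −30 to −35 dB relative to full scale
(high SNR). Detectors train for 3000 iterations — loss is converged well
before that at this scale — and results are reported as the median over 3
training seeds. `scripts/acceptance.py` runs the same experiment at
12 subjects × 4 clips with one training seed, plus a 1200 s
generator-fidelity scene at the fasting-SSI defaults.

## Numerical and degenerate-input conventions

* Interval times are float seconds; label files are written with 6
  decimals and round-trip to ≥ 1 ms.
* Frame-overlap threshold comparisons carry a 1e-9 tolerance so exact
  50%-overlap cases are stable.
* Silent input: mel values all equal the dB floor; constant patches
  standardize to zeros; a detector trained on one class is an error.
* Metrics 0/0 → `None` markers; correlations with zero variance → `None`.
* Constant (zero-contrast) patches decode to p = 0 at prediction time: a
  burst by construction creates spectro-temporal contrast, and a
  featureless patch (e.g. digital silence, which standardizes to all
  zeros) lies outside the training distribution, so its classifier output
  would otherwise be arbitrary.
* WAV input is clipped to [−1, 1] after integer scaling (full-scale
  negative PCM values can map slightly below −1).

## Known limitations

* The 3×11 input interpretation (band aggregation) is one reading of an
  underspecified description; a raw mel crop is buildable via the same
  configuration surface but is not the default.
* The LSTM baseline is a stand-in, not a reproduction; comparisons against
  it are directional only.
* Training at the published 100 000 iterations is supported but
  unnecessary at synthetic scale; defaults in the experiment helpers use
  far fewer.
* The published headline numbers were computed on recordings that were
  never released and cannot be reproduced here; the synthetic benchmark
  verifies the machinery, not the published values.
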