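# Methods

This note documents the modelling choices behind `cardiostage`: the
feature model, the cleaning and exclusion rules, the network and its
calibration, the training protocol, the synthetic-data model, and the
numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and features

The pipeline assumes two raw channels per night: single-lead ECG (≥ 100
Hz; 125 Hz in the simulator) and abdominal excursion (any rate; 25 Hz in
the simulator), plus an expert hypnogram at 30-s epochs. Sleep stages
modulate autonomic tone, so heart-rate level and variability carry
stage information; large body movements saturate the abdominal band,
concentrating in wake. Four per-15-s streams capture this:

| stream | definition | units |
|---|---|---|
| `hr_mean` | 60 / mean(IBI) over IBIs ending in the window | BPM |
| `ibi_sd` | sample SD of those IBIs | s |
| `hr_sd_4min` | sample SD of `hr_mean` over a centered 16-interval window | BPM |
| `abd_range` | max − min of the abdominal samples in the window | signal units |

Conventions that the data format does not force and were therefore
fixed here:

* an IBI belongs to the window containing its **ending** R-peak;
  windows with fewer than two IBIs are missing;
* IBIs outside **[0.3, 2.0] s** (200–30 BPM) are discarded before any
  statistic, so isolated detector glitches cannot dominate `ibi_sd`;
* the 4-min window is **centered** (`[i−8, i+8)`) and needs ≥ 8
  non-missing members; edge windows truncate under the same rule;
* sample SD (n−1 denominator) everywhere;
* interior missing runs of ≤ 4 intervals are filled linearly; longer
  runs are left entirely missing (no partial fill), and leading /
  trailing runs are never filled;
* standardization constants (μ, σ of the non-missing entries) are
  computed **after** gap interpolation; entries still missing after
  standardization are set to 0, which equals the recording mean under
  the z-score — the network needs dense input;
* a zero-variance stream raises a degenerate-feature error and sends
  the recording to QC rather than being silently repaired.

`hr_mean` is expressed in BPM rather than as mean IBI: it is a
monotone per-recording reparameterization of the same quantity, and BPM
matches the units of the exclusion thresholds.

### R-peak detection

A Pan–Tompkins-style detector written on scipy primitives: band-pass
5–30 Hz (2nd-order Butterworth, zero-phase), squaring, 150-ms
moving-average envelope, threshold at 20% of the envelope's 99th
percentile, candidate peaks ≥ 0.25 s apart, each snapped to the local
maximum of the squared filtered signal within ±100 ms. Any detector
meeting the same contract (strictly increasing times, 0.25-s
refractory, empty output on flat/short input) can be substituted. On
the simulator the detector recovers ≥ 99% of planted peaks within
10 ms (tested).

## Label cleaning

Raw stage strings are mapped through a configurable synonym table
(R&K, AASM, and common numeric spellings); S1/S2/N1/N2 → light,
S3/S4/N3 → deep; anything unrecognized becomes *unknown*. Unknown runs
at either end of the night become wake; interior unknown runs take the
**preceding** known label — a deterministic forward-fill convention for
categorical series (nearest-label interpolation would need a
tie-break; the choice is config-free and standard-agnostic). Cleaned
30-s labels are copied into their two 15-s intervals, encoded wake=0,
REM=1, light=2, deep=3, and truncated to the feature-stream length when
label and signal durations disagree (mismatches > 2 intervals are
logged).

## Quality control

Rules, evaluated exhaustively per recording so the report is an audit
trail: both channels present; duration ≤ 10 h; sample SD of
pre-standardization `hr_mean` over the **middle 50% of intervals**
(half-open index slice `[⌊n/4⌋, ⌊3n/4⌋)`) within [1.5, 13.5] BPM. The
middle region is measured over clock time by interval index — the
labeled sleep period is an alternative reading of "middle duration",
but index-based slicing is deterministic and label-independent.
Database-specific curation rules (sampling-rate caps, age limits,
disorder status) are not hard-coded; they concern corpora this package
does not ship and can be expressed as predicates over recording
metadata by the caller.

## Network

Input 2400 × 4 (10 h of 15-s intervals; shorter nights are left-padded
with zero features and wake labels, and the pad length is retained).
Default architecture:

* encoder: 4 × [Conv1d(k=3, dilation 1/2/4/8, filters 8/16/32/64) →
  batch norm → ReLU → maxpool×2], residual output saved pre-pool;
* middle: Conv1d(k=3, 32) → BN → ReLU → bidirectional LSTM(50) at
  150 steps (offline whole-night scoring justifies bidirectionality);
* decoder: 4 × [upsample×2 → concat mirror-encoder residual →
  Conv1d(k=3, dilation 8/4/2/1, filters 38/30/18/10) → BN → ReLU];
  residual connections are channel-wise **concatenation**, not
  addition;
* head: 1×1 convolution to 4 classes, softmax.

This configuration has exactly 76,552 trainable and 496 non-trainable
parameters; the non-trainable count is the running mean and variance of
the 248 batch-normalized channels. The doubling encoder and the
parameter totals pin most of the design; the decoder widths
(38/30/18/10) and LSTM width (50) were calibrated so the totals are met
exactly, and `architecture_summary()` (also written as
`architecture.txt` by the training CLI) records the resulting per-layer
shapes for inspection. Dilation rates do not affect parameter counts;
the increasing-then-decreasing pattern (1-2-4-8 / 8-4-2-1) widens the
receptive field toward the bottleneck.

Numerical conventions: float64 throughout; batch-norm eps 1e-3 with
exponential running statistics (momentum 0.99); LSTM gate order
(input, forget, cell, output) with forget bias 1, Glorot-uniform input
kernels and orthogonal recurrent kernels; argmax ties break toward the
lowest class code for determinism across numeric backends; prediction
trims the padded region before any metric. The whole kernel is NumPy
with hand-written backpropagation, verified against central finite
differences in the test suite.

## Training

Cross-entropy over all 2400 intervals, padded region included — the
padding scheme deliberately labels padded intervals as wake, and the
model learns the zero-feature → wake association; a `mask_padding`
switch excludes the padding from the loss but is off by default.
Evaluation metrics always exclude the padding, which would otherwise
inflate wake accuracy. Pooled metrics come from the summed confusion
matrix across recordings; per-recording values are reported alongside.

Adam with batch size 100 and learning rates 1e-4 (initial and
from-scratch training) and 1e-5 (fine-tuning) are the corpus-scale
defaults. The desk-scale presets shipped with the package use smaller
batches and proportionally larger rates (1e-3 from scratch, 1e-4
fine-tune, batches 8 and 5): with 48–60 recordings a batch of 100 would
collapse an epoch into a single update and the corpus-scale rates would
need thousands of epochs. Epoch budget and early stopping (default max
200 epochs, patience 20 on validation loss, best-validation checkpoint
restored) are this package's choices; class weighting is available but
off by default, letting the model inherit the natural stage imbalance.

Fine-tuning freezes every encoder parameter — weights and batch-norm
statistics; frozen batch-norm layers run in inference mode — so the
encoder is bit-identical before and after, which the suite asserts
exactly. Recordings are treated as independent samples in the 4:1
split (validation = ⌊N/5⌋) even when corpora are longitudinal.

## Synthetic data

The simulator generates exactly the structure the features measure,
and nothing else:

* stage sequence: first-order Markov chain at 30-s epochs, started in
  wake; default transitions give long stage runs and realistic stage
  percentages (roughly 15% wake, 20% REM, 45% light, 20% deep at
  stationarity);
* heart rate: per-stage mean IBI (wake 70, REM 65, light 60, deep
  56 BPM — a 14-BPM wake-deep gap) with per-stage gaussian IBI noise
  (50/40/25/15 ms) and a slow sinusoidal drift (±3 BPM, 90-min period,
  random phase) emulating long-term HRV;
* ECG: a gaussian-mixture QRS template at each planted peak over mild
  noise and baseline wander — adequate for QRS detectors, with no
  claim to morphological realism (no P/T waves, arrhythmias or apnea);
* abdominal channel: 0.25-Hz breathing oscillation (amplitude 1) with
  Poisson movement bursts in wake epochs (rate 0.3/epoch, 2–5 s)
  clipped at the ±5 saturation amplitude;
* labels: dialect "A" emits R&K-style strings, dialect "B" AASM-style
  strings and additionally relabels boundary epochs of deep runs as
  light with probability 0.8, a controllable stand-in for systematic
  scoring drift between the standards; 2% of epochs become "?" to
  exercise unknown-label interpolation.

Everything is deterministic under (config, seed): fixtures written
twice with the same seed are byte-identical. What passing tests on
this generator show is that the pipeline recovers planted structure —
detector accuracy, per-stage HR separation, QC selectivity,
learnability, and the direction of the fine-tuning benefit. What they
cannot show is performance on real PSG: real autonomic stage
signatures are weaker, subject-dependent and confounded by disorders,
so synthetic κ values are upper bounds of a mechanism check, not
clinical estimates.

QC-violation configs intentionally break the generator's normal
envelope (an 11-h night; a flat-HR night; a ±25-BPM drift), so the
duration bound that applies to training inputs is enforced at padding
time (> 2400 intervals is an error directing to QC), not in the
simulator config.

## Desk-scale experiment sizes

The bundled `acceptance_small` preset uses 60 nights × 4 h for training
(48/12 split, ≤ 50 epochs), 15 dialect-B nights for fine-tuning with 5
early-stop nights and 10 held-out evaluation nights, and a 20-recording
QC cohort with 6 planted violations. These sizes keep a full
from-scratch run in the low minutes on one CPU while leaving the
learnability and transfer effects comfortably measurable.

## Known limitations

* The NumPy kernel is single-threaded apart from BLAS matmuls; it is
  sized for desk-scale experiments, not 10k-night corpora.
* Only 4-class staging is implemented; N1 vs N2 separation is out of
  scope.
* The EDF writer quantizes to the format's 16-bit range (lossless at
  stored precision, not bit-exact for arbitrary floats), writes 1-s
  records and integer sampling rates, and does not emit EDF+
  annotations; hypnograms travel as plain CSV.
* The simulator's dialect shift models one specific, local relabeling
  mechanism; real inter-standard drift also moves sleep-onset and
  arousal scoring.
* Breathing-rate, spectral-HRV and movement-morphology features are
  deliberately absent from the feature set.
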