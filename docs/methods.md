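# Methods

This note documents the models, numerical choices, and limitations behind
`zfecg`, in the order data flows through the package.

## Synthetic zebrafish ECG

No public zebrafish ECG recordings with beat-level annotations exist, so
the package ships a generator whose records carry exact ground truth.

**Beat model.** A beat is the sum of five Gaussian bumps — P, Q, R, S, T —
with amplitudes in mV, widths as Gaussian σ in seconds, and positions as
fractions of the R-R interval. Defaults (P 0.12 mV/18 ms, Q −0.15/6, R
1.0/6, S −0.20/6, T 0.25/30 ms) keep P and T clearly below half the R
amplitude (so the 50 % R-detection threshold is meaningful) while leaving
each wave the unambiguous extremum of its search window. Gaussian mixtures
are the standard surrogate when only peak locations and amplitudes matter;
the model makes no claim about wave *onsets/offsets* or biophysics.

**Scheduling.** The R-peak times are scheduled first: a base R-R from the
mean heart rate, Gaussian beat-to-beat jitter (default SD 5 ms), and the
anomaly's modulation. All other waves are placed fractionally within the
actual R-R interval they occupy — S and T after their own R (at 0.04 and
0.35 of the interval), the P and Q of the *next* beat late in the interval
(0.80 and 0.96) — matching the windowed extractor's model of zebrafish wave
order. Scheduling R directly means the generated R-to-R gaps *are* the
jittered series, which is what the rate and variability rules read; an
earlier design that concatenated per-beat templates smeared R-R modulation
across neighboring intervals and was discarded.

**Rates.** The base default is 120 BPM; `awake_spec()` uses 200 BPM
(intrinsic awake rates commonly exceed 200 BPM) and `anesthetized_spec()`
100 BPM (tricaine). Bradycardic records must stay above ~72 BPM only if
the 50 ms Q/S windows are to contain the fractional Q/S offsets; at the 60
BPM injection default the offsets are 40 ms and remain inside.

**Noise.** Additive terms, all in mV: baseline wander (0.15 mV sine at
0.25 Hz), mains hum (0.02 mV at 60 Hz — most of it is removed by the
hardware notch in a real chain, hence the small default), white sensor
noise (SD 0.02 mV), and optional gill-motion bursts (damped 12 Hz
oscillations recurring at the 2–4 Hz gill beat rate, off by default in the
base spec). `NoiseParams.none()` gives the noise-free configuration used
for parameter-recovery oracles.

**Anomalies.** Each injection satisfies its diagnostic inequality by
construction, and raises if parameterized so that it cannot:

* AVB: every k-th beat (default 2) loses Q/R/S/T, keeping its P wave.
* SA: ≥ 2 consecutive whole beats deleted, so the surviving P-P gap is at
  least 3 R-R intervals — strictly greater than the 2×R-R criterion.
* STE: constant offset (default 0.15 mV) added strictly between S and T.
  The default keeps the elevated plateau below half the R amplitude;
  larger offsets are possible but can cross the R-detection threshold.
* brady-/tachycardia: mean rate forced to 60 / 180 BPM by default.
* sinus arrhythmia: R-R alternates ± spread/2 (default spread 0.20 s >
  0.16 s).

**What passing tests show.** The generator produces aligned, stationary,
morphologically clean records; real recordings have drifting electrode
contact, heart-rate trends, nonstationary artifacts, and P/T waves that are
often barely visible in awake fish. Perfect recovery and classification on
synthetic data therefore validate the *algorithmic chain* (windows, rules,
arithmetic, clustering mechanics) — not field performance on recorded fish.

## Filtering cascade

Order: optional 60 Hz notch → FIR lowpass → wavelet detrend → wavelet
denoise. All stages are deterministic and length-preserving.

* **Lowpass**: 201-tap linear-phase FIR, Dolph-Chebyshev window at 60 dB
  sidelobe attenuation, cutoff 150 Hz, applied zero-phase via symmetric
  convolution with reflected edges. DC gain is exactly 1. Edge transients
  decay within one kernel length; steady-state stopband rejection is
  better than 10⁻³.
* **Detrend**: Daubechies-6 multilevel decomposition; the approximation at
  the automatically chosen level (smallest level whose approximation band
  is below 0.5 Hz, capped by the decomposable depth) is zeroed. Removes
  constant offsets exactly and sub-Hz wander to a few percent.
* **Denoise**: translation-invariant (stationary-transform) soft
  thresholding at the universal threshold σⱼ·√(2 ln N) per detail level.
  Two numerical points matter. First, the noise scale must be estimated
  where noise dominates: standalone, σ comes from the finest-level detail
  MAD of the record itself; inside the cascade the lowpass has already
  emptied that band, so the pipeline estimates σ on the *raw* input and
  propagates it through the lowpass response (level j keeps the fraction
  of its band below the cutoff). Estimating σ per level from deep-level
  coefficients was rejected: clean periodic ECG occupies most coefficients
  there, and MAD then reads signal as noise and crushes T waves and ST
  plateaus. Second, the normalized stationary transform scales level-j
  detail noise by 2^(−j/2), and the thresholds follow that scale; with
  orthogonal-scale thresholds the stage annihilates all detail bands.
  The decomposition depth is chosen so the untouched approximation band
  lies below 2 Hz (≈ the beat rate); slower noise is the detrend stage's
  job. Under clean conditions all thresholds are ≈ 0 and the stage is an
  identity to reconstruction precision.

The quiet-baseline noise floor of a 1 mVpp broadband-noise record drops
more than tenfold through the cascade (measured on samples ≥ 0.5 s from
the record edges and outside wave neighborhoods, as the steady-state
baseline one would read off a chart).

## Fiducial windows

"Maximum amplitude" for the 50 % R threshold is taken over the analysis
window — the whole record in batch mode, the trailing display window in
streaming mode. A 150 ms refractory spacing collapses near-coincident
superthreshold maxima to the larger one; on clean data no other wave
crosses the threshold, so it is inert, but it protects against artifact
spikes. Search windows are inclusive of both endpoints, ties break to the
earlier sample, and windows clamped at the record boundary are flagged.
The extractor always returns a peak per window (the windowing algorithm's
contract); a prominence score (peak minus window median) lets downstream
code recognize degenerate detections, e.g. the baseline "T" of an AV-block
interval. Beats before the first R and after the last R are not assigned
intervals; P/T of the final partial interval are therefore not reported.

## Features and HRV conventions

Within interval (R₁, R₂): QR = R₁−Q, RS = S−R₁, ST = T−S, RT = T−R₁,
TP = P−T, PQ = Q′−P (Q′ from the next interval), PR = R₂−P. These follow
the zebrafish wave order in which the detected P belongs to the *next*
beat; the sub-intervals RS+ST+TP+PQ+Q′R₂ then tile the R-R interval
exactly. The amplitude feature is signed: amplitude(R₁) − amplitude(T).

The isoelectric line defaults to the median of the interval's own T-to-P
segment (the conventional baseline region); a constant override is
available. ST statistics use population (N) standard deviations; HRV uses
sample (N−1) standard deviations, matching common HRV practice. Samples
exactly on the isoelectric line count as "above". NN50 uses a strict
inequality (> 50 ms), and pNN50 = 100·NN50/(#RR−1).

## Rule engine

Heart rate is per interval (60/RR), not a running mean. The arrhythmia
window is the trailing up-to-10 beats (using what exists once ≥ 2 have
accumulated). The sinus-arrest reference R-R is the median of that same
trailing window, and P-P is the gap between consecutive detected P waves;
the first interval has no preceding P, so arrest is reported as
not-evaluable there rather than false. ST elevation/depression thresholds
default to ±0.1 mV — no zebrafish reference values exist, so these are
explicitly working defaults and excluded from quantitative acceptance.
AV block is deliberately not rule-diagnosed (its orphaned-P signature is
left to the classification path); on AVB records the merged intervals
still surface through the bradycardia/arrest rules.

Streaming mode re-runs the batch chain on the trailing window every hop
(default 10 s window, 1 s hop) and reports each flag as the OR over the
intervals in view, which is how a live display would behave.

## Classification

Feature vectors for K-means are the truncated (2916-sample), per-segment
min-max-normalized 1-D signals; the 54×54 z-layout images are an
equivalent re-indexing of the same values, kept for inspection and for the
CNN adapter. K-means is Lloyd's iteration with seeded random
initialization, 10 restarts keeping the lowest within-cluster sum of
squares (the canonical guard against poor initializations), empty clusters
re-seeded from the farthest point, and an assignment-fixed-point stopping
rule. Clusters are mapped to class labels by majority vote on training
data, ties breaking to the earliest class in the configured order.

Cross-validation is stratified 10-fold; average accuracy, macro precision
and macro recall are averaged over folds, and the reported F1 is the
harmonic mean of the averaged precision and recall — the same arithmetic
that links the per-class F1 cells to their precision/recall in the
published table this evaluation format follows. A class absent from the
test truths has undefined recall and is excluded from the macro averages
with a note; a class never predicted gets precision 0.

The default synthetic dataset mirrors the published experiment's shape
(three phenotype classes, ~3000-sample segments of 4–5 beats at ~92 BPM,
dozens of segments per class) and is separable by construction: segments
share a fixed generation phase, 5 ms jitter, and mild noise, so perfect
cross-validated scores on it verify the encoding/clustering/metric
machinery, not real-world classifier quality. The published accuracies on
recorded fish (~76 % for K-means) are not reproducible without the
original recordings and are out of scope.

The CNN path is an adapter interface only: transfer learning from a
pretrained Inception-style backbone requires weights and a deep-learning
runtime that are not dependencies of this package. `cnn_adapter` raises a
"plugin disabled" error when no backbone or registered adapter exists, and
the K-means path is the complete supported classifier.

## Problem sizes

Defaults throughout were chosen so the full test suite and the acceptance
script each run in well under a minute on one CPU: 10–20 s records for
filtering and rule checks, 9 noise-free records for parameter recovery,
1000 random R-R series for the HRV oracle, and 60 segments per class for
cross-validation. All sizes are configurable upward.

## Known limitations

* The original acquisition chain's filter internals (cutoffs, orders,
  threshold rules) are not published; the cascade's defaults are this
  package's own calibration, documented above, not claims of fidelity.
* Fiducials are peak locations only; durations (QT, QRS width) and wave
  onsets are out of scope.
* The rule engine's ST thresholds and the sinus-arrest reference are
  working conventions pending zebrafish reference data.
* Multichannel records are analyzed per channel; no cross-channel fusion.
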