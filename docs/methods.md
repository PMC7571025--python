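# Methods

This note documents the models, algorithmic choices and limitations of
`cogload`, stage by stage. Defaults are stated with units; anything
configurable is exposed through the dataclasses in `cogload.types`,
`cogload.synthetic` and `cogload.selection`.

## Signals and inclusion rule

The unit of analysis is one subject-condition minute: an RR-interval
series (ms) and a multichannel EEG segment (µV). The RR series must
contain at least 80 intervals; longer series are truncated to the
*first* 80 (the earliest task response is preserved and the choice is
deterministic), shorter ones raise `SubjectExcluded` — a signaled
outcome the cohort assembly logs and skips, not an error.

## R-peak detection

`detect_r_peaks` is a member of the wavelet family of QRS detectors:

* stationary wavelet transform (db4) of the mean-removed trace; detail
  levels whose nominal band [fs/2^(j+1), fs/2^j] overlaps 5–20 Hz are
  squared and summed into an envelope, smoothed by a 100 ms moving
  average. The SWT is computed on an edge-padded copy (margin ≈ 8×2^L
  samples) because the transform is periodic and boundary wrap-around
  otherwise fakes QRS energy at the edges;
* adaptive threshold per non-overlapping 2 s window: k × window RMS,
  k = 1.5 by default; a trailing stub shorter than half a window merges
  with its predecessor (its own RMS would be edge-dominated);
* each supra-threshold region contributes one candidate, refined to the
  local maximum of a 30 Hz low-passed copy of the raw trace within
  ±50 ms (plus a hill-climb to the exact maximum);
* a 250 ms refractory period keeps the stronger of two close candidates.

Accuracy is verified against ground-truth beat positions of a toy ECG
(Gaussian bumps + white noise): at 10 dB SNR (power ratio), ≥99% of
peaks land within ±2 samples at fs = 250 Hz. The detector is *not*
validated on pathological rhythms or real artifact; ectopic-beat
handling is out of scope.

## HRV features (27)

Time domain: SDRR (population SD — fixed, documented choice), RMSSD,
Mean, Area (= Σ RR), MFD, pNN20/pNN10 (strict `>`), HRVC = SDRR/Mean.
**MFD** is implemented as the mean *absolute* first difference: the
signed mean telescopes to (RR_n − RR_1)/(n−1), which carries no
fluctuation information, while the feature is meant to measure the
average fluctuation of autonomic activity.

Frequency domain: the tachogram (interval value at each cumulative beat
time) is cubic-spline resampled at 4 Hz, mean-removed and analysed with
a single-segment Hann periodogram; VLF/LF/HF/TOTPWR integrate
[0, 0.04), [0.04, 0.15), [0.15, 0.4), [0, 0.4) Hz in ms². The spline +
Welch route (rather than Lomb–Scargle) was chosen for ubiquity and
determinism. An 80-interval minute supports barely one VLF cycle;
a low-frequency-support warning is emitted and VLF should be read with
that caveat. LF/HF is NaN (never ∞) when HF = 0.

Entropies (tunable (m, r, τ, scale), defaults = tuned task-vs-rest
values): ApEn (Chebyshev distance, self-matches included), SampEn (no
self-matches), PeEn (ordinal-pattern Shannon entropy normalized by
ln m!, so the value lies in [0, 1]), and MFEn — a multiscale fuzzy
measure entropy: the series is coarse-grained by non-overlapping means
of width `scale`, then a local (templates centred on their own mean)
and a global (centred on the series mean) fuzzy entropy with
exponential membership exp(−(d/r)²) are summed with equal weight.
Tolerances are either a factor × SDRR or absolute on the z-scored
series; a zero-variance series makes the tolerance degenerate and
raises `FeatureUndefinedError`.

DFA-1 with least-squares detrending per non-overlapping box: α1 from
box sizes 4–16, α2 from 16–32 (hence ≥64 intervals required), both as
log–log regression slopes. TFC sums, over coarse-graining scales
s = 1..M (M = 10), the mean absolute successive difference of the
scale-s series divided by the series mean — scale-free by construction;
this coarse-grained-fluctuation definition is an interpretation (the
source formula is only cited in the literature) and nothing downstream
depends on its absolute value, only on oracle equivalence and
invariances. RLHE is the max − min of windowed DFA-α1 exponents
(window 32, step 4) — again an interpretation of "local Hurst
exponents" with the window geometry exposed as configuration. Poincaré:
SD1² = mean(ΔRR²)/2 (uncentered, making SD1 = RMSSD/√2 an exact
identity), SD2² = 2·var(RR) − SD1², clipped at zero with a warning.

## EEG features (6 per channel)

Welch band powers (2 s Hann windows, 50% overlap → 0.5 Hz resolution)
over the protocol's printed edges: δ 1–4, θ 4.1–5.8, α 5.9–7.4,
β 13–19.9, γ 20–25 Hz. The θ/α/γ edges are nonstandard but are applied
exactly as defined, and the gaps between bands belong to no band; a
`bands` argument switches to conventional edges when wanted. Powers are
absolute (µV²), not normalized. Wavelet entropy is the Shannon entropy
of relative energies across the 128 terminal nodes of a 7-level db4
wavelet-packet decomposition; it is amplitude-invariant and ranges from
≈0 (single-node energy) to ln 128 (flat spectrum).

## Entropy-parameter tuning

For each entropy feature a grid (m 1–3 and r 0.1–0.9 — ×SDRR for ApEn,
absolute for SampEn/MFEn; m 3–7 for PeEn) is scored by the two-sided
Mann–Whitney U p-value between the two groups of the problem; the
argmin-p point wins, with ties broken toward smaller m then smaller r
(parsimony), and the result is flagged non-significant when even the
best p ≥ 0.05. The exact U distribution is used when n_A·n_B ≤ 400 and
the data are tie-free, the tie-corrected normal approximation
otherwise. No multiple-testing correction is applied across grid points
(deliberately, matching the protocol). τ is the first strict local
minimum of the lagged mutual information (2-D histogram, √n bins per
axis); a flat or monotone MI curve falls back to τ = 1 with a warning.
For white noise this "first minimum" is an order statistic of noise and
lands at lag 1 only about half the time (≤3 in ≈95% of runs) — an
inherent property of the estimator, reflected in the tests.

## Balancing

Borderline-SMOTE1, implemented in `cogload.datasets`: a minority sample
is *borderline* when more than half, but not all, of its k = 5 nearest
neighbours (Euclidean, full table) are majority; synthetic rows are
uniform interpolations between a borderline sample and one of its
minority neighbours, until the minority count reaches the target. If no
borderline sample exists the generator falls back to plain SMOTE over
all minority samples, with a warning. Original rows are never modified;
synthetic rows carry `synthetic = 1` and the subject id of their seed
sample, so LOSO folds exclude them together with their subject. By
default balancing happens once, globally, before selection (matching
the protocol's order); note the leakage caveat: synthetic rows derived
from neighbours of a later-held-out subject can transport information
across folds. Callers wanting strict leakage safety can balance inside
training folds instead (`RunConfig(balance=False)` plus per-fold
balancing of their own).

## Selection and evaluation

LOSO fitness z-scores the masked features by training-fold statistics;
a fold whose training set lacks a class is skipped with a warning and
excluded from the denominator. SBS reads "least important feature" as
the greedy rule: remove the feature whose removal yields the highest
f1, ties removing the larger column index. Binary PSO uses P = 30
particles, T = 50–100 iterations (smaller values are fine for small
tables), ω = 0.7298, C1 = C2 = 2, velocities clamped to ±4, and — since
the binarization is not specified by the protocol — the standard
sigmoid transfer with per-dimension Bernoulli draws; all-zero positions
are repaired by activating one random bit, and a mask-level cache makes
repeated positions free. The hybrid runs PSO first and SBS within the
PSO-selected features. `cap_select` returns the highest-f1 trajectory
entry with dimension ≤ 4 (ties → smaller dimension).

Classifiers (hyperparameters are not fixed by the protocol; these
defaults are logged and overridable): SVM with inhomogeneous degree-2
polynomial kernel or RBF (width 1/dimension), cost 1; KNN with k = 5
and Euclidean distance weighting; Gini decision tree of unlimited
depth. Metrics follow the protocol's printed formulas, including the
nonstandard F1 (harmonic mean of Sens and Spec) and AUC
((Sens + Spec)/2 — balanced accuracy); `conventional=True` yields the
standard precision/recall F1, but a conventional ROC AUC cannot be
derived from confusion counts and is not offered. Zero denominators
yield NaN plus an `undefined` flag, never a silent zero. Run reports
are JSON-serializable and byte-identical under a fixed seed; wall-clock
timing is deliberately kept out of them.

## Synthetic cohorts

The generator targets only quantities the analysis relies on, and
exposes everything else as configuration:

* cohort: 24 good-count + 12 bad-count subjects (split threshold 10
  accurate calculations — the boundary implied by the two groups'
  21 ± 7.4 vs 7 ± 3.6 counts), each with BL and CL conditions;
* RR series: mean + SD × (√(1−w²)·oscillation + w·white jitter), the
  oscillation a ~0.1 Hz modulation with random phase/frequency, clipped
  to the 250–2000 ms physiological guard. The jitter weight w is
  calibrated once per condition by bisection on Monte-Carlo mean
  ApEn(m = 2, r = 0.4·SDRR) (200 draws on common random numbers,
  tolerance 0.02), so the population mean ApEn hits the configured
  target — 0.67 under load, 0.78 at baseline by default. Only the mean
  is calibrated; the across-subject ApEn SD emerges from sampling
  variability and is smaller than in real cohorts;
* RR level defaults: BL 745 ± 45 ms, CL 700 ± 35 ms — heart rate rises
  and variability falls under load, and both rates are compatible with
  the ≥80 beats/min inclusion rule;
* EEG: per channel, a sum of FFT-band-limited Gaussian noise components
  (one per analysis band; δ strongest) at 250 Hz — the lowest common
  rate supporting the 45 Hz content of the source recordings — with the
  beta component's variance multiplied by `beta_power_gain` (default
  2.0 under load).

What the generator does **not** emulate: ECG waveform morphology (a
separate toy-ECG op exists for detector testing), respiration and its
coupling into HF power, artifacts, 1/f EEG background, cross-channel
correlation, or any time/frequency-domain group statistics beyond the
RR level/variability defaults. Passing pipeline tests on these cohorts
therefore demonstrates that the machinery recovers planted structure at
realistic sample sizes — not that real recordings would be classified
with the same accuracy.

## Problem sizes in the test suite

Tests run the pipeline on reduced cohorts (typically 10–12 subjects,
1–3 EEG channels, 10–12 s segments) and reduced swarm sizes (P = 10–12,
T = 5–10): these sizes already make every asserted effect detectable,
and they keep the suite quick to iterate on. The full-size defaults
(36 subjects, 19 channels, 60 s, P = 30, T = 50–100) are exercised for
structure (counts, shapes) rather than end-to-end accuracy.

## Known limitations

* The exact feature subsets of the source analysis depend on the real
  recordings and are not reproduced; only the procedures are.
* PeEn at m = 6 on 75 templates is heavily undersampled (720 possible
  patterns); it is computed as specified, but its absolute value on
  80-interval series is biased low.
* Global balancing before LOSO (the default, protocol-faithful order)
  is not leakage-free; see above.
* EDF ingestion assumes channel naming close to the 10/20 labels and is
  exercised only lightly.
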