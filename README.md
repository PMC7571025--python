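# cogload

Subject-independent recognition of cognitive-load states from heart-rate
variability (HRV) and EEG features.

## What this package is for

When a learner works on a mentally demanding task, the autonomic nervous
system shifts (heart rate rises, beat-to-beat variability drops and
becomes more regular) and cortical activity changes (beta-band EEG power
grows). `cogload` implements a complete, tested pipeline that turns raw
one-minute ECG/EEG segments into binary classifications of:

* **task vs. rest** — cognitive load (CL) vs. baseline (BL);
* **load mismatch vs. match** — task-period states of poor performers
  (CLMM) vs. good performers (CLM),

validated *subject-independently*: every test fold holds out all samples
of one subject (leave-one-subject-out, LOSO).

It is aimed at psychophysiology / affective-computing researchers who
want the individual stages (HRV feature extraction, entropy-parameter
tuning, wrapper feature selection) as reusable, verifiable components.

## The method

1. **ECG → RR.** R peaks are located by a stationary-wavelet QRS
   envelope with an adaptive RMS threshold; series without 80 RR
   intervals in the minute are excluded, longer ones truncated to 80.
2. **Features.** 27 HRV features (time domain, Welch band powers of the
   4 Hz-resampled tachogram, ApEn/SampEn/PeEn/MFEn, DFA α1/α2, total
   fluctuation coefficient, Poincaré SD1/SD2, local-Hurst range) and 6
   EEG features per channel (δ/θ/α/β/γ band powers and wavelet-packet
   entropy, rendered `BP_F4`-style).
3. **Entropy tuning.** Embedding dimension m and tolerance r are chosen
   per problem as the grid point with the smallest two-sided
   Mann–Whitney U p-value between the two groups; the delay τ comes from
   the first local minimum of lagged mutual information.
4. **Balancing.** The 1:2-unbalanced matching problem is balanced by
   Borderline-SMOTE1 (interpolation near the class boundary).
5. **Selection.** Wrapper search over feature masks x⃗ ∈ {0,1}^M scored
   by LOSO accuracy f1 = Σ n_correct / n_total: sequential backward
   selection (SBS), binary particle swarm optimization minimizing
   f2 = α·(#Features/#AllFeatures) + (1−α)·(ErrorRate/ER) with α = 0.8,
   or PSO followed by SBS; a dimension cap (default 4) picks the final
   subset.
6. **Evaluation.** SVM (quadratic / RBF), KNN and decision-tree
   classifiers; metrics from the confusion counts, including the
   protocol's definitions F1 = 2·Sens·Spec/(Sens+Spec) and
   AUC = (Sens+Spec)/2.

A synthetic-cohort generator reproduces the statistical structure the
analysis assumes (24/12 performance split, 80-interval RR series with
condition-calibrated approximate entropy, beta-power EEG contrast), so
the whole pipeline is testable without any recordings.

## Worked example

`examples/07_full_model.py` generates a strongly contrasted 12-subject
cohort and runs the task-vs-rest model on HRV features:

```text
selected features: ['SDRR']
LOSO f1 = 1.000 over 24 samples
confusion: TP=12 FN=0 FP=0 TN=12
metrics: {'Sens': 1.0, 'Spec': 1.0, 'Prec': 1.0, 'Acc': 1.0, 'F1': 1.0, 'AUC': 1.0}
```

The pipeline tuned the entropy parameters, ran SBS under the dimension
cap, and found that a single variability feature separates the two
conditions of this synthetic cohort perfectly under LOSO — every one of
the 24 subject-condition samples is classified correctly when its
subject is held out. The other scripts in `examples/` exercise each
stage on its own (simulation, R-peak detection, HRV and EEG features,
entropy tuning, balancing + selection).

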