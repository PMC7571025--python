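"""Detect R peaks in a noisy toy ECG and apply the 80-interval rule.

The detector combines a stationary-wavelet QRS envelope, an adaptive
RMS threshold and a 250 ms refractory period.
"""

import numpy as np

import cogload as cg

# 85 beats in ~64 s, with timing jitter and measurement noise
rng = np.random.default_rng(0)
beat_times = np.cumsum(rng.normal(0.75, 0.04, 85))
ecg = cg.synthetic_ecg(beat_times, fs=250.0, noise_sd=0.05, seed=1)

peaks = cg.detect_r_peaks(ecg)
rr = cg.to_rr_series(peaks, ecg.fs, subject_id="demo", condition="CL")
print(f"detected {len(peaks)} peaks -> {len(rr)} RR intervals")
print(f"mean RR {np.mean(rr.intervals):.0f} ms "
      f"(true beat period {np.mean(np.diff(beat_times)) * 1000:.0f} ms)")

kept = cg.apply_length_rule(rr, required_length=80)
print(f"after the inclusion rule: {len(kept)} intervals (first 80 kept)")
# A subject whose minute yields fewer than 80 intervals would instead
# raise SubjectExcluded and be dropped from the cohort.
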