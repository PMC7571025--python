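"""Per-channel EEG band powers and wavelet-packet entropy.

The beta band (13-19.9 Hz) carries the load effect in the synthetic
generator: its power roughly doubles under the CL condition.
"""

import cogload as cg

sub = cg.SubjectRecord("S01", "F", "G", 20)
cfg = cg.CohortConfig(eeg_channels=("F4", "Cz"), segment_duration=10.0)

for cond in ("BL", "CL"):
    seg = cg.generate_eeg_segment(cond, sub, cfg, seed=5)
    feats = cg.eeg.extract_all(seg)
    print(f"{cond}:  BP_F4 {feats['BP_F4']:7.2f} uV^2   "
          f"DP_F4 {feats['DP_F4']:7.2f} uV^2   WE_F4 {feats['WE_F4']:.3f}")
# BP (beta power) separates the conditions; DP (delta) and the wavelet
# entropy WE are condition-independent in this generator.
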