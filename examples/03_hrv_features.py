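"""The full 27-feature HRV vector of one 80-interval RR series."""

import numpy as np

import cogload as cg

sub = cg.SubjectRecord("S01", "F", "G", 20)
rr = cg.generate_rr_series("CL", sub, cg.CohortConfig(), seed=3)

feats = cg.hrv.extract_all(rr)
print(f"{len(feats)} features extracted\n")
for name in ("Mean", "SDRR", "RMSSD", "LF", "HF", "LF/HF",
             "ApEn", "SampEn", "DFA_alpha1", "SD1", "TFC"):
    print(f"  {name:12s} {feats[name]:10.4f}")

print("\nidentities:")
print(f"  SD1 = RMSSD/sqrt(2): {feats['SD1']:.4f} "
      f"= {feats['RMSSD'] / np.sqrt(2):.4f}")
print(f"  LF/(LF+HF) + HF/(LF+HF) = "
      f"{feats['LF/(LF+HF)'] + feats['HF/(LF+HF)']:.4f}")
# Mean/Area track overall autonomic level, the band powers split the
# tachogram spectrum, and the entropy/fractal block quantifies how
# regular the beat-to-beat dynamics are.
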