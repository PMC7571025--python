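"""Choose entropy parameters (m, r) by Mann-Whitney discrimination.

For every grid point the entropy is computed on both condition groups;
the chosen parameters minimize the two-sided U-test p-value.
"""

import cogload as cg

cfg = cg.CohortConfig(n_good=6, n_bad=3, eeg_channels=("Cz",),
                      segment_duration=2.0, seed=11)
cohort = cg.generate_cohort(cfg)

cl = [cohort.rr[(s.subject_id, "CL")] for s in cohort.subjects]
bl = [cohort.rr[(s.subject_id, "BL")] for s in cohort.subjects]

res = cg.tune_feature("ApEn", cl, bl)
print(f"ApEn: m={res.params.m}, r={res.params.r:.1f}x SDRR, "
      f"p={res.p_value:.4g}, significant={res.significant}")
print(f"grid explored: {len(res.table)} points")
# A significant point means the entropy feature, at those parameters,
# separates the cognitive-load and baseline groups.
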