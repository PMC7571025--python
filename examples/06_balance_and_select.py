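"""Balance an unbalanced problem and select features by SBS under LOSO.

The matching problem (CLMM vs CLM) is 1:2 unbalanced; Borderline-SMOTE1
interpolates new minority samples near the class boundary before the
wrapper selection runs.
"""

import numpy as np
import pandas as pd

import cogload as cg

# a small toy table: 6 CLMM vs 12 CLM subjects, 5 features, one informative
rng = np.random.default_rng(2)
rows = []
for i in range(18):
    label = "CLMM" if i < 6 else "CLM"
    vals = rng.normal(0, 1, 5)
    if label == "CLMM":
        vals[0] += 3.0  # feat0 carries the group difference
    rows.append({"subject_id": f"S{i:02d}", "label": label,
                 **{f"feat{j}": v for j, v in enumerate(vals)}})
table = cg.FeatureTable(pd.DataFrame(rows))

print("before balancing:", table.class_counts())
balanced = cg.borderline_smote1(table, 12, seed=0)
print("after balancing: ", balanced.class_counts())

traj = cg.sbs(balanced, cg.ClassifierSpec("DT"))
for step in traj:
    names = step.mask.selected_names(balanced.feature_names)
    print(f"  dim {step.dimension}: f1={step.f1:.3f}  {names}")

mask, f1 = cg.cap_select(traj, max_dim=4)
print("selected (cap 4):", mask.selected_names(balanced.feature_names),
      f"f1={f1:.3f}")
# The informative feature survives to the end of the elimination.
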