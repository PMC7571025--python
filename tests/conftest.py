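import numpy as np
import pandas as pd
import pytest

import cogload as cg


def make_table(n_subjects=10, n_features=6, informative=0, sep=4.0,
               rows_per_subject=1, seed=0, labels=("CL", "BL"),
               feature_names=None):
    """Toy feature table: noise columns plus optional informative columns.

    Subjects alternate between the two labels (subject-disjoint classes);
    informative columns are shifted by ``sep`` for the first label.
    """
    rng = np.random.default_rng(seed)
    if feature_names is None:
        feature_names = [f"feat{j}" for j in range(n_features)]
    rows = []
    for i in range(n_subjects):
        label = labels[i % 2]
        for _ in range(rows_per_subject):
            vals = rng.normal(0.0, 1.0, n_features)
            if label == labels[0]:
                vals[:informative] += sep
            rows.append({"subject_id": f"S{i:02d}", "label": label,
                         **dict(zip(feature_names, vals))})
    return cg.FeatureTable(pd.DataFrame(rows))


def make_paired_table(n_subjects=4, n_features=3, seed=0):
    """Each subject contributes one row per condition (CL and BL)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for label in ("CL", "BL"):
            rows.append({"subject_id": f"S{i:02d}", "label": label,
                         **{f"feat{j}": rng.normal() for j in range(n_features)}})
    return cg.FeatureTable(pd.DataFrame(rows))


SEPARABLE_TARGETS = {
    "BL": cg.ConditionTarget(apen_mean=0.78, apen_sd=0.14, beta_power_gain=1.0,
                             mean_rr_ms=800.0, sd_rr_ms=45.0),
    "CL": cg.ConditionTarget(apen_mean=0.55, apen_sd=0.16, beta_power_gain=3.0,
                             mean_rr_ms=650.0, sd_rr_ms=30.0),
}


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort with strong condition effects (separable setting)."""
    cfg = cg.CohortConfig(n_good=8, n_bad=4, eeg_channels=("F4", "Cz", "O1"),
                          segment_duration=12.0,
                          condition_targets=SEPARABLE_TARGETS, seed=7)
    return cg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_subject():
    return cg.SubjectRecord("S01", "F", "G", 20)
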