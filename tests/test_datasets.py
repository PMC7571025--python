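"""Problem assembly (models A–F) and Borderline-SMOTE1 balancing."""

import numpy as np
import pandas as pd
import pytest

import cogload as cg
from conftest import make_table
from cogload.types import ConfigurationError


def _cohort_table(n_good, n_bad, n_eeg_channels=2, seed=0):
    """Subject-condition table with full HRV + EEG column sets."""
    rng = np.random.default_rng(seed)
    channels = ["F4", "O1", "Cz"][:n_eeg_channels]
    eeg_cols = [f"{k}_{c}" for c in channels for k in cg.EEG_FEATURE_KINDS]
    cols = list(cg.HRV_FEATURE_NAMES) + eeg_cols
    subjects, rows = [], []
    for i in range(n_good + n_bad):
        grp = "G" if i < n_good else "B"
        sid = f"S{i:02d}"
        subjects.append(cg.SubjectRecord(sid, "F", grp, 20 if grp == "G" else 5))
        for cond in ("CL", "BL"):
            rows.append({"subject_id": sid, "label": cond,
                         **{c: rng.normal() for c in cols}})
    return cg.FeatureTable(pd.DataFrame(rows)), subjects


def test_clmm_clm_counts_from_default_split():
    table, subjects = _cohort_table(24, 12)
    out = cg.build_problem(table, cg.MODEL_SPECS["D"], subjects)
    assert out.class_counts() == {"CLM": 24, "CLMM": 12}


def test_cl_bl_counts_on_27_subjects():
    table, subjects = _cohort_table(18, 9)
    out = cg.build_problem(table, cg.MODEL_SPECS["A"], subjects)
    assert out.class_counts() == {"CL": 27, "BL": 27}


def test_hrv_model_has_27_feature_columns():
    table, subjects = _cohort_table(4, 2)
    out = cg.build_problem(table, cg.MODEL_SPECS["A"], subjects)
    assert len(out.feature_names) == 27
    assert tuple(out.feature_names) == cg.HRV_FEATURE_NAMES


def test_eeg_model_excludes_hrv_columns():
    table, subjects = _cohort_table(4, 2)
    out = cg.build_problem(table, cg.MODEL_SPECS["E"], subjects)
    assert not set(out.feature_names) & set(cg.HRV_FEATURE_NAMES)
    assert len(out.feature_names) == 12  # 6 kinds × 2 channels


def test_build_problem_drops_subjects_missing_a_condition(caplog):
    table, subjects = _cohort_table(3, 2)
    df = table.df[~((table.df.subject_id == "S00") & (table.df.label == "BL"))]
    out = cg.build_problem(cg.FeatureTable(df), cg.MODEL_SPECS["A"], subjects)
    assert "S00" not in set(out.subjects)
    assert out.class_counts() == {"CL": 4, "BL": 4}


def test_build_problem_is_deterministic_and_idempotent():
    table, subjects = _cohort_table(4, 2)
    a = cg.build_problem(table, cg.MODEL_SPECS["F"], subjects)
    b = cg.build_problem(table, cg.MODEL_SPECS["F"], subjects)
    assert a.df.equals(b.df)


def test_unknown_subject_rejected():
    table, _ = _cohort_table(2, 2)
    with pytest.raises(ConfigurationError):
        cg.build_problem(table, cg.MODEL_SPECS["A"], [])


# ------------------------------------------------------------------- SMOTE

def _imbalanced(n_min=9, n_maj=18, n_features=4, seed=0, spread=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_min):
        rows.append({"subject_id": f"m{i}", "label": "CLMM",
                     **{f"f{j}": rng.normal(0, spread) for j in range(n_features)}})
    for i in range(n_maj):
        rows.append({"subject_id": f"M{i}", "label": "CLM",
                     **{f"f{j}": rng.normal(0.5, spread) for j in range(n_features)}})
    return cg.FeatureTable(pd.DataFrame(rows))


@pytest.mark.parametrize("seed", [0, 1, 17])
def test_minority_expands_to_exact_target(seed):
    out = cg.borderline_smote1(_imbalanced(seed=seed), 18, seed=seed)
    assert out.class_counts() == {"CLM": 18, "CLMM": 18}


def test_balanced_table_returned_unchanged():
    table = _imbalanced(n_min=10, n_maj=10)
    out = cg.borderline_smote1(table, 10, seed=0)
    assert out.df.equals(table.df)


def test_original_rows_preserved_verbatim():
    table = _imbalanced()
    out = cg.borderline_smote1(table, 18, seed=3)
    assert out.df.iloc[: len(table.df)].equals(table.df)
    assert (out.df["synthetic"].iloc[len(table.df):] == 1).all()


def test_synthetic_rows_lie_on_minority_segments():
    table = _imbalanced(seed=5)
    out = cg.borderline_smote1(table, 18, seed=5)
    originals = table.df[table.df.label == "CLMM"][table.feature_names].to_numpy()
    synth = out.df[out.df.synthetic == 1][table.feature_names].to_numpy()
    for row in synth:
        on_segment = False
        for a in range(len(originals)):
            for b in range(len(originals)):
                if a == b:
                    continue
                d = originals[b] - originals[a]
                denom = d[np.abs(d) > 1e-12]
                if denom.size == 0:
                    continue
                u = (row - originals[a])[np.abs(d) > 1e-12] / denom
                if np.allclose(u, u[0]) and -1e-9 <= u[0] <= 1 + 1e-9:
                    on_segment = True
        assert on_segment


def test_synthetic_rows_inherit_seed_subject_id():
    table = _imbalanced()
    out = cg.borderline_smote1(table, 18, seed=2)
    minority_subjects = set(table.df[table.df.label == "CLMM"].subject_id)
    synth_subjects = set(out.df[out.df.synthetic == 1].subject_id)
    assert synth_subjects <= minority_subjects


def test_isolated_minority_falls_back_to_plain_smote():
    # minority far from majority: no borderline samples exist
    rng = np.random.default_rng(7)
    rows = [{"subject_id": f"m{i}", "label": "CLMM",
             **{f"f{j}": rng.normal(100, 0.1) for j in range(3)}} for i in range(5)]
    rows += [{"subject_id": f"M{i}", "label": "CLM",
              **{f"f{j}": rng.normal(0, 0.1) for j in range(3)}} for i in range(10)]
    with pytest.warns(UserWarning, match="plain SMOTE"):
        out = cg.borderline_smote1(cg.FeatureTable(pd.DataFrame(rows)), 10, seed=0)
    assert out.class_counts() == {"CLM": 10, "CLMM": 10}


def test_feature_table_roundtrip_with_synthetic_flag(tmp_path):
    from cogload.io import read_feature_table, write_feature_table
    out = cg.borderline_smote1(_imbalanced(), 18, seed=1)
    path = write_feature_table(out, tmp_path / "features.csv")
    back = read_feature_table(path)
    assert back.df["synthetic"].sum() == 9
    np.testing.assert_allclose(back.X, out.X)
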