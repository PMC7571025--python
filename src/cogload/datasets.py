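"""Problem assembly and minority-class balancing.

``build_problem`` turns a per-subject-condition feature table into one of
the two binary problems:

* CL_vs_BL — every subject's task ('CL') and baseline ('BL') rows;
* CLMM_vs_CLM — task rows only, relabeled 'CLMM' for bad-count ('B')
  performers and 'CLM' for good-count ('G') performers,

restricted to the requested signal family (HRV columns, per-channel EEG
columns, or both).

``borderline_smote1`` balances the minority class by interpolating new
samples near the class boundary: minority samples whose k nearest
neighbours (in the full table) are more than half — but not all —
majority are 'borderline'; synthetic rows are drawn uniformly on segments
between a borderline sample and one of its minority neighbours.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .types import (ConfigurationError, EEG_FEATURE_KINDS, FeatureTable,
                    HRV_FEATURE_NAMES, ModelSpec, SubjectRecord)

__all__ = ["build_problem", "borderline_smote1", "split_signal_columns"]

log = logging.getLogger(__name__)


def split_signal_columns(feature_names: Sequence[str]) -> dict:
    """Partition feature columns into the HRV and EEG families."""
    hrv_cols = [c for c in feature_names if c in HRV_FEATURE_NAMES]
    eeg_cols = [c for c in feature_names
                if c.split("_")[0] in EEG_FEATURE_KINDS and "_" in c]
    return {"HRV": hrv_cols, "EEG": eeg_cols}


def build_problem(table: FeatureTable, spec: ModelSpec,
                  cohort: Sequence[SubjectRecord]) -> FeatureTable:
    """Assemble the sample set of one model from a subject-condition table.

    ``table`` rows must be labeled 'CL' or 'BL'.  Subjects present in the
    table but missing a required condition are dropped with a log entry.
    Deterministic and idempotent: rows keep their original order.
    """
    groups = {s.subject_id: s.performance_group for s in cohort}
    unknown = set(table.subjects) - set(groups)
    if unknown:
        raise ConfigurationError(f"subjects not in cohort: {sorted(unknown)}")

    df = table.df
    fam = split_signal_columns(table.feature_names)
    if spec.signals == "HRV":
        cols = fam["HRV"]
    elif spec.signals == "EEG":
        cols = fam["EEG"]
    else:
        cols = fam["HRV"] + fam["EEG"]
    if not cols:
        raise ConfigurationError(f"no {spec.signals} columns in table")

    if spec.problem == "CL_vs_BL":
        keep = df[df["label"].isin(["CL", "BL"])].copy()
        # drop subjects lacking either condition
        counts = keep.groupby("subject_id")["label"].nunique()
        incomplete = counts[counts < 2].index.tolist()
        for sid in incomplete:
            log.info("subject %s dropped: missing a condition", sid)
        keep = keep[~keep["subject_id"].isin(incomplete)]
    else:  # CLMM_vs_CLM: task-condition rows only, relabeled by group
        keep = df[df["label"] == "CL"].copy()
        keep["label"] = keep["subject_id"].map(
            lambda sid: "CLMM" if groups[sid] == "B" else "CLM")
    return FeatureTable(keep[list(FeatureTable.RESERVED) + cols], cols)


def _k_nearest(X: np.ndarray, i: int, pool: np.ndarray, k: int) -> np.ndarray:
    """Indices (into ``pool``) of the k nearest pool points to X[i]."""
    d = cdist(X[i: i + 1], X[pool])[0]
    order = np.argsort(d, kind="stable")
    return pool[order[:k]]


def borderline_smote1(table: FeatureTable, target_per_class: int,
                      k: int = 5, seed: int = 0) -> FeatureTable:
    """Oversample the minority class to ``target_per_class`` rows.

    Original rows are preserved verbatim; synthetic rows carry the
    subject_id of their seed sample (so LOSO folds exclude them together)
    and ``synthetic=1``.  When no borderline sample exists the generator
    falls back to plain SMOTE over all minority samples, with a warning.
    """
    counts = table.class_counts()
    if len(counts) != 2:
        raise ConfigurationError("balancing requires exactly two classes")
    minority = min(counts, key=counts.get)
    n_min = counts[minority]
    if n_min < 2:
        raise ConfigurationError("minority class needs >= 2 samples")
    n_new = target_per_class - n_min
    if n_new <= 0:
        return table.copy()

    X = table.X
    y = table.y
    min_idx = np.flatnonzero(y == minority)
    all_idx = np.arange(len(y))

    # danger zone: more than half, but not all, of the k NN are majority
    danger = []
    for i in min_idx:
        pool = all_idx[all_idx != i]
        nn = _k_nearest(X, i, pool, min(k, len(pool)))
        n_maj = int(np.sum(y[nn] != minority))
        if k / 2 < n_maj < min(k, len(pool)):
            danger.append(i)
    if not danger:
        warnings.warn("no borderline minority samples; falling back to plain SMOTE")
        danger = list(min_idx)

    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_new):
        b = danger[int(rng.integers(len(danger)))]
        pool = min_idx[min_idx != b]
        nn = _k_nearest(X, b, pool, min(k, len(pool)))
        p = nn[int(rng.integers(len(nn)))]
        u = float(rng.uniform())
        new = X[b] + u * (X[p] - X[b])
        row = {"subject_id": table.df.loc[b, "subject_id"],
               "label": minority, "synthetic": 1}
        row.update(dict(zip(table.feature_names, new)))
        rows.append(row)

    out = pd.concat([table.df, pd.DataFrame(rows)], ignore_index=True)
    return FeatureTable(out, list(table.feature_names))
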