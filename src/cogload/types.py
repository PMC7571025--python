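"""Core domain types shared across the pipeline.

The pipeline moves data through a small set of containers: raw ECG traces
become RR-interval series, multichannel EEG segments become per-channel
feature values, and both end up as rows of a :class:`FeatureTable` on which
balancing, wrapper feature selection and leave-one-subject-out (LOSO)
evaluation operate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CogloadError",
    "ConfigurationError",
    "DetectionError",
    "FeatureUndefinedError",
    "SubjectExcluded",
    "ECGTrace",
    "RRSeries",
    "EEGSegment",
    "SubjectRecord",
    "EntropyParams",
    "FeatureTable",
    "ModelSpec",
    "ClassifierSpec",
    "ConfusionCounts",
    "MODEL_SPECS",
    "HRV_FEATURE_NAMES",
    "EEG_FEATURE_KINDS",
]


class CogloadError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(CogloadError):
    """Invalid or inconsistent configuration."""


class DetectionError(CogloadError):
    """R-peak detection could not run on the given trace."""


class FeatureUndefinedError(CogloadError):
    """A feature is undefined for the given input (too short, degenerate...)."""


class SubjectExcluded(CogloadError):
    """Signaled outcome: a subject's series fails an inclusion rule.

    Not a failure of the pipeline — callers catch it and drop the subject.
    """


@dataclass(frozen=True)
class ECGTrace:
    """A single-lead ECG recording in millivolts."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat (R-to-R) intervals in milliseconds."""

    intervals: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.size and np.any(iv <= 0):
            raise ConfigurationError("RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals)

    def with_intervals(self, intervals) -> "RRSeries":
        return RRSeries(np.asarray(intervals, dtype=float), self.subject_id, self.condition)


@dataclass(frozen=True)
class EEGSegment:
    """Multichannel EEG samples (µV), channels × time."""

    samples: np.ndarray
    fs: float
    channel_labels: tuple
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        x = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if len(self.channel_labels) != x.shape[0]:
            raise ConfigurationError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel labels must be unique")
        if self.fs <= 50:
            raise ConfigurationError("EEG sampling rate must exceed 50 Hz")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: performance group follows the accurate-count split."""

    subject_id: str
    sex: str  # 'F' or 'M'
    performance_group: str  # 'G' (good count) or 'B' (bad count)
    accurate_count: int  # accurate calculations per 4 min

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ConfigurationError("sex must be 'F' or 'M'")
        if self.performance_group not in ("G", "B"):
            raise ConfigurationError("performance_group must be 'G' or 'B'")
        if self.accurate_count < 0:
            raise ConfigurationError("accurate_count must be nonnegative")


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the regularity statistics (ApEn/SampEn/PeEn/MFEn).

    ``r`` is a tolerance: with ``r_mode='sdrr'`` it is a factor multiplied by
    the series SD; with ``r_mode='absolute'`` it applies to the z-scored
    series directly (equivalently, it is expressed in SD units).
    ``scale`` is the coarse-graining width used by the multiscale fuzzy
    measure entropy only.
    """

    m: int = 2
    r: float = 0.2
    r_mode: str = "sdrr"  # 'sdrr' (factor × SDRR) or 'absolute'
    tau: int = 1
    scale: int = 1

    def __post_init__(self):
        if self.m < 1 or self.tau < 1 or self.scale < 1:
            raise ConfigurationError("m, tau and scale must be >= 1")
        if self.r <= 0:
            raise ConfigurationError("tolerance r must be positive")
        if self.r_mode not in ("sdrr", "absolute"):
            raise ConfigurationError("r_mode must be 'sdrr' or 'absolute'")


# Canonical HRV feature names, in table order.
HRV_FEATURE_NAMES = (
    "SDRR", "RMSSD", "Mean", "Area", "MFD", "pNN20", "pNN10", "HRVC",
    "VLF", "LF", "HF", "TOTPWR", "HF/(LF+HF)", "LF/(LF+HF)", "LF/HF",
    "PeEn", "ApEn", "MFEn", "SampEn",
    "DFA_alpha1", "DFA_alpha2", "alpha1/alpha2",
    "TFC", "SD1", "SD2", "SD1/SD2", "RLHE",
)

# Per-channel EEG feature kinds; rendered as '<kind>_<channel>' in tables.
EEG_FEATURE_KINDS = ("DP", "TP", "AP", "BP", "GP", "WE")


class FeatureTable:
    """Labeled samples × named features.

    Wraps a DataFrame with reserved columns ``subject_id``, ``label`` and
    ``synthetic`` (0 for measured rows, 1 for oversampled rows); all other
    columns are features.
    """

    RESERVED = ("subject_id", "label", "synthetic")

    def __init__(self, df: pd.DataFrame, feature_names: Sequence[str] | None = None):
        df = df.copy()
        if "synthetic" not in df.columns:
            df["synthetic"] = 0
        for col in ("subject_id", "label"):
            if col not in df.columns:
                raise ConfigurationError(f"feature table requires a '{col}' column")
        if feature_names is None:
            feature_names = [c for c in df.columns if c not in self.RESERVED]
        missing = [c for c in feature_names if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing feature columns: {missing}")
        self.feature_names = list(feature_names)
        self.df = df[list(self.RESERVED) + self.feature_names].reset_index(drop=True)
        if self.df[self.feature_names].isna().any().any():
            raise ConfigurationError("feature table contains missing values")

    # -- accessors -------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def class_counts(self) -> dict:
        return self.df["label"].value_counts().to_dict()

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        unknown = [n for n in names if n not in self.feature_names]
        if unknown:
            raise ConfigurationError(f"unknown features: {unknown}")
        return FeatureTable(self.df[list(self.RESERVED) + list(names)], list(names))

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.df.copy(), list(self.feature_names))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (f"FeatureTable({self.n_samples} samples, "
                f"{len(self.feature_names)} features, classes={self.class_counts()})")


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model definitions: a problem × a signal family."""

    name: str  # 'A'..'F'
    problem: str  # 'CL_vs_BL' or 'CLMM_vs_CLM'
    signals: str  # 'HRV', 'EEG' or 'HRV+EEG'

    def __post_init__(self):
        if self.problem not in ("CL_vs_BL", "CLMM_vs_CLM"):
            raise ConfigurationError("unknown problem")
        if self.signals not in ("HRV", "EEG", "HRV+EEG"):
            raise ConfigurationError("unknown signal family")

    @property
    def positive_label(self) -> str:
        # CL and CLM are the positive classes of the two problems.
        return "CL" if self.problem == "CL_vs_BL" else "CLM"

    @property
    def labels(self) -> tuple:
        return ("CL", "BL") if self.problem == "CL_vs_BL" else ("CLMM", "CLM")


MODEL_SPECS: Mapping[str, ModelSpec] = {
    "A": ModelSpec("A", "CL_vs_BL", "HRV"),
    "B": ModelSpec("B", "CL_vs_BL", "EEG"),
    "C": ModelSpec("C", "CL_vs_BL", "HRV+EEG"),
    "D": ModelSpec("D", "CLMM_vs_CLM", "HRV"),
    "E": ModelSpec("E", "CLMM_vs_CLM", "EEG"),
    "F": ModelSpec("F", "CLMM_vs_CLM", "HRV+EEG"),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four evaluated classifier families.

    kinds: 'SVM_quadratic', 'SVM_rbf', 'KNN', 'DT'.
    Hyperparameters not fixed by the study design are exposed through
    ``hyperparams`` and documented in the methods note.
    """

    kind: str
    hyperparams: tuple = ()  # sorted (key, value) pairs; use .params for a dict
    seed: int = 0

    KINDS = ("SVM_quadratic", "SVM_rbf", "KNN", "DT")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ConfigurationError(f"classifier kind must be one of {self.KINDS}")
        if isinstance(self.hyperparams, dict):
            object.__setattr__(self, "hyperparams",
                               tuple(sorted(self.hyperparams.items())))

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion counts with an explicit positive class."""

    TP: int
    TN: int
    FP: int
    FN: int
    positive_class: str = "CL"

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.total == 0:
            raise ConfigurationError("confusion counts must not be all zero")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def swapped(self) -> "ConfusionCounts":
        """The same predictions with the positive/negative roles exchanged."""
        return replace(self, TP=self.TN, TN=self.TP, FP=self.FN, FN=self.FP,
                       positive_class="(swapped)")
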