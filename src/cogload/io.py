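"""Plain-text persistence: cohort directories, feature tables, ECG/EEG CSV.

Cohort layout::

    cohort.json                     subject records + config summary
    <subject>_<condition>_rr.csv    one column: rr_ms
    <subject>_<condition>_eeg.csv   t_s + one column per 10/20 channel

Optional EDF ingestion (for the public mental-arithmetic recordings) uses
``mne`` and is imported lazily.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, CohortConfig, ConditionTarget
from .types import ConfigurationError, ECGTrace, EEGSegment, FeatureTable, RRSeries, SubjectRecord

__all__ = ["write_cohort", "read_cohort", "read_ecg_csv", "write_feature_table",
           "read_feature_table", "read_edf_ecg", "read_edf_eeg"]


def write_cohort(cohort: Cohort, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "subjects": [vars(s) for s in cohort.subjects],
        "conditions": list(cohort.conditions),
        "eeg_fs": cohort.config.eeg_fs,
        "rr_length": cohort.config.rr_length,
        "seed": cohort.config.seed,
    }
    (directory / "cohort.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for (sid, cond), rr in cohort.rr.items():
        pd.DataFrame({"rr_ms": rr.intervals}).to_csv(
            directory / f"{sid}_{cond}_rr.csv", index=False)
    for (sid, cond), seg in cohort.eeg.items():
        df = pd.DataFrame(seg.samples.T, columns=list(seg.channel_labels))
        df.insert(0, "t_s", np.arange(seg.samples.shape[1]) / seg.fs)
        df.to_csv(directory / f"{sid}_{cond}_eeg.csv", index=False,
                  float_format="%.6g")
    return directory


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    meta = json.loads((directory / "cohort.json").read_text())
    subjects = [SubjectRecord(**s) for s in meta["subjects"]]
    fs = float(meta["eeg_fs"])
    rr, eeg = {}, {}
    for s in subjects:
        for cond in meta["conditions"]:
            rr_path = directory / f"{s.subject_id}_{cond}_rr.csv"
            if rr_path.exists():
                rr[(s.subject_id, cond)] = RRSeries(
                    pd.read_csv(rr_path)["rr_ms"].to_numpy(), s.subject_id, cond)
            eeg_path = directory / f"{s.subject_id}_{cond}_eeg.csv"
            if eeg_path.exists():
                df = pd.read_csv(eeg_path)
                chans = [c for c in df.columns if c != "t_s"]
                eeg[(s.subject_id, cond)] = EEGSegment(
                    df[chans].to_numpy().T, fs, chans, s.subject_id, cond)
    cfg = CohortConfig(n_good=max(1, sum(s.performance_group == "G" for s in subjects)),
                       n_bad=max(1, sum(s.performance_group == "B" for s in subjects)),
                       rr_length=int(meta["rr_length"]), eeg_fs=fs,
                       seed=int(meta["seed"]))
    return Cohort(subjects, rr, eeg, cfg)


def read_ecg_csv(path, fs: float | None = None, subject_id: str = "",
                 condition: str = "") -> ECGTrace:
    """ECG from a two-column CSV (``t_s``, ``mv``)."""
    df = pd.read_csv(path)
    if not {"t_s", "mv"} <= set(df.columns):
        raise ConfigurationError("ECG CSV requires columns 't_s' and 'mv'")
    if fs is None:
        dt = np.diff(df["t_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    return ECGTrace(df["mv"].to_numpy(), fs, subject_id, condition)


def write_feature_table(table: FeatureTable, path) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path


def read_feature_table(path) -> FeatureTable:
    return FeatureTable(pd.read_csv(path))


def _load_edf(path):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError("EDF support requires the 'edf' extra (mne)") from exc
    return mne.io.read_raw_edf(str(path), preload=True, verbose="error")


def read_edf_ecg(path, channel: str = "ECG", subject_id: str = "",
                 condition: str = "") -> ECGTrace:
    """One ECG channel from an EDF file (channel match case-insensitive)."""
    raw = _load_edf(path)
    names = {c.lower(): c for c in raw.ch_names}
    if channel.lower() not in names:
        raise ConfigurationError(f"channel {channel!r} not in {raw.ch_names}")
    data = raw.get_data(picks=[names[channel.lower()]])[0] * 1e3  # V -> mV
    return ECGTrace(data, float(raw.info["sfreq"]), subject_id, condition)


def read_edf_eeg(path, channels=None, subject_id: str = "",
                 condition: str = "") -> EEGSegment:
    """EEG channels from an EDF file, in µV."""
    raw = _load_edf(path)
    if channels is None:
        picks = [c for c in raw.ch_names if not c.lower().startswith("ecg")]
    else:
        names = {c.lower(): c for c in raw.ch_names}
        missing = [c for c in channels if c.lower() not in names]
        if missing:
            raise ConfigurationError(f"channels not found: {missing}")
        picks = [names[c.lower()] for c in channels]
    data = raw.get_data(picks=picks) * 1e6  # V -> µV
    return EEGSegment(data, float(raw.info["sfreq"]), picks, subject_id, condition)
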