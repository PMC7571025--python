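"""Synthetic cohorts of RR-interval series and EEG segments.

The generator emulates only the statistical structure the downstream
analysis relies on, not cardiac or cortical physiology:

* a cohort of ``n_good`` + ``n_bad`` subjects (default 24 good-count and
  12 bad-count performers), each with a baseline ('BL') and a
  cognitive-load ('CL') condition;
* per condition, an 80-interval RR series built as a mixture of a smooth
  oscillatory component (a low-frequency modulation around 0.1 Hz) and
  white jitter.  The mixing weight is calibrated once per condition — by
  bisection on Monte-Carlo ApEn estimates — so that the population mean
  approximate entropy (m=2, r=0.4·SDRR) matches the configured target
  (defaults: 0.67 under load, 0.78 at baseline);
* per condition, a multichannel EEG segment as a sum of band-limited
  Gaussian noise components, one per analysis band, with the beta-band
  variance scaled by ``beta_power_gain`` under load.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np

from .eeg import STUDY_BANDS
from .hrv import apen
from .types import (ConfigurationError, EEGSegment, EntropyParams, RRSeries,
                    SubjectRecord)

__all__ = ["ConditionTarget", "CohortConfig", "Cohort", "generate_rr_series",
           "generate_eeg_segment", "generate_cohort", "DEFAULT_CONDITION_TARGETS",
           "TEN_TWENTY_19"]

TEN_TWENTY_19 = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
                 "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2")


@dataclass(frozen=True)
class ConditionTarget:
    """Per-condition generator targets.

    ``apen_mean``/``apen_sd`` describe the intended population distribution
    of ApEn(m=2, r=0.4·SDRR); only the mean is actively calibrated, the SD
    emerges from sampling variability.  ``beta_power_gain`` multiplies the
    beta-band EEG variance.  RR mean/SD are in milliseconds.
    """

    apen_mean: float
    apen_sd: float
    beta_power_gain: float
    mean_rr_ms: float
    sd_rr_ms: float


# Baseline: slower heart rate, higher variability, more irregular RR
# dynamics (higher ApEn); under load HR rises, variability and entropy
# drop, beta-band EEG power roughly doubles.
DEFAULT_CONDITION_TARGETS: Mapping[str, ConditionTarget] = {
    "BL": ConditionTarget(apen_mean=0.78, apen_sd=0.14, beta_power_gain=1.0,
                          mean_rr_ms=745.0, sd_rr_ms=45.0),
    "CL": ConditionTarget(apen_mean=0.67, apen_sd=0.16, beta_power_gain=2.0,
                          mean_rr_ms=700.0, sd_rr_ms=35.0),
}

# Base per-band amplitude (µV, SD of the band-limited component) before
# any condition gain; delta dominates as in scalp recordings.
_BAND_SD_UV = {"DP": 8.0, "TP": 6.0, "AP": 6.0, "BP": 4.0, "GP": 2.0}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition configuration for the synthetic cohort."""

    n_good: int = 24
    n_bad: int = 12
    rr_length: int = 80
    eeg_channels: tuple = TEN_TWENTY_19
    eeg_fs: float = 250.0
    segment_duration: float = 60.0
    condition_targets: Mapping[str, ConditionTarget] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_TARGETS))
    split_threshold: int = 10  # accurate count above -> group G
    seed: int = 0

    def __post_init__(self):
        if self.n_good < 1 or self.n_bad < 1:
            raise ConfigurationError("need at least one subject per group")
        if self.rr_length < 2:
            raise ConfigurationError("rr_length must be >= 2")
        if self.eeg_fs <= 2 * 25.0:
            raise ConfigurationError("eeg_fs must exceed twice the 25 Hz band edge")
        object.__setattr__(self, "eeg_channels", tuple(self.eeg_channels))
        object.__setattr__(self, "condition_targets", dict(self.condition_targets))


@dataclass
class Cohort:
    """A generated cohort: subject records plus per-condition signals."""

    subjects: list
    rr: dict  # (subject_id, condition) -> RRSeries
    eeg: dict  # (subject_id, condition) -> EEGSegment
    config: CohortConfig

    @property
    def conditions(self) -> tuple:
        return tuple(self.config.condition_targets)


def _subseed(*parts) -> list:
    """Stable, small (< 2^31) entropy words from heterogeneous parts."""
    return [zlib.crc32(str(p).encode()) & 0x7FFFFFFF for p in parts]


# ----------------------------------------------------------------------
# RR generation and ApEn calibration
# ----------------------------------------------------------------------

def _rr_shape(rng: np.random.Generator, n: int, w: float,
              mean_rr_s: float) -> np.ndarray:
    """Unit-variance mixture: sqrt(1−w²)·oscillation + w·white jitter."""
    t = np.arange(n) * mean_rr_s
    freq = rng.uniform(0.08, 0.12)
    phase = rng.uniform(0.0, 2 * np.pi)
    osc = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t + phase)
    eps = rng.standard_normal(n)
    return np.sqrt(max(0.0, 1.0 - w * w)) * osc + w * eps


_CAL_PARAMS = EntropyParams(m=2, r=0.4, r_mode="sdrr")


def _mean_apen(w: float, n: int, mean_rr_s: float, draws: int, seed: int) -> float:
    """Monte-Carlo mean ApEn(m=2, r=0.4·SDRR) of the mixture at weight w.

    The RNG depends only on ``seed``, so different weights are compared on
    common random draws: the estimated calibration curve is then strictly
    increasing in w, which bisection requires.
    """
    rng = np.random.default_rng([seed])
    vals = []
    for _ in range(draws):
        x = _rr_shape(rng, n, w, mean_rr_s)
        if np.std(x) == 0:
            continue
        vals.append(apen(x, _CAL_PARAMS))
    return float(np.mean(vals))


@lru_cache(maxsize=32)
def _calibrate_weight(target: float, n: int, mean_rr_ms: float,
                      draws: int = 200, tol: float = 0.02,
                      max_iter: int = 14) -> float:
    """Bisection on the jitter weight so mean ApEn approaches ``target``.

    The mean ApEn of the mixture increases monotonically with the white
    jitter weight, so bisection on [0, 1] converges.  The calibration RNG
    is fixed (independent of user seeds) to make the weight reproducible.
    """
    mean_rr_s = mean_rr_ms / 1000.0
    cal_seed = _subseed("apen-cal", round(target, 4), n)[0]
    lo, hi = 0.0, 1.0
    lo_v = _mean_apen(lo, n, mean_rr_s, draws, cal_seed)
    hi_v = _mean_apen(hi, n, mean_rr_s, draws, cal_seed)
    if target <= lo_v:
        return lo
    if target >= hi_v:
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = _mean_apen(mid, n, mean_rr_s, draws, cal_seed)
        if abs(v - target) < tol / 2:
            return mid
        if v < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_rr_series(condition: str, subject: SubjectRecord,
                       cfg: CohortConfig, seed: int) -> RRSeries:
    """One subject-condition RR series of exactly ``cfg.rr_length`` intervals."""
    if condition not in cfg.condition_targets:
        raise ConfigurationError(f"unknown condition {condition!r}")
    tgt = cfg.condition_targets[condition]
    w = _calibrate_weight(tgt.apen_mean, cfg.rr_length, tgt.mean_rr_ms)
    rng = np.random.default_rng([seed] + _subseed(subject.subject_id, condition, "rr"))
    shape = _rr_shape(rng, cfg.rr_length, w, tgt.mean_rr_ms / 1000.0)
    rr = tgt.mean_rr_ms + tgt.sd_rr_ms * shape
    rr = np.clip(rr, 250.0, 2000.0)  # physiological guard
    return RRSeries(rr, subject.subject_id, condition)


# ----------------------------------------------------------------------
# EEG generation
# ----------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float, sd: float) -> np.ndarray:
    """Gaussian noise band-limited to [lo, hi] Hz with SD ``sd`` (FFT mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    s = np.std(x)
    return x * (sd / s) if s > 0 else x


def generate_eeg_segment(condition: str, subject: SubjectRecord,
                         cfg: CohortConfig, seed: int) -> EEGSegment:
    """One subject-condition EEG segment (channels × time, µV)."""
    if condition not in cfg.condition_targets:
        raise ConfigurationError(f"unknown condition {condition!r}")
    tgt = cfg.condition_targets[condition]
    n = int(round(cfg.segment_duration * cfg.eeg_fs))
    rng = np.random.default_rng([seed] + _subseed(subject.subject_id, condition, "eeg"))
    data = np.zeros((len(cfg.eeg_channels), n))
    for ch in range(len(cfg.eeg_channels)):
        for band, (lo, hi) in STUDY_BANDS.items():
            sd = _BAND_SD_UV[band]
            if band == "BP":
                sd *= np.sqrt(tgt.beta_power_gain)
            data[ch] += _band_noise(rng, n, cfg.eeg_fs, lo, hi, sd)
    return EEGSegment(data, cfg.eeg_fs, cfg.eeg_channels,
                      subject.subject_id, condition)


# ----------------------------------------------------------------------
# cohort assembly
# ----------------------------------------------------------------------

def _make_subjects(cfg: CohortConfig) -> list:
    rng = np.random.default_rng([cfg.seed] + _subseed("subjects"))
    subjects = []
    n_total = cfg.n_good + cfg.n_bad
    for i in range(n_total):
        group = "G" if i < cfg.n_good else "B"
        sid = f"S{i + 1:02d}"
        sex = "F" if rng.uniform() < 0.65 else "M"  # roughly the study's ratio
        if group == "G":
            count = int(round(rng.normal(21.0, 7.4)))
            count = max(cfg.split_threshold + 1, count)
        else:
            count = int(round(rng.normal(7.0, 3.6)))
            count = int(np.clip(count, 0, cfg.split_threshold))
        subjects.append(SubjectRecord(sid, sex, group, count))
    return subjects


def generate_cohort(cfg: CohortConfig | None = None) -> Cohort:
    """Full cohort: records plus RR series and EEG segment per condition."""
    cfg = cfg or CohortConfig()
    subjects = _make_subjects(cfg)
    rr, eeg = {}, {}
    for subject in subjects:
        for condition in cfg.condition_targets:
            rr[(subject.subject_id, condition)] = generate_rr_series(
                condition, subject, cfg, cfg.seed)
            eeg[(subject.subject_id, condition)] = generate_eeg_segment(
                condition, subject, cfg, cfg.seed)
    return Cohort(subjects, rr, eeg, cfg)
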