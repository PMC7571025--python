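"""R-peak detection and RR-series construction.

The detector follows the wavelet family of QRS detectors: a stationary
wavelet transform of the trace, detail levels whose passbands overlap the
QRS-energy band (≈5–20 Hz) squared and summed into an envelope, an
adaptive per-window threshold (k × window RMS), local-maximum refinement
on a low-passed copy of the raw trace within ±50 ms, and a 250 ms
refractory period.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy.signal import butter, filtfilt

from .types import DetectionError, ECGTrace, RRSeries, SubjectExcluded

__all__ = ["detect_r_peaks", "to_rr_series", "apply_length_rule", "synthetic_ecg"]

log = logging.getLogger(__name__)

_QRS_BAND = (5.0, 20.0)
_REFRACTORY_S = 0.250
_REFINE_S = 0.050


def _qrs_levels(fs: float, max_level: int = 6) -> list:
    """SWT detail levels whose nominal band [fs/2^(j+1), fs/2^j] meets 5–20 Hz."""
    levels = []
    for j in range(1, max_level + 1):
        lo, hi = fs / 2 ** (j + 1), fs / 2 ** j
        if hi > _QRS_BAND[0] and lo < _QRS_BAND[1]:
            levels.append(j)
    return levels


def detect_r_peaks(ecg: ECGTrace, k: float = 1.5, window_s: float = 2.0) -> np.ndarray:
    """Sample indices of R peaks, strictly increasing.

    ``k`` scales the adaptive threshold (k × RMS of the wavelet envelope in
    each ``window_s`` window).  A zero-variance trace yields no peaks; a
    trace shorter than one window raises :class:`DetectionError`.
    """
    fs = ecg.fs
    if fs < 100:
        raise DetectionError("detection requires fs >= 100 Hz")
    x = ecg.samples - np.mean(ecg.samples)
    win = int(round(window_s * fs))
    if len(x) < win:
        raise DetectionError("trace shorter than one analysis window")
    if np.std(x) == 0:
        return np.array([], dtype=int)

    levels = _qrs_levels(fs)
    max_level = max(levels)
    # SWT is periodic and needs a length divisible by 2**level: pad both
    # ends with the edge value — wide enough to out-reach the filter spread
    # — so boundary wrap-around cannot fake QRS energy, then crop.
    block = 2 ** max_level
    margin = 8 * block  # > db4 support at the deepest level
    left = margin
    right = margin + ((-(len(x) + left + margin)) % block)
    xp = np.pad(x, (left, right), mode="edge")
    coeffs = pywt.swt(xp, "db4", level=max_level)
    # coeffs[i] corresponds to level max_level - i
    env = np.zeros(len(xp))
    for i, (_, cd) in enumerate(coeffs):
        if (max_level - i) in levels:
            env += np.asarray(cd) ** 2
    env = env[left: left + len(x)]
    # light smoothing (~100 ms) stabilizes the envelope maxima
    smooth = max(1, int(round(0.1 * fs)))
    env = np.convolve(env, np.ones(smooth) / smooth, mode="same")

    # adaptive threshold per non-overlapping window; a trailing stub
    # shorter than half a window merges with the previous one (its own
    # RMS would be dominated by edge spillover)
    starts = list(range(0, len(env), win))
    if len(starts) > 1 and len(env) - starts[-1] < win // 2:
        starts.pop()
    thr = np.empty_like(env)
    for i, start in enumerate(starts):
        stop = starts[i + 1] if i + 1 < len(starts) else len(env)
        seg = env[start:stop]
        thr[start:stop] = k * np.sqrt(np.mean(seg ** 2))

    above = env > thr
    if not np.any(above):
        return np.array([], dtype=int)
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    regions = np.split(idx, breaks + 1)

    # refinement trace: low-passed raw signal (reduces jitter of the maximum)
    nyq = fs / 2.0
    b, a = butter(4, min(30.0, 0.9 * nyq) / nyq)
    xr = filtfilt(b, a, x)

    refine = int(round(_REFINE_S * fs))
    cand = []
    for reg in regions:
        c = reg[np.argmax(env[reg])]
        lo, hi = max(0, c - refine), min(len(x), c + refine + 1)
        p = lo + int(np.argmax(xr[lo:hi]))
        # hill-climb to the exact local maximum of the refinement trace
        while p + 1 < len(x) and xr[p + 1] > xr[p]:
            p += 1
        while p - 1 >= 0 and xr[p - 1] > xr[p]:
            p -= 1
        cand.append((p, float(np.max(env[reg]))))

    # refractory: keep the stronger of any two candidates closer than 250 ms
    refr = int(round(_REFRACTORY_S * fs))
    cand.sort()
    peaks: list = []
    strengths: list = []
    for pos, s in cand:
        if peaks and pos - peaks[-1] < refr:
            if s > strengths[-1]:
                peaks[-1], strengths[-1] = pos, s
        else:
            peaks.append(pos)
            strengths.append(s)
    return np.asarray(sorted(set(peaks)), dtype=int)


def to_rr_series(peaks, fs: float, subject_id: str = "", condition: str = "") -> RRSeries:
    """Successive peak spacings in ms: (peak[i+1] − peak[i]) / fs × 1000."""
    peaks = np.asarray(peaks)
    if len(peaks) < 2:
        raise DetectionError("need >= 2 peaks to build an RR series")
    intervals = np.diff(peaks) / fs * 1000.0
    return RRSeries(intervals, subject_id, condition)


def apply_length_rule(rr: RRSeries, required_length: int = 80) -> RRSeries:
    """Inclusion rule: keep the first ``required_length`` intervals.

    A series with fewer intervals raises :class:`SubjectExcluded` — a
    signaled outcome (the subject is dropped from the cohort), not an error.
    """
    if len(rr) < required_length:
        log.info("subject %s/%s excluded: %d < %d intervals",
                 rr.subject_id, rr.condition, len(rr), required_length)
        raise SubjectExcluded(
            f"{rr.subject_id}/{rr.condition}: {len(rr)} < {required_length} intervals")
    return rr.with_intervals(rr.intervals[:required_length])


def synthetic_ecg(beat_times_s, fs: float = 250.0, duration_s: float | None = None,
                  amplitude_mv: float = 1.0, width_s: float = 0.02,
                  noise_sd: float = 0.0, seed: int = 0,
                  kind: str = "gauss") -> ECGTrace:
    """Toy ECG for detector testing: a bump (or impulse) per beat plus noise.

    Not a physiological waveform model — a controlled trace with known
    ground-truth R positions at ``beat_times_s``.
    """
    beat_times = np.asarray(beat_times_s, dtype=float)
    if duration_s is None:
        duration_s = float(beat_times[-1]) + 0.5
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    idx = np.round(beat_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    if kind == "impulse":
        x[idx] = amplitude_mv
    else:
        t = np.arange(n) / fs
        for bt in idx / fs:
            x += amplitude_mv * np.exp(-0.5 * ((t - bt) / width_s) ** 2)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return ECGTrace(x, fs)
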