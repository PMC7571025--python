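"""Per-channel EEG features: sub-band powers and wavelet entropy.

Band powers use the study's printed band edges — delta 1–4 Hz, theta
4.1–5.8 Hz, alpha 5.9–7.4 Hz, beta 13–19.9 Hz, gamma 20–25 Hz.  These
theta/alpha/gamma edges are nonstandard but are applied exactly as
defined; the gaps between bands (4.0–4.1, 7.4–13, 19.9–20 Hz) belong to
no band.  A ``bands`` argument allows conventional edges.

Wavelet entropy is the Shannon entropy of the relative energies of the
128 terminal nodes of a 7-level Daubechies-4 wavelet-packet decomposition.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.signal import welch

from .types import EEGSegment, FeatureUndefinedError

__all__ = ["STUDY_BANDS", "band_powers", "wavelet_entropy", "extract_all",
           "channel_band_power"]

STUDY_BANDS = {
    "DP": (1.0, 4.0),
    "TP": (4.1, 5.8),
    "AP": (5.9, 7.4),
    "BP": (13.0, 19.9),
    "GP": (20.0, 25.0),
}

_WELCH_WINDOW_S = 2.0  # 0.5 Hz resolution


def _psd(x: np.ndarray, fs: float):
    nperseg = int(round(_WELCH_WINDOW_S * fs))
    if len(x) < nperseg:
        raise FeatureUndefinedError("segment shorter than one analysis window")
    return welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def channel_band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Integrated Welch power of one channel over [lo, hi] Hz (inclusive)."""
    f, p = _psd(np.asarray(x, dtype=float), fs)
    df = f[1] - f[0]
    return float(np.sum(p[(f >= lo) & (f <= hi)]) * df)


def band_powers(seg: EEGSegment, bands: dict | None = None) -> dict:
    """Per-channel band powers, keyed '<band>_<channel>' (µV²)."""
    bands = bands or STUDY_BANDS
    out = {}
    for ch, label in enumerate(seg.channel_labels):
        f, p = _psd(seg.samples[ch], seg.fs)
        df = f[1] - f[0]
        for name, (lo, hi) in bands.items():
            out[f"{name}_{label}"] = float(np.sum(p[(f >= lo) & (f <= hi)]) * df)
    return out


def wavelet_entropy(seg: EEGSegment, wavelet: str = "db4", level: int = 7) -> dict:
    """Per-channel wavelet-packet entropy, keyed 'WE_<channel>'.

    Energy concentrated in a single terminal node gives entropy near 0;
    broadband noise approaches the maximum ln(2^level).
    """
    if seg.samples.shape[1] < 2 ** level:
        raise FeatureUndefinedError(f"segment needs >= {2 ** level} samples")
    out = {}
    for ch, label in enumerate(seg.channel_labels):
        wp = pywt.WaveletPacket(data=seg.samples[ch], wavelet=wavelet,
                                mode="symmetric", maxlevel=level)
        energies = np.array([np.sum(np.asarray(node.data) ** 2)
                             for node in wp.get_level(level, order="natural")])
        total = energies.sum()
        if total == 0:
            raise FeatureUndefinedError(f"zero-energy channel {label}: WE undefined")
        p = energies / total
        p = p[p > 0]
        out[f"WE_{label}"] = float(-np.sum(p * np.log(p)))
    return out


def extract_all(seg: EEGSegment, bands: dict | None = None) -> dict:
    """All six per-channel EEG features for one segment."""
    out = band_powers(seg, bands)
    out.update(wavelet_entropy(seg))
    return out
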