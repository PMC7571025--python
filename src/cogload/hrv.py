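"""Heart-rate-variability features of a short RR-interval series.

27 features in four families:

* time domain — SDRR, RMSSD, Mean, Area, MFD, pNN20, pNN10, HRVC;
* frequency domain — VLF/LF/HF/TOTPWR band powers of the tachogram and the
  derived ratios, from a cubic-spline resampled (4 Hz), mean-removed
  single-segment Hann periodogram;
* regularity/complexity — PeEn, ApEn, MFEn, SampEn with tunable (m, r, τ,
  scale), DFA short/long-scale exponents α1 (boxes 4–16) and α2 (16–32),
  total fluctuation coefficient (TFC) over coarse-graining scales 1..M and
  the range of local Hurst exponents (RLHE) from windowed DFA;
* Poincaré geometry — SD1, SD2 and their ratio.

All features are functions of the interval values only, so they are
invariant under shifts of the recording's time origin.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .types import EntropyParams, FeatureUndefinedError, HRV_FEATURE_NAMES, RRSeries

__all__ = [
    "time_domain", "freq_domain", "entropy_features", "dfa", "poincare",
    "tfc", "rlhe", "extract_all", "apen", "sampen", "peen", "mfen",
    "dfa_alpha", "DEFAULT_ENTROPY_PARAMS",
]

# Tuned defaults for the task-vs-rest problem (tolerance r in SD units for
# the absolute-mode entropies; MFEn coarse-graining scale 5).
DEFAULT_ENTROPY_PARAMS: Mapping[str, EntropyParams] = {
    "ApEn": EntropyParams(m=2, r=0.4, r_mode="sdrr"),
    "SampEn": EntropyParams(m=1, r=0.3, r_mode="absolute"),
    "PeEn": EntropyParams(m=6, r=1.0, tau=1),  # r unused by PeEn
    "MFEn": EntropyParams(m=1, r=0.1, r_mode="absolute", scale=5),
}


def _values(rr) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.intervals
    return np.asarray(rr, dtype=float)


# ----------------------------------------------------------------------
# time domain
# ----------------------------------------------------------------------

def time_domain(rr) -> dict:
    """SDRR, RMSSD, Mean, Area, MFD, pNN20, pNN10, HRVC.

    SDRR is the population standard deviation; MFD is the mean *absolute*
    first difference (the signed mean telescopes to an endpoint difference
    and carries no fluctuation information); pNNx uses a strict ``>``.
    """
    x = _values(rr)
    if len(x) < 2:
        raise FeatureUndefinedError("time-domain features need >= 2 intervals")
    d = np.diff(x)
    mean = float(np.mean(x))
    sdrr = float(np.std(x))  # population SD
    return {
        "SDRR": sdrr,
        "RMSSD": float(np.sqrt(np.mean(d ** 2))),
        "Mean": mean,
        "Area": float(np.sum(x)),
        "MFD": float(np.mean(np.abs(d))),
        "pNN20": float(np.mean(np.abs(d) > 20.0)),
        "pNN10": float(np.mean(np.abs(d) > 10.0)),
        "HRVC": sdrr / mean,
    }


# ----------------------------------------------------------------------
# frequency domain
# ----------------------------------------------------------------------

_BANDS = {"VLF": (0.0, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}
_RESAMPLE_FS = 4.0


def freq_domain(rr) -> dict:
    """Band powers of the tachogram and their ratios.

    The unevenly sampled tachogram (interval value at each cumulative beat
    time) is cubic-spline resampled at 4 Hz, mean-removed and analysed with
    a single-segment Hann periodogram.  Band powers (ms²) integrate
    [0, 0.04), [0.04, 0.15), [0.15, 0.4) and [0, 0.4) Hz.  LF/HF is NaN
    (with a warning) when HF is zero.
    """
    x = _values(rr)
    if len(x) < 2:
        raise FeatureUndefinedError("frequency-domain features need >= 2 intervals")
    t = np.cumsum(x) / 1000.0  # beat times, s
    span = t[-1] - t[0]
    if span <= 1.0 / 0.04:
        warnings.warn("series shorter than one VLF cycle: VLF has low frequency support")
    spline = CubicSpline(t, x)
    tt = np.arange(t[0], t[-1], 1.0 / _RESAMPLE_FS)
    xx = spline(tt)
    xx = xx - np.mean(xx)
    if np.allclose(xx, 0.0):
        powers = {k: 0.0 for k in _BANDS}
        powers["TOTPWR"] = 0.0
    else:
        f, p = welch(xx, fs=_RESAMPLE_FS, window="hann", nperseg=len(xx))
        df = f[1] - f[0]
        powers = {name: float(np.sum(p[(f >= lo) & (f < hi)]) * df)
                  for name, (lo, hi) in _BANDS.items()}
        powers["TOTPWR"] = float(np.sum(p[(f >= 0.0) & (f < 0.4)]) * df)
    lf, hf = powers["LF"], powers["HF"]
    denom = lf + hf
    if denom > 0:
        hf_n, lf_n = hf / denom, lf / denom
    else:
        hf_n = lf_n = np.nan
    if hf > 0:
        lf_hf = lf / hf
    else:
        warnings.warn("HF power is zero: LF/HF undefined")
        lf_hf = np.nan
    return {**powers, "HF/(LF+HF)": hf_n, "LF/(LF+HF)": lf_n, "LF/HF": lf_hf}


# ----------------------------------------------------------------------
# regularity statistics
# ----------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embedded template matrix, shape (n_templates, m)."""
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise FeatureUndefinedError("series too short for embedding")
    idx = np.arange(m) * tau
    return x[np.arange(n)[:, None] + idx[None, :]]


def _resolve_r(x: np.ndarray, params: EntropyParams) -> tuple:
    """Return (series to embed, absolute tolerance)."""
    sd = np.std(x)
    if params.r_mode == "sdrr":
        if sd == 0:
            raise FeatureUndefinedError("degenerate tolerance: SDRR is zero")
        return x, params.r * sd
    # absolute tolerance applies to the z-scored series
    if sd == 0:
        raise FeatureUndefinedError("degenerate input: zero variance")
    return (x - np.mean(x)) / sd, params.r


def _cheb(templates: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distance matrix."""
    return np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1)


def apen(rr, params: EntropyParams) -> float:
    """Approximate entropy: Φ(m) − Φ(m+1), self-matches included."""
    x, r = _resolve_r(_values(rr), params)
    if len(x) < (params.m + 1 - 1) * params.tau + 1 + 1:
        raise FeatureUndefinedError("series too short for ApEn")

    def phi(m):
        tmpl = _embed(x, m, params.tau)
        c = np.mean(_cheb(tmpl) <= r, axis=1)  # self-match included
        return np.mean(np.log(c))

    return float(phi(params.m) - phi(params.m + 1))


def sampen(rr, params: EntropyParams) -> float:
    """Sample entropy: −ln(A/B) over matched template pairs, no self-matches."""
    x, r = _resolve_r(_values(rr), params)
    m, tau = params.m, params.tau
    n_tmpl = len(x) - m * tau  # templates that extend to length m+1
    if n_tmpl < 2:
        raise FeatureUndefinedError("series too short for SampEn")
    tm = _embed(x, m, tau)[:n_tmpl]
    tm1 = _embed(x, m + 1, tau)
    iu = np.triu_indices(n_tmpl, k=1)
    b = np.count_nonzero(_cheb(tm)[iu] <= r)
    a = np.count_nonzero(_cheb(tm1)[iu] <= r)
    if b == 0 or a == 0:
        raise FeatureUndefinedError("no matched templates: SampEn undefined")
    return float(-np.log(a / b))


def peen(rr, params: EntropyParams) -> float:
    """Permutation entropy of ordinal patterns, normalized by ln(m!)."""
    x = _values(rr)
    m, tau = params.m, params.tau
    tmpl = _embed(x, m, tau)
    # ordinal pattern = ranks of each template (ties broken by position)
    patterns = np.argsort(tmpl, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    import math
    return float(h / np.log(math.factorial(m)))


def _coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    n = len(x) // scale
    if n < 2:
        raise FeatureUndefinedError("series too short for the requested scale")
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def _fuzzy_phi(tmpl: np.ndarray, r: float) -> float:
    d = _cheb(tmpl)
    iu = np.triu_indices(len(tmpl), k=1)
    return float(np.mean(np.exp(-((d[iu] / r) ** 2))))


def mfen(rr, params: EntropyParams) -> float:
    """Multiscale fuzzy measure entropy.

    The series is coarse-grained at ``params.scale`` (non-overlapping
    means), then a fuzzy measure entropy is computed with exponential
    membership exp(−(d/r)²): the sum, with equal weight, of a *local*
    fuzzy entropy (templates centred on their own mean, capturing local
    pattern similarity) and a *global* one (templates centred on the series
    mean, capturing similarity of absolute level).
    """
    x, r = _resolve_r(_values(rr), params)
    y = _coarse_grain(x, params.scale)
    m, tau = params.m, params.tau
    if len(y) < m * tau + 2:
        raise FeatureUndefinedError("coarse-grained series too short for MFEn")

    def fuzzy_en(center_local: bool) -> float:
        out = []
        for mm in (m, m + 1):
            n_tmpl = len(y) - m * tau  # common template count for both orders
            tmpl = _embed(y, mm, tau)[:n_tmpl]
            if center_local:
                tmpl = tmpl - tmpl.mean(axis=1, keepdims=True)
            else:
                tmpl = tmpl - np.mean(y)
            out.append(_fuzzy_phi(tmpl, r))
        if out[0] <= 0 or out[1] <= 0:
            raise FeatureUndefinedError("fuzzy similarity collapsed to zero")
        return float(np.log(out[0] / out[1]))

    return fuzzy_en(True) + fuzzy_en(False)


def entropy_features(rr, params: Mapping[str, EntropyParams] | None = None) -> dict:
    """ApEn, SampEn, PeEn and MFEn with per-feature parameters."""
    p = dict(DEFAULT_ENTROPY_PARAMS)
    if params:
        p.update(params)
    return {
        "PeEn": peen(rr, p["PeEn"]),
        "ApEn": apen(rr, p["ApEn"]),
        "MFEn": mfen(rr, p["MFEn"]),
        "SampEn": sampen(rr, p["SampEn"]),
    }


# ----------------------------------------------------------------------
# detrended fluctuation analysis
# ----------------------------------------------------------------------

def _dfa_fluctuations(x: np.ndarray, box_sizes: np.ndarray) -> np.ndarray:
    """Root-mean-square fluctuation per box size (DFA-1, non-overlapping)."""
    y = np.cumsum(x - np.mean(x))
    out = []
    for n in box_sizes:
        n_boxes = len(y) // n
        segs = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n, dtype=float)
        t_c = t - t.mean()
        slope = segs @ t_c / np.sum(t_c ** 2)
        resid = segs - segs.mean(axis=1, keepdims=True) - slope[:, None] * t_c
        out.append(np.sqrt(np.mean(resid ** 2)))
    return np.asarray(out)


def dfa_alpha(x, lo: int, hi: int) -> float:
    """Scaling exponent: log–log slope of fluctuation vs box size on [lo, hi]."""
    x = _values(x)
    if len(x) < 2 * lo:
        raise FeatureUndefinedError("series too short for DFA")
    sizes = np.arange(lo, min(hi, len(x) // 2) + 1)
    if len(sizes) < 2:
        raise FeatureUndefinedError("not enough box sizes for DFA")
    fl = _dfa_fluctuations(x, sizes)
    if np.any(fl <= 0):
        raise FeatureUndefinedError("zero fluctuation: DFA undefined")
    return float(np.polyfit(np.log(sizes), np.log(fl), 1)[0])


def dfa(rr) -> dict:
    """Short- and long-scale exponents (boxes 4–16 and 16–32) and their ratio."""
    x = _values(rr)
    if len(x) < 64:
        raise FeatureUndefinedError("DFA alpha2 needs >= 64 intervals")
    a1 = dfa_alpha(x, 4, 16)
    a2 = dfa_alpha(x, 16, 32)
    return {"DFA_alpha1": a1, "DFA_alpha2": a2, "alpha1/alpha2": a1 / a2}


# ----------------------------------------------------------------------
# Poincaré plot
# ----------------------------------------------------------------------

def poincare(rr) -> dict:
    """SD1/SD2 dispersions of the lag-1 return map.

    SD1² = mean(ΔRR²)/2 — the uncentered second moment, which makes
    SD1 = RMSSD/√2 an exact identity — and SD2² = 2·var(RR) − SD1²
    (population variance); a negative SD2² from the identity is clipped
    to zero with a warning.
    """
    x = _values(rr)
    if len(x) < 2:
        raise FeatureUndefinedError("Poincaré features need >= 2 intervals")
    d = np.diff(x)
    sd1_sq = np.mean(d ** 2) / 2.0
    sd2_sq = 2.0 * np.var(x) - sd1_sq
    if sd2_sq < 0:
        warnings.warn("negative SD2^2 from variance identity; clipped to 0")
        sd2_sq = 0.0
    sd1, sd2 = float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))
    return {"SD1": sd1, "SD2": sd2, "SD1/SD2": sd1 / sd2 if sd2 > 0 else np.nan}


# ----------------------------------------------------------------------
# total fluctuation coefficient and local Hurst range
# ----------------------------------------------------------------------

def tfc(rr, M: int = 10) -> float:
    """Total fluctuation coefficient over coarse-graining scales 1..M.

    F(s) is the mean absolute successive difference of the series
    coarse-grained by non-overlapping means of width s, normalized by the
    series mean; TFC = Σ_{s=1}^{M} F(s).  Scale-free by construction.
    """
    x = _values(rr)
    if len(x) < 2 * M:
        raise FeatureUndefinedError(f"TFC needs >= {2 * M} intervals")
    mu = np.mean(x)
    if mu == 0:
        raise FeatureUndefinedError("zero-mean series: TFC undefined")
    total = 0.0
    for s in range(1, M + 1):
        cg = _coarse_grain(x, s)
        total += float(np.mean(np.abs(np.diff(cg)))) / mu
    return total


def rlhe(rr, window: int = 32, step: int = 4) -> float:
    """Range (max − min) of local Hurst exponents.

    The short-scale DFA exponent α1 is estimated in sliding windows; RLHE
    is the spread of those local exponents, large when roughness varies
    along the series.
    """
    x = _values(rr)
    if len(x) < window + step:
        raise FeatureUndefinedError("series too short for RLHE")
    exps = []
    for start in range(0, len(x) - window + 1, step):
        w = x[start: start + window]
        if np.std(w) == 0:
            continue
        exps.append(dfa_alpha(w, 4, 16))
    if not exps:
        raise FeatureUndefinedError("zero variance in every window: RLHE undefined")
    return float(np.max(exps) - np.min(exps))


# ----------------------------------------------------------------------
# full vector
# ----------------------------------------------------------------------

def extract_all(rr, entropy_params: Mapping[str, EntropyParams] | None = None,
                tfc_M: int = 10, rlhe_window: int = 32, rlhe_step: int = 4) -> dict:
    """The full 27-feature HRV vector, keyed by canonical names."""
    out = {}
    out.update(time_domain(rr))
    out.update(freq_domain(rr))
    out.update(entropy_features(rr, entropy_params))
    out.update(dfa(rr))
    out["TFC"] = tfc(rr, M=tfc_M)
    out.update(poincare(rr))
    out["RLHE"] = rlhe(rr, window=rlhe_window, step=rlhe_step)
    return {name: out[name] for name in HRV_FEATURE_NAMES}
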