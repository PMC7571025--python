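"""Entropy-parameter selection by Mann–Whitney U discrimination.

For each regularity statistic the embedding dimension m and tolerance r
are chosen from a grid as the point whose two-group Mann–Whitney U test
gives the smallest two-sided p-value; the choice is flagged
non-significant when even the best p is >= 0.05.  The embedding delay τ
is estimated per series as the first local minimum of the lagged mutual
information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .types import ConfigurationError, EntropyParams, FeatureUndefinedError, RRSeries
from . import hrv

__all__ = ["TuningGrid", "TuningResult", "mi_delay", "mann_whitney",
           "tune", "tune_feature", "default_grid"]

_EXACT_LIMIT = 400  # use the exact U distribution when n_A * n_B <= this


@dataclass(frozen=True)
class TuningGrid:
    """Grid of candidate (m, r) values for one entropy feature."""

    feature: str  # 'ApEn', 'SampEn', 'PeEn', 'MFEn'
    m_values: tuple
    r_values: tuple  # empty for PeEn
    r_mode: str = "absolute"  # or 'sdrr'
    tau_rule: str = "fixed"  # 'fixed' or 'mutual_information'
    scale: int = 1

    def __post_init__(self):
        if self.feature not in ("ApEn", "SampEn", "PeEn", "MFEn"):
            raise ConfigurationError("unknown entropy feature")
        if not self.m_values:
            raise ConfigurationError("empty m grid")
        if self.feature != "PeEn" and not self.r_values:
            raise ConfigurationError("empty r grid")
        object.__setattr__(self, "m_values", tuple(self.m_values))
        object.__setattr__(self, "r_values", tuple(self.r_values))

    def points(self) -> list:
        """All candidate EntropyParams, ordered by (m, r) for tie-breaks."""
        out = []
        for m in self.m_values:
            if self.feature == "PeEn":
                out.append(EntropyParams(m=m, r=1.0, scale=self.scale))
            else:
                for r in self.r_values:
                    out.append(EntropyParams(m=m, r=r, r_mode=self.r_mode,
                                             scale=self.scale))
        return out


_R_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))


def default_grid(feature: str, problem: str = "CL_vs_BL") -> TuningGrid:
    """The study's grid ranges; MFEn scale is 5 (task-vs-rest) or 2."""
    if feature == "ApEn":
        return TuningGrid("ApEn", (1, 2, 3), _R_GRID, r_mode="sdrr")
    if feature == "SampEn":
        return TuningGrid("SampEn", (1, 2, 3), _R_GRID, r_mode="absolute")
    if feature == "PeEn":
        return TuningGrid("PeEn", (3, 4, 5, 6, 7), (), tau_rule="mutual_information")
    if feature == "MFEn":
        scale = 5 if problem == "CL_vs_BL" else 2
        return TuningGrid("MFEn", (1, 2, 3), _R_GRID, r_mode="absolute", scale=scale)
    raise ConfigurationError(f"unknown feature {feature!r}")


def mi_delay(series, max_lag: int = 20) -> int:
    """Embedding delay: first local minimum of the lagged mutual information.

    MI is estimated from a 2-D histogram with √n bins per axis.  When the
    MI curve has no strict local minimum up to ``max_lag`` (flat or
    monotone), τ = 1 is returned with a warning.
    """
    x = np.asarray(series.intervals if isinstance(series, RRSeries) else series,
                   dtype=float)
    if len(x) <= max_lag + 1:
        raise ConfigurationError("series too short for the requested max_lag")
    if np.std(x) == 0:
        raise FeatureUndefinedError("constant series: mutual information undefined")
    bins = max(2, int(np.sqrt(len(x))))

    def mi(lag: int) -> float:
        a, b = x[:-lag], x[lag:]
        h, _, _ = np.histogram2d(a, b, bins=bins)
        p = h / h.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))

    curve = np.array([mi(lag) for lag in range(1, max_lag + 1)])
    for k in range(len(curve) - 1):
        if curve[k] < curve[k + 1]:  # first strict upturn -> local minimum
            return k + 1
    warnings.warn("no local minimum of mutual information; using tau=1")
    return 1


def mann_whitney(group_a, group_b) -> tuple:
    """Two-sided Mann–Whitney U: (U for group A, p-value).

    Exact distribution when n_A·n_B <= 400 and the data are tie-free;
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (a.size * b.size <= _EXACT_LIMIT and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TuningResult:
    params: EntropyParams
    p_value: float
    significant: bool
    table: tuple = ()  # ((EntropyParams, p), ...) over the whole grid

    def to_dict(self) -> dict:
        return {
            "m": self.params.m, "r": self.params.r, "r_mode": self.params.r_mode,
            "tau": self.params.tau, "scale": self.params.scale,
            "p_value": self.p_value, "significant": self.significant,
            "grid": [{"m": p.m, "r": p.r, "p_value": pv} for p, pv in self.table],
        }


def tune(samples: Mapping[EntropyParams, tuple]) -> TuningResult:
    """Pick the grid point with the smallest two-sided U-test p-value.

    ``samples`` maps each candidate parameter set to the (group A values,
    group B values) computed with it.  Ties in p break toward smaller m,
    then smaller r (parsimony).  ``significant`` is False when the best
    p >= 0.05.
    """
    if not samples:
        raise ConfigurationError("empty tuning grid")
    rows = []
    for params, (va, vb) in samples.items():
        if len(va) < 3 or len(vb) < 3:
            raise ConfigurationError("need >= 3 samples per group")
        _, p = mann_whitney(va, vb)
        rows.append((params, p))
    best = min(rows, key=lambda t: (t[1], t[0].m, t[0].r))
    return TuningResult(best[0], best[1], bool(best[1] < 0.05), tuple(rows))


def tune_feature(feature: str, series_a: Sequence, series_b: Sequence,
                 grid: TuningGrid | None = None,
                 problem: str = "CL_vs_BL") -> TuningResult:
    """Tune one entropy feature on two groups of RR series.

    Computes the feature at every grid point for every series (series on
    which it is undefined are skipped for that point) and applies
    :func:`tune`.  With ``tau_rule='mutual_information'`` the delay is the
    median MI delay over all series.
    """
    grid = grid or default_grid(feature, problem)
    fn: Callable = {"ApEn": hrv.apen, "SampEn": hrv.sampen,
                    "PeEn": hrv.peen, "MFEn": hrv.mfen}[feature]
    tau = 1
    if grid.tau_rule == "mutual_information":
        taus = []
        for s in list(series_a) + list(series_b):
            try:
                taus.append(mi_delay(s))
            except FeatureUndefinedError:
                continue
        tau = int(np.median(taus)) if taus else 1

    samples = {}
    for point in grid.points():
        point = EntropyParams(m=point.m, r=point.r, r_mode=point.r_mode,
                              tau=tau, scale=point.scale)

        def values(group):
            vals = []
            for s in group:
                try:
                    vals.append(fn(s, point))
                except FeatureUndefinedError:
                    continue
            return vals

        va, vb = values(series_a), values(series_b)
        if len(va) >= 3 and len(vb) >= 3:
            samples[point] = (va, vb)
    if not samples:
        raise ConfigurationError("no grid point defined on enough series")
    return tune(samples)
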