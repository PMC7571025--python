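"""Wrapper feature selection scored by leave-one-subject-out accuracy.

Two search strategies and their combination:

* SBS — sequential backward selection: from the full set, greedily remove
  the feature whose removal leaves the highest LOSO accuracy f1, down to a
  single feature, recording the whole trajectory;
* binary PSO — a particle swarm over feature masks minimizing
  f2 = α·(#selected/#all) + (1−α)·(ErrorRate/ER), α = 0.8, where ER is the
  LOSO error with all features; velocities are continuous, positions are
  re-sampled through a sigmoid transfer with per-dimension Bernoulli draws;
* hybrid — PSO first, then SBS restricted to the PSO-selected features.

A dimension cap (default 4) picks the final subset from a trajectory:
the highest-f1 entry among those with no more dimensions than the cap.

Inside every LOSO fold, features are z-scored by the training fold's
statistics; nothing from the held-out subject enters training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import clone

from .classify import make_classifier
from .types import ClassifierSpec, CogloadError, ConfigurationError, FeatureTable

__all__ = ["FeatureMask", "FitnessConfig", "PSOConfig", "CVResult", "SelectionStep",
           "loso_fitness", "pso_fitness", "sbs", "pso", "hybrid_pso_sbs",
           "cap_select", "baseline_error"]


@dataclass(frozen=True)
class FeatureMask:
    """Binary selection vector over a table's feature columns."""

    bits: tuple

    def __post_init__(self):
        object.__setattr__(self, "bits", tuple(int(bool(b)) for b in self.bits))

    @classmethod
    def full(cls, n: int) -> "FeatureMask":
        return cls((1,) * n)

    @classmethod
    def from_names(cls, names: Sequence[str], all_names: Sequence[str]) -> "FeatureMask":
        sel = set(names)
        return cls(tuple(1 if n in sel else 0 for n in all_names))

    @property
    def n_selected(self) -> int:
        return sum(self.bits)

    def selected_names(self, all_names: Sequence[str]) -> list:
        return [n for n, b in zip(all_names, self.bits) if b]

    def drop(self, j: int) -> "FeatureMask":
        bits = list(self.bits)
        bits[j] = 0
        return FeatureMask(tuple(bits))

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class FitnessConfig:
    """Weights of the PSO fitness: subset-size term vs relative error term."""

    alpha: float = 0.8
    all_features: int = 0
    baseline_error: float = 0.0  # ER: mean LOSO error with the full feature set

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in [0, 1]")
        if not 0.0 <= self.baseline_error <= 1.0:
            raise ConfigurationError("baseline_error must lie in [0, 1]")


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters (inertia and accelerations as in the study)."""

    population: int = 30
    max_iter: int = 50
    inertia: float = 0.7298
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.population < 2 or self.max_iter < 1:
            raise ConfigurationError("population >= 2 and max_iter >= 1 required")


@dataclass(frozen=True)
class CVResult:
    """LOSO outcome: per-subject correct counts and overall accuracy f1."""

    per_subject: tuple  # ((subject_id, n_correct, n_subject_samples), ...)
    n_total: int
    f1: float


@dataclass(frozen=True)
class SelectionStep:
    dimension: int
    mask: FeatureMask
    f1: float


def _estimator(clf):
    return make_classifier(clf) if isinstance(clf, ClassifierSpec) else clf


def loso_fitness(table: FeatureTable, mask: FeatureMask | Sequence[int],
                 clf) -> CVResult:
    """Leave-one-subject-out accuracy with the masked features.

    Each subject's rows (including any synthetic rows carrying its id) form
    one test fold; the classifier is trained on all other subjects' rows,
    z-scored by training-fold statistics.  A fold whose training set lacks
    a class is skipped with a warning and excluded from ``n_total``.
    """
    if not isinstance(mask, FeatureMask):
        mask = FeatureMask(tuple(mask))
    if mask.n_selected == 0:
        raise CogloadError("empty feature mask")
    if len(mask) != len(table.feature_names):
        raise ConfigurationError("mask length does not match table")
    cols = np.flatnonzero(np.asarray(mask.bits, dtype=bool))
    X = table.X[:, cols]
    y = table.y
    subjects = table.subjects
    uniq = list(dict.fromkeys(subjects))  # original order
    if len(uniq) < 2:
        raise ConfigurationError("LOSO requires >= 2 subjects")

    base = _estimator(clf)
    per_subject = []
    n_total = 0
    n_correct_total = 0
    for sid in uniq:
        test = subjects == sid
        train = ~test
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {sid}: training set lacks a class; skipped")
            continue
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        est = clone(base)
        est.fit((X[train] - mu) / sd, y_train)
        pred = est.predict((X[test] - mu) / sd)
        n_corr = int(np.sum(pred == y[test]))
        per_subject.append((sid, n_corr, int(np.sum(test))))
        n_total += int(np.sum(test))
        n_correct_total += n_corr
    if n_total == 0:
        raise CogloadError("no scorable LOSO folds")
    return CVResult(tuple(per_subject), n_total, n_correct_total / n_total)


def loso_predict(table: FeatureTable, mask: FeatureMask | Sequence[int],
                 clf) -> tuple:
    """LOSO predictions: (truth, predictions, subject ids) over scorable folds.

    Same fold construction and standardization as :func:`loso_fitness`;
    use this when confusion counts, not just accuracy, are needed.
    """
    if not isinstance(mask, FeatureMask):
        mask = FeatureMask(tuple(mask))
    if mask.n_selected == 0:
        raise CogloadError("empty feature mask")
    cols = np.flatnonzero(np.asarray(mask.bits, dtype=bool))
    X = table.X[:, cols]
    y = table.y
    subjects = table.subjects
    y_true, y_pred, sids = [], [], []
    base = _estimator(clf)
    for sid in dict.fromkeys(subjects):
        test = subjects == sid
        train = ~test
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {sid}: training set lacks a class; skipped")
            continue
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        est = clone(base)
        est.fit((X[train] - mu) / sd, y[train])
        pred = est.predict((X[test] - mu) / sd)
        y_true.extend(y[test])
        y_pred.extend(pred)
        sids.extend([sid] * int(np.sum(test)))
    return np.asarray(y_true), np.asarray(y_pred), np.asarray(sids)


def baseline_error(table: FeatureTable, clf) -> float:
    """ER: mean LOSO error with every feature selected."""
    full = FeatureMask.full(len(table.feature_names))
    return 1.0 - loso_fitness(table, full, clf).f1


def pso_fitness(mask: FeatureMask, table: FeatureTable, clf,
                cfg: FitnessConfig) -> float:
    """f2 = α·(#selected/#all) + (1−α)·(ErrorRate/ER); lower is better."""
    if mask.n_selected == 0:
        raise CogloadError("empty feature mask")
    n_all = cfg.all_features or len(table.feature_names)
    err = 1.0 - loso_fitness(table, mask, clf).f1
    if cfg.baseline_error > 0:
        rel = err / cfg.baseline_error
    else:
        rel = 0.0 if err == 0.0 else float("inf")
    return cfg.alpha * (mask.n_selected / n_all) + (1.0 - cfg.alpha) * rel


class _Scorer:
    """Caches LOSO f1 per mask so repeated swarm positions cost nothing."""

    def __init__(self, table: FeatureTable, clf):
        self.table = table
        self.clf = clf
        self._cache: dict = {}

    def f1(self, mask: FeatureMask) -> float:
        if mask.bits not in self._cache:
            self._cache[mask.bits] = loso_fitness(self.table, mask, self.clf).f1
        return self._cache[mask.bits]


def sbs(table: FeatureTable, clf, features: Sequence[str] | None = None,
        _scorer: "_Scorer | None" = None) -> list:
    """Backward-elimination trajectory from the full set down to one feature.

    At each step the feature whose removal yields the highest f1 is
    eliminated (ties: the larger column index goes).  ``features`` may
    restrict the search to a subset of the table's columns; masks in the
    trajectory are always expressed over the full column list.
    """
    names = table.feature_names
    if features is None:
        mask = FeatureMask.full(len(names))
    else:
        mask = FeatureMask.from_names(features, names)
    if mask.n_selected < 2:
        raise ConfigurationError("SBS needs >= 2 features to start")
    scorer = _scorer or _Scorer(table, clf)
    traj = [SelectionStep(mask.n_selected, mask, scorer.f1(mask))]
    while mask.n_selected > 1:
        best = None  # (f1, column index j to drop)
        for j in np.flatnonzero(mask.bits):
            f1 = scorer.f1(mask.drop(int(j)))
            # tie-break: prefer removing the larger column index
            if best is None or f1 > best[0] or (f1 == best[0] and j > best[1]):
                best = (f1, int(j))
        mask = mask.drop(best[1])
        traj.append(SelectionStep(mask.n_selected, mask, best[0]))
    return traj


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def pso(table: FeatureTable, clf, pso_cfg: PSOConfig | None = None,
        fit_cfg: FitnessConfig | None = None) -> tuple:
    """Binary PSO over feature masks; returns (best FeatureMask, best f2).

    Positions are Bernoulli(0.5)-initialized (all-zero candidates repaired
    by activating one uniformly random bit); velocities evolve with the
    configured inertia and accelerations and are clamped to ±v_max; the
    sigmoid of each velocity component is the probability of selecting
    that feature in the next position.
    """
    d = len(table.feature_names)
    if d < 2:
        raise ConfigurationError("PSO needs >= 2 features")
    pso_cfg = pso_cfg or PSOConfig()
    if fit_cfg is None:
        fit_cfg = FitnessConfig(all_features=d,
                                baseline_error=baseline_error(table, clf))
    rng = np.random.default_rng(pso_cfg.seed)
    scorer = _Scorer(table, clf)

    def f2_of(bits: np.ndarray) -> float:
        mask = FeatureMask(tuple(int(b) for b in bits))
        err = 1.0 - scorer.f1(mask)
        if fit_cfg.baseline_error > 0:
            rel = err / fit_cfg.baseline_error
        else:
            rel = 0.0 if err == 0.0 else float("inf")
        n_all = fit_cfg.all_features or d
        return fit_cfg.alpha * (mask.n_selected / n_all) + (1 - fit_cfg.alpha) * rel

    def repair(bits: np.ndarray) -> np.ndarray:
        if not bits.any():
            bits[rng.integers(d)] = 1
        return bits

    P = pso_cfg.population
    pos = (rng.uniform(size=(P, d)) < 0.5).astype(int)
    for i in range(P):
        repair(pos[i])
    vel = rng.uniform(-1.0, 1.0, size=(P, d))
    pbest = pos.copy()
    pbest_f2 = np.array([f2_of(pos[i]) for i in range(P)])
    g = int(np.argmin(pbest_f2))
    gbest, gbest_f2 = pbest[g].copy(), float(pbest_f2[g])

    for _ in range(pso_cfg.max_iter):
        r1 = rng.uniform(size=(P, d))
        r2 = rng.uniform(size=(P, d))
        vel = (pso_cfg.inertia * vel
               + pso_cfg.c1 * r1 * (pbest - pos)
               + pso_cfg.c2 * r2 * (gbest[None, :] - pos))
        np.clip(vel, -pso_cfg.v_max, pso_cfg.v_max, out=vel)
        pos = (rng.uniform(size=(P, d)) < _sigmoid(vel)).astype(int)
        for i in range(P):
            repair(pos[i])
            f2 = f2_of(pos[i])
            if f2 < pbest_f2[i]:
                pbest[i], pbest_f2[i] = pos[i].copy(), f2
                if f2 < gbest_f2:
                    gbest, gbest_f2 = pos[i].copy(), f2
    return FeatureMask(tuple(int(b) for b in gbest)), gbest_f2


@dataclass(frozen=True)
class HybridResult:
    pso_mask: FeatureMask
    pso_f2: float
    trajectory: tuple  # SelectionStep entries (PSO best first, then SBS)


def hybrid_pso_sbs(table: FeatureTable, clf, pso_cfg: PSOConfig | None = None,
                   fit_cfg: FitnessConfig | None = None) -> HybridResult:
    """PSO for a good subset, then SBS within it to shrink the dimension."""
    best_mask, best_f2 = pso(table, clf, pso_cfg, fit_cfg)
    scorer = _Scorer(table, clf)
    if best_mask.n_selected <= 1:
        step = SelectionStep(best_mask.n_selected, best_mask, scorer.f1(best_mask))
        return HybridResult(best_mask, best_f2, (step,))
    traj = sbs(table, clf,
               features=best_mask.selected_names(table.feature_names),
               _scorer=scorer)
    return HybridResult(best_mask, best_f2, tuple(traj))


def cap_select(trajectory: Sequence[SelectionStep],
               max_dim: int | float = 4) -> tuple:
    """Best (mask, f1) among trajectory entries of dimension <= max_dim.

    Ties in f1 break toward the smaller dimension.  Raises when no entry
    fits within the cap.
    """
    if not trajectory:
        raise ConfigurationError("empty trajectory")
    within = [s for s in trajectory if s.dimension <= max_dim]
    if not within:
        raise CogloadError(f"no trajectory entry within dimension cap {max_dim}")
    best = max(within, key=lambda s: (s.f1, -s.dimension))
    return best.mask, best.f1
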