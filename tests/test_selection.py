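"""Wrapper feature selection: LOSO fitness, SBS, binary PSO, hybrid, cap."""

import numpy as np
import pytest
from sklearn.dummy import DummyClassifier

import cogload as cg
from conftest import make_paired_table, make_table
from cogload.selection import (FeatureMask, FitnessConfig, PSOConfig,
                               SelectionStep, baseline_error, cap_select,
                               hybrid_pso_sbs, loso_fitness, pso, pso_fitness,
                               sbs)
from cogload.types import CogloadError

DT = cg.ClassifierSpec("DT")
ALL_CLF = [cg.ClassifierSpec(k) for k in cg.ClassifierSpec.KINDS]


# ------------------------------------------------------------- loso_fitness

def test_majority_dummy_on_paired_design_scores_half():
    # each training fold ties 3–3, so the constant prediction gets exactly
    # one of the held-out subject's two rows (hand enumeration)
    table = make_paired_table(n_subjects=4)
    cv = loso_fitness(table, FeatureMask.full(3),
                      DummyClassifier(strategy="most_frequent"))
    assert cv.f1 == 0.5


def test_majority_dummy_on_subject_disjoint_classes_scores_zero():
    # the training majority is always the class not held out
    table = make_table(n_subjects=4, n_features=3, rows_per_subject=1)
    cv = loso_fitness(table, FeatureMask.full(3),
                      DummyClassifier(strategy="most_frequent"))
    assert cv.f1 == 0.0


@pytest.mark.parametrize("clf", ALL_CLF, ids=lambda c: c.kind)
def test_separable_clusters_reach_perfect_f1(clf):
    table = make_table(n_subjects=10, n_features=4, informative=4, sep=8.0,
                       rows_per_subject=2, seed=1)
    cv = loso_fitness(table, FeatureMask.full(4), clf)
    assert cv.f1 == 1.0


def test_per_subject_counts_sum_to_total_accuracy():
    table = make_table(n_subjects=8, n_features=3, rows_per_subject=2, seed=2)
    cv = loso_fitness(table, FeatureMask.full(3), DT)
    assert sum(c for _, c, _ in cv.per_subject) == pytest.approx(cv.n_total * cv.f1)


def test_empty_mask_rejected():
    table = make_table(n_subjects=4, n_features=3)
    with pytest.raises(CogloadError):
        loso_fitness(table, FeatureMask((0, 0, 0)), DT)


def test_fold_missing_a_class_is_skipped_with_warning():
    # 3 subjects: the only 'CL' subject's fold leaves a single-class train set
    import pandas as pd
    rng = np.random.default_rng(3)
    rows = [{"subject_id": s, "label": lab,
             **{f"f{j}": rng.normal() for j in range(2)}}
            for s, lab in [("S0", "CL"), ("S1", "BL"), ("S2", "BL")]]
    table = cg.FeatureTable(pd.DataFrame(rows))
    with pytest.warns(UserWarning, match="lacks a class"):
        cv = loso_fitness(table, FeatureMask.full(2), DT)
    assert cv.n_total == 2  # S0's row excluded from the denominator


# -------------------------------------------------------------- pso_fitness

def test_full_mask_fitness_is_one():
    table = make_table(n_subjects=6, n_features=4, rows_per_subject=2, seed=4)
    er = baseline_error(table, DT)
    cfg = FitnessConfig(alpha=0.8, all_features=4, baseline_error=max(er, 1e-9))
    if er > 0:
        assert pso_fitness(FeatureMask.full(4), table, DT, cfg) == pytest.approx(1.0)


def test_half_mask_with_unchanged_error_scores_point_six():
    # a constant classifier's error is independent of the feature mask
    table = make_paired_table(n_subjects=5, n_features=4)
    clf = DummyClassifier(strategy="most_frequent")
    er = baseline_error(table, clf)
    cfg = FitnessConfig(alpha=0.8, all_features=4, baseline_error=er)
    f2 = pso_fitness(FeatureMask((1, 1, 0, 0)), table, clf, cfg)
    assert f2 == pytest.approx(0.8 * 0.5 + 0.2 * 1.0)


def test_single_feature_zero_error_arithmetic():
    table = make_table(n_subjects=8, n_features=33, informative=1, sep=10.0,
                       rows_per_subject=1, seed=5)
    cfg = FitnessConfig(alpha=0.8, all_features=33, baseline_error=0.3)
    mask = FeatureMask((1,) + (0,) * 32)
    f2 = pso_fitness(mask, table, cg.ClassifierSpec("KNN"), cfg)
    assert f2 == pytest.approx(0.8 / 33)


def test_fitness_monotone_in_subset_size_at_fixed_error():
    table = make_paired_table(n_subjects=5, n_features=6)
    clf = DummyClassifier(strategy="most_frequent")
    cfg = FitnessConfig(alpha=0.8, all_features=6,
                        baseline_error=baseline_error(table, clf))
    f2 = [pso_fitness(FeatureMask((1,) * k + (0,) * (6 - k)), table, clf, cfg)
          for k in range(1, 7)]
    assert all(a < b for a, b in zip(f2, f2[1:]))


# ---------------------------------------------------------------------- SBS

def test_sbs_trajectory_dimensions_descend_to_one():
    table = make_table(n_subjects=6, n_features=5, rows_per_subject=2, seed=6)
    traj = sbs(table, DT)
    assert [s.dimension for s in traj] == [5, 4, 3, 2, 1]


def test_sbs_keeps_the_informative_feature_last():
    for seed in range(20):
        table = make_table(n_subjects=8, n_features=5, informative=1, sep=8.0,
                           rows_per_subject=1, seed=seed)
        traj = sbs(table, DT)
        assert traj[-1].mask.selected_names(table.feature_names) == ["feat0"]


def test_sbs_equals_exhaustive_remove_one_search():
    table = make_table(n_subjects=6, n_features=5, informative=2, sep=2.0,
                       rows_per_subject=2, seed=7)
    traj = sbs(table, DT)
    # independent oracle: at each step, evaluate all remove-one masks
    mask = FeatureMask.full(5)
    for step in traj[1:]:
        best = None
        for j in np.flatnonzero(mask.bits):
            f1 = loso_fitness(table, mask.drop(int(j)), DT).f1
            if best is None or f1 > best[0] or (f1 == best[0] and j > best[1]):
                best = (f1, int(j))
        mask = mask.drop(best[1])
        assert step.mask == mask
        assert step.f1 == pytest.approx(best[0])


def test_sbs_trajectory_f1_matches_recomputation_from_masks():
    table = make_table(n_subjects=6, n_features=4, rows_per_subject=2, seed=8)
    for step in sbs(table, DT):
        assert loso_fitness(table, step.mask, DT).f1 == pytest.approx(step.f1)


# ---------------------------------------------------------------------- PSO

PSO_CFG = PSOConfig(population=12, max_iter=10, seed=0)


def test_pso_best_no_worse_than_initial_population():
    table = make_table(n_subjects=8, n_features=6, informative=1, sep=6.0,
                       rows_per_subject=1, seed=9)
    er = baseline_error(table, DT)
    fit = FitnessConfig(alpha=0.8, all_features=6, baseline_error=max(er, 1e-9))
    mask, f2 = pso(table, DT, PSO_CFG, fit)
    rng = np.random.default_rng(PSO_CFG.seed)
    init = (rng.uniform(size=(PSO_CFG.population, 6)) < 0.5).astype(int)
    for bits in init:
        if not bits.any():
            bits[rng.integers(6)] = 1
        assert f2 <= pso_fitness(FeatureMask(tuple(bits)), table, DT, fit) + 1e-12


def test_pso_deterministic_under_fixed_seed():
    table = make_table(n_subjects=8, n_features=6, informative=1, sep=6.0,
                       rows_per_subject=1, seed=10)
    a = pso(table, DT, PSO_CFG)
    b = pso(table, DT, PSO_CFG)
    assert a[0] == b[0] and a[1] == b[1]


def test_pso_recovers_planted_informative_feature():
    hits = 0
    for seed in range(10):
        table = make_table(n_subjects=10, n_features=6, informative=1, sep=8.0,
                           rows_per_subject=1, seed=seed)
        cfg = PSOConfig(population=12, max_iter=10, seed=seed)
        mask, _ = pso(table, DT, cfg)
        hits += mask.bits[0] == 1
    assert hits >= 9


# ------------------------------------------------------------------- hybrid

def test_hybrid_sbs_stage_restricted_to_pso_mask():
    table = make_table(n_subjects=8, n_features=6, informative=2, sep=4.0,
                       rows_per_subject=1, seed=11)
    res = hybrid_pso_sbs(table, DT, PSO_CFG)
    pso_set = set(np.flatnonzero(res.pso_mask.bits))
    for step in res.trajectory:
        assert set(np.flatnonzero(step.mask.bits)) <= pso_set
        assert step.dimension <= res.pso_mask.n_selected


def test_hybrid_recovers_planted_informative_feature():
    hits = 0
    for seed in range(10):
        table = make_table(n_subjects=10, n_features=6, informative=1, sep=8.0,
                           rows_per_subject=1, seed=seed)
        res = hybrid_pso_sbs(table, DT, PSOConfig(population=12, max_iter=10,
                                                  seed=seed))
        final = res.trajectory[-1]
        hits += final.mask.selected_names(table.feature_names) == ["feat0"]
    assert hits >= 9


# --------------------------------------------------------------- cap_select

def _traj(entries):
    return [SelectionStep(d, FeatureMask((1,) * d + (0,) * (5 - d)), f1)
            for d, f1 in entries]


def test_cap_select_picks_best_within_cap():
    traj = _traj([(5, 0.95), (4, 0.93), (3, 0.94), (2, 0.80)])
    mask, f1 = cap_select(traj, 4)
    assert (mask.n_selected, f1) == (3, 0.94)


def test_cap_select_all_above_cap_errors():
    with pytest.raises(CogloadError):
        cap_select(_traj([(5, 0.95)]), 4)


def test_cap_select_unbounded_is_global_argmax():
    traj = _traj([(5, 0.95), (4, 0.93), (3, 0.94)])
    mask, f1 = cap_select(traj, float("inf"))
    assert (mask.n_selected, f1) == (5, 0.95)


def test_cap_select_tie_prefers_smaller_dimension():
    traj = _traj([(4, 0.9), (3, 0.9), (2, 0.8)])
    mask, _ = cap_select(traj, 4)
    assert mask.n_selected == 3
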