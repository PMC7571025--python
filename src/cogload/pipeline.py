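"""End-to-end orchestration of one recognition model.

``run_model`` wires the stages together for one of the six model
definitions (problem × signal family):

1. tune entropy parameters on the problem's two groups of RR series;
2. extract the HRV and/or per-channel EEG feature vectors;
3. assemble the binary problem and balance the minority class
   (Borderline-SMOTE1) when the classes are unequal;
4. select features (SBS, binary PSO, or PSO→SBS) under LOSO fitness;
5. apply the dimension cap and evaluate the final subset under LOSO,
   reporting confusion counts and the study's metric set.

The report is a plain JSON-serializable dict; reruns with the same seed
produce byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import eeg as eeg_mod
from . import hrv as hrv_mod
from .classify import confusion, metrics
from .datasets import borderline_smote1, build_problem
from .selection import (FeatureMask, FitnessConfig, PSOConfig, SelectionStep,
                        baseline_error, cap_select, hybrid_pso_sbs,
                        loso_fitness, loso_predict, sbs)
from .synthetic import Cohort
from .tuning import tune_feature
from .types import (ClassifierSpec, ConfigurationError, FeatureTable,
                    ModelSpec, MODEL_SPECS)

__all__ = ["RunConfig", "extract_features", "tune_cohort_entropy", "run_model",
           "report_json"]

log = logging.getLogger(__name__)

_ENTROPY_FEATURES = ("ApEn", "SampEn", "PeEn", "MFEn")


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one pipeline run; defaults mirror the study protocol."""

    classifier: ClassifierSpec = ClassifierSpec("DT")
    method: str = "sbs"  # 'sbs', 'pso' or 'pso+sbs'
    cap: int = 4
    alpha: float = 0.8
    pso: PSOConfig = field(default_factory=PSOConfig)
    balance: bool = True
    balance_k: int = 5
    tune_entropy: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("sbs", "pso", "pso+sbs"):
            raise ConfigurationError("method must be 'sbs', 'pso' or 'pso+sbs'")


def tune_cohort_entropy(cohort: Cohort, spec: ModelSpec) -> dict:
    """Entropy-parameter tuning on the problem's two RR-series groups."""
    if spec.problem == "CL_vs_BL":
        group_a = [rr for (sid, c), rr in cohort.rr.items() if c == "CL"]
        group_b = [rr for (sid, c), rr in cohort.rr.items() if c == "BL"]
    else:
        bad = {s.subject_id for s in cohort.subjects if s.performance_group == "B"}
        group_a = [rr for (sid, c), rr in cohort.rr.items()
                   if c == "CL" and sid in bad]  # CLMM
        group_b = [rr for (sid, c), rr in cohort.rr.items()
                   if c == "CL" and sid not in bad]  # CLM
    results = {}
    for feature in _ENTROPY_FEATURES:
        results[feature] = tune_feature(feature, group_a, group_b,
                                        problem=spec.problem)
    return results


def extract_features(cohort: Cohort, entropy_params: Mapping | None = None,
                     include_hrv: bool = True, include_eeg: bool = True) -> FeatureTable:
    """One feature row per subject-condition, labeled by condition."""
    rows = []
    for subject in cohort.subjects:
        for cond in cohort.conditions:
            row = {"subject_id": subject.subject_id, "label": cond, "synthetic": 0}
            if include_hrv:
                rr = cohort.rr[(subject.subject_id, cond)]
                row.update(hrv_mod.extract_all(rr, entropy_params))
            if include_eeg:
                seg = cohort.eeg[(subject.subject_id, cond)]
                row.update(eeg_mod.extract_all(seg))
            rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


def _trajectory_json(traj, names) -> list:
    return [{"dimension": s.dimension,
             "features": s.mask.selected_names(names),
             "f1": s.f1} for s in traj]


def run_model(spec: ModelSpec | str, cohort: Cohort,
              config: RunConfig | None = None) -> dict:
    """Run one model end-to-end; returns a JSON-serializable report."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    config = config or RunConfig()

    # 1. entropy-parameter tuning (or the tuned study defaults)
    if config.tune_entropy:
        tuning = tune_cohort_entropy(cohort, spec)
        entropy_params = {k: v.params for k, v in tuning.items()}
        tuning_report = {k: v.to_dict() for k, v in tuning.items()}
        for k in tuning_report:  # the full grid is bulky; keep the choice
            tuning_report[k].pop("grid", None)
    else:
        entropy_params = None
        tuning_report = None

    # 2. feature extraction restricted to the model's signal family
    table = extract_features(
        cohort, entropy_params,
        include_hrv=spec.signals in ("HRV", "HRV+EEG"),
        include_eeg=spec.signals in ("EEG", "HRV+EEG"))

    # 3. problem assembly and balancing
    problem = build_problem(table, spec, cohort.subjects)
    counts = problem.class_counts()
    if config.balance and len(set(counts.values())) > 1:
        problem = borderline_smote1(problem, max(counts.values()),
                                    k=config.balance_k, seed=config.seed)
        log.info("balanced %s: %s -> %s", spec.name, counts, problem.class_counts())

    # 4. feature selection
    names = problem.feature_names
    er = baseline_error(problem, config.classifier)
    fit_cfg = FitnessConfig(alpha=config.alpha, all_features=len(names),
                            baseline_error=er)
    if config.method == "sbs":
        traj = sbs(problem, config.classifier)
        pso_info = None
    elif config.method == "pso":
        mask, f2 = _pso_with_seed(problem, config, fit_cfg)
        traj = [SelectionStep(mask.n_selected, mask,
                              loso_fitness(problem, mask, config.classifier).f1)]
        pso_info = {"f2": f2, "features": mask.selected_names(names)}
    else:
        res = hybrid_pso_sbs(problem, config.classifier,
                             _seeded_pso_cfg(config), fit_cfg)
        traj = list(res.trajectory)
        pso_info = {"f2": res.pso_f2,
                    "features": res.pso_mask.selected_names(names)}

    # 5. cap, final evaluation, metric arithmetic
    mask, f1 = cap_select(traj, config.cap)
    cv = loso_fitness(problem, mask, config.classifier)
    y_true, y_pred, _ = loso_predict(problem, mask, config.classifier)
    cm = confusion(y_pred, y_true, spec.positive_label)
    ms = metrics(cm)

    return {
        "model": spec.name,
        "problem": spec.problem,
        "signals": spec.signals,
        "classifier": config.classifier.kind,
        "method": config.method,
        "seed": config.seed,
        "entropy_tuning": tuning_report,
        "baseline_error": er,
        "pso": pso_info,
        "trajectory": _trajectory_json(traj, names),
        "selected_features": mask.selected_names(names),
        "cv": {"f1": cv.f1, "n_total": cv.n_total,
               "per_subject": [list(t) for t in cv.per_subject]},
        "confusion": {"TP": cm.TP, "TN": cm.TN, "FP": cm.FP, "FN": cm.FN,
                      "positive_class": cm.positive_class},
        "metrics": ms.to_dict(),
    }


def _seeded_pso_cfg(config: RunConfig) -> PSOConfig:
    p = config.pso
    return PSOConfig(population=p.population, max_iter=p.max_iter,
                     inertia=p.inertia, c1=p.c1, c2=p.c2, v_max=p.v_max,
                     seed=config.seed)


def _pso_with_seed(problem, config, fit_cfg):
    from .selection import pso
    return pso(problem, config.classifier, _seeded_pso_cfg(config), fit_cfg)


def report_json(report: dict) -> str:
    """Canonical JSON rendering of a run report (stable across reruns)."""
    return json.dumps(report, sort_keys=True, indent=1)
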