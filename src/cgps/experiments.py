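"""Reference experiments on synthetic cohorts.

These functions encode the study-replica experiments the package is
validated with: a role-split cohort (a small exploratory discovery arm plus
a larger independent validation arm drawn from one simulated multi-centre
cohort), full planted-structure recovery through the discovery pipeline,
and Youden-threshold recovery at the subject level.  Both the test suite
and the acceptance script drive these entry points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import stage_seed
from .containers import Cohort
from .model import CGPSStudy, CGPSStudyResults
from .simulate import (DEFAULT_BOUNDARIES, OPTIMAL_COMBO, DISEASE_TEMPLATE,
                       SimConfig, generate_cohort)
from .stats import roc_with_youden

#: discovery-arm design: a small exploratory arm, as in two-cohort
#: biomarker studies (5 healthy donors + 5 progressed patients)
N_DISCOVERY_HD = 5
N_DISCOVERY_DP = 5


def role_split_cohort(seed: int, n_per_group: int = 30,
                      cells_per_subject: int = 2000,
                      outcome_label_noise: float = 0.0
                      ) -> tuple[Cohort, Cohort, Cohort]:
    """One simulated cohort split into discovery and validation roles.

    The discovery role takes the first 5 healthy donors and the first 5
    progressed (DP) patients; everyone else is validation.  Returns
    ``(discovery, validation, full)``.
    """
    cfg = SimConfig(
        n_subjects={g: n_per_group for g in
                    ("HD", "nonGVHD_stable", "nonGVHD_active",
                     "cGVHD_nonDP", "cGVHD_DP")},
        cells_per_subject=cells_per_subject,
        outcome_label_noise=outcome_label_noise,
        seed=stage_seed(seed, "simulate"))
    full = generate_cohort(cfg)
    subj = full.subjects
    disc_ids = (subj.loc[subj["sim_group"] == "HD", "subject_id"]
                .head(N_DISCOVERY_HD).tolist()
                + subj.loc[subj["sim_group"] == "cGVHD_DP", "subject_id"]
                .head(N_DISCOVERY_DP).tolist())
    valid_ids = [sid for sid in subj["subject_id"] if sid not in disc_ids]
    return full.subset(disc_ids), full.subset(valid_ids), full


@dataclass
class PlantedRecovery:
    """Outcome of one seeded planted-structure recovery run."""

    seed: int
    cluster_recall: float           # planted disease cells captured
    cluster_disease_fraction: float  # cGVHD fraction of the found cluster
    candidates: list[str]
    selected_markers: tuple[str, ...]
    panel_contains_combo: bool       # CD20/CD27/CD86 within the panel
    validation_auc: float
    threshold_nonGVHD: float | None
    threshold_cGVHD: float | None
    disease_auc: float | None
    results: CGPSStudyResults | None = None


def planted_recovery(seed: int, n_per_group: int = 30,
                     cells_per_subject: int = 2000,
                     keep_results: bool = False) -> PlantedRecovery:
    """Run the full discovery arm on one role-split cohort and measure how
    much of the planted structure is recovered."""
    discovery, validation, full = role_split_cohort(
        seed, n_per_group=n_per_group, cells_per_subject=cells_per_subject)
    study = CGPSStudy(discovery=discovery, validation=validation, n_boot=200)
    results = study.fit(seed=seed)

    # recall of planted disease-template cells by the identified cluster
    meta = results.clustering.meta
    # meta rows are ordered sample-by-sample with cell_index into the sample
    truth = np.concatenate([
        full.cell_truth[s.sample_id][
            meta.loc[meta["sample_id"] == s.sample_id, "cell_index"]
            .to_numpy()]
        for s in discovery.samples])
    is_disease = truth == DISEASE_TEMPLATE
    in_cluster = results.clustering.cluster_mask(results.disease_cluster)
    recall = (float((is_disease & in_cluster).sum() / is_disease.sum())
              if is_disease.any() else float("nan"))
    comp = results.clustering.composition
    row = comp[(comp["cluster"] == results.disease_cluster)
               & (comp["group"] == "cGVHD")]
    disease_fraction = float(row["fraction"].iloc[0]) if len(row) else 0.0

    thr = {c: (results.thresholds_fitted[c].youden_threshold
               if c in results.thresholds_fitted else None)
           for c in ("nonGVHD", "cGVHD")}
    return PlantedRecovery(
        seed=seed, cluster_recall=recall,
        cluster_disease_fraction=disease_fraction,
        candidates=results.candidate_markers,
        selected_markers=results.selected_markers,
        panel_contains_combo=set(OPTIMAL_COMBO)
        <= set(results.selected_markers),
        validation_auc=float(results.selected.validation_auc),
        threshold_nonGVHD=thr["nonGVHD"], threshold_cGVHD=thr["cGVHD"],
        disease_auc=(float(results.disease_roc.auc)
                     if results.disease_roc else None),
        results=results if keep_results else None)


def threshold_recovery(seed: int, context: str = "nonGVHD",
                       n_per_group: int = 30) -> tuple[float, float]:
    """Recover the Youden threshold from subject-level planted frequencies.

    Per-subject frequencies are drawn from the two groups straddling the
    context's decision boundary; outcome labels follow the planted
    frequency (noiseless coupling).  Returns ``(recovered_threshold,
    generator_boundary)``.
    """
    if context == "nonGVHD":
        groups = ("nonGVHD_stable", "nonGVHD_active")
    elif context == "cGVHD":
        groups = ("cGVHD_nonDP", "cGVHD_DP")
    else:
        raise ValueError(f"unknown context {context!r}")
    boundary = DEFAULT_BOUNDARIES[context]
    cfg = SimConfig(
        n_subjects={g: (n_per_group if g in groups else 0)
                    for g in ("HD", "nonGVHD_stable", "nonGVHD_active",
                              "cGVHD_nonDP", "cGVHD_DP")},
        cells_per_subject=1,  # frequencies only; cells are not used
        seed=stage_seed(seed, "thresholds"))
    rng = np.random.default_rng(cfg.seed)
    from .simulate import DEFAULT_FREQ, CGVHD_FLOOR_PCT, _draw_frequency
    scores, labels = [], []
    for g in groups:
        mean, sd = DEFAULT_FREQ[g]
        for _ in range(n_per_group):
            f = _draw_frequency(rng, mean, sd)
            if context == "cGVHD":
                f = max(f, CGVHD_FLOOR_PCT)
            scores.append(f)
            labels.append(1 if f > boundary else 0)
    labels = np.asarray(labels)
    if labels.min() == labels.max():  # degenerate draw: no straddle
        return float("nan"), boundary
    res = roc_with_youden(np.asarray(scores), labels, n_boot=1,
                          seed=stage_seed(seed, "evaluate"))
    return float(res.youden_threshold), boundary
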