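"""Exhaustive marker-combination screening and two-stage panel selection.

Stage 1 (screen): for every candidate marker subset, a random forest is
trained on discovery-cohort cells to recognise the disease-associated cell
cluster from that subset alone; subsets whose held-out accuracy exceeds 0.90
survive, and their fitted classifier is frozen (serialised and hashed).

Stage 2 (validate): each frozen classifier scores every cell of an
independent cohort — no re-training — per-subject scores are the mean
predicted disease probability over the subject's cells, and the subject-level
ROC AUC (disease vs healthy) must exceed 0.90.

Final selection: among stage-2 survivors, the fewest markers win; equal
sizes are ranked by validation AUC, then lexicographically by marker names.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from ._utils import sha256_bytes
from .cluster import ClusterResult
from .containers import Cohort
from .stats import auc_score

ACCURACY_CUTOFF = 0.90
AUC_CUTOFF = 0.90
DEFAULT_SPLIT = 0.70
N_TREES = 100
#: cap on positive (disease-cluster) cells in the screening matrix
DEFAULT_CLASS_CAP = 300
#: negatives kept per positive: rebalances the rare positive class while
#: retaining enough rare near-miss negatives for the trees to learn from
DEFAULT_NEGATIVE_RATIO = 2.0


@dataclass
class MarkerComboResult:
    """One marker subset with its frozen classifier and stage outcomes."""

    markers: tuple[str, ...]
    combo_class: str
    model_bytes: bytes | None = None
    model_hash: str | None = None
    train_accuracy: float | None = None
    validation_auc: float | None = None
    passed_stage1: bool = False
    passed_stage2: bool = False
    seed: int | None = None

    def model(self):
        if self.model_bytes is None:
            raise ValueError(f"combo {self.markers} has no frozen model")
        return pickle.loads(self.model_bytes)

    def row(self) -> dict:
        return {
            "markers": "/".join(self.markers),
            "combo_class": self.combo_class,
            "train_accuracy": self.train_accuracy,
            "validation_auc": self.validation_auc,
            "passed_stage1": self.passed_stage1,
            "passed_stage2": self.passed_stage2,
            "model_hash": self.model_hash,
        }


def results_table(results: Sequence[MarkerComboResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results])


def enumerate_combos(candidates: Sequence[str],
                     sizes: Sequence[int]) -> list[tuple[str, ...]]:
    """All subsets of each requested size, in deterministic lexicographic
    order (within and across sizes)."""
    candidates = sorted(candidates)
    sizes = sorted(set(int(s) for s in sizes))
    for s in sizes:
        if s < 2 or s > len(candidates):
            raise ValueError(
                f"combination size {s} out of range 2..{len(candidates)}")
    out: list[tuple[str, ...]] = []
    for s in sizes:
        out.extend(combinations(candidates, s))
    return out


def _screen_cells(cohort: Cohort, markers: Sequence[str],
                  cluster_result: ClusterResult | None,
                  cluster_id: int | None,
                  rng: np.random.Generator,
                  class_cap: int | None,
                  negative_ratio: float = DEFAULT_NEGATIVE_RATIO
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (cells, labels) screening matrix restricted to a subset.

    With a cluster result, label 1 marks membership in the disease cluster
    (the clinically positive cell population); classes are rebalanced by
    seeded downsampling so that held-out accuracy measures separation
    rather than prevalence.  Half of the kept negatives are *hard*: the
    ones closest to the positive-class centroid in the candidate marker
    subspace.  Without mining, rare look-alike populations (cells matching
    the disease phenotype on all but one marker) can be bootstrap-starved
    out of the forest, and an ambiguous combination can screen as clean.

    Without a cluster result, cells inherit their subject's clinical label
    (cGVHD 1, HD 0) — provided for completeness; at realistic disease-subset
    frequencies this unit cannot reach high accuracy because most patient
    cells are phenotypically normal.
    """
    panel = cohort.markers
    missing = [m for m in markers if m not in panel]
    if missing:
        raise KeyError(f"markers absent from cohort: {missing}")
    cols = [panel.index(m) for m in markers]

    if cluster_result is not None:
        if cluster_id is None:
            raise ValueError("cluster_id required with cluster_result")
        X = cluster_result.cells[:, cols]
        y = cluster_result.cluster_mask(int(cluster_id)).astype(int)
    else:
        X_all, meta = cohort.pooled()
        keep = meta["group"].isin(["HD", "cGVHD"]).to_numpy()
        X = X_all[keep][:, cols]
        y = (meta.loc[keep, "group"] == "cGVHD").to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("screening needs both classes present")

    if class_cap is not None:
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        n_pos = min(len(idx_pos), class_cap)
        n_neg = min(len(idx_neg), int(round(negative_ratio * n_pos)))
        keep_pos = rng.choice(idx_pos, size=n_pos, replace=False)
        centroid = X[keep_pos].mean(axis=0)
        dist = np.linalg.norm(X[idx_neg] - centroid, axis=1)
        order = np.argsort(dist, kind="stable")
        n_hard = min(n_neg // 2, len(idx_neg))
        # sample the hard half uniformly from a wider near-positive pool
        # (nearest 10%, at least 3x the hard count) so that *every*
        # look-alike population is represented, not just the nearest band
        pool_size = min(len(idx_neg),
                        max(3 * n_hard, int(0.10 * len(idx_neg))))
        hard = rng.choice(idx_neg[order[:pool_size]], size=n_hard,
                          replace=False)
        remaining = np.setdiff1d(idx_neg, hard, assume_unique=False)
        rest = rng.choice(remaining, size=n_neg - n_hard, replace=False)
        take = np.concatenate([keep_pos, hard, rest])
        take.sort()
        X, y = X[take], y[take]
    return X, y


def screen_combo(cohort1: Cohort, markers: Sequence[str],
                 split_fraction: float = DEFAULT_SPLIT, seed: int = 0, *,
                 cluster_result: ClusterResult | None = None,
                 cluster_id: int | None = None,
                 class_cap: int | None = DEFAULT_CLASS_CAP,
                 negative_ratio: float = DEFAULT_NEGATIVE_RATIO,
                 n_candidates: int | None = None,
                 accuracy_cutoff: float = ACCURACY_CUTOFF) -> MarkerComboResult:
    """Stage 1: train/test a random forest on one marker subset and freeze it.

    70% of cells train the forest, 30% measure accuracy (split seeded and
    stratified).  ``passed_stage1`` requires accuracy > 0.90.  The fitted
    model is pickled immediately; its hash is the freeze certificate checked
    again at validation time.
    """
    if not (0 < split_fraction < 1):
        raise ValueError("split_fraction must be in (0, 1)")
    markers = tuple(markers)
    rng = np.random.default_rng(seed)
    X, y = _screen_cells(cohort1, markers, cluster_result, cluster_id,
                         rng, class_cap, negative_ratio)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_fraction, stratify=y,
        random_state=int(rng.integers(2**31)))
    # all features are candidates at every split: with 2-3 marker panels,
    # sqrt-feature subsampling would starve trees of the one marker that
    # resolves a near-miss population
    clf = RandomForestClassifier(n_estimators=N_TREES, max_features=None,
                                 n_jobs=1,
                                 random_state=int(rng.integers(2**31)))
    clf.fit(X_tr, y_tr)
    acc = float((clf.predict(X_te) == y_te).mean())
    blob = pickle.dumps(clf, protocol=5)
    n_cand = n_candidates if n_candidates is not None else len(markers)
    return MarkerComboResult(
        markers=markers, combo_class=f"C{n_cand}{len(markers)}",
        model_bytes=blob, model_hash=sha256_bytes(blob),
        train_accuracy=acc, passed_stage1=acc > accuracy_cutoff, seed=seed)


def validate_combo(result: MarkerComboResult, cohort2: Cohort,
                   aggregation: str = "per_subject_mean_probability",
                   max_cells_per_subject: int | None = None,
                   seed: int = 0,
                   auc_cutoff: float = AUC_CUTOFF) -> MarkerComboResult:
    """Stage 2: score an independent cohort with the frozen model.

    The model is deserialised from its frozen bytes (hash re-checked), every
    cell of each HD/cGVHD subject is scored, per-subject scores are the mean
    predicted disease probability, and the subject-level AUC (cGVHD = 1,
    HD = 0) must exceed 0.90.  Calling this on a combo that failed stage 1
    is an error: freezing precedes validation.
    """
    if not result.passed_stage1:
        raise ValueError(f"combo {result.markers} did not pass stage 1; "
                         "validation requires a frozen qualifying model")
    if aggregation != "per_subject_mean_probability":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if sha256_bytes(result.model_bytes) != result.model_hash:
        raise ValueError("frozen model bytes do not match their hash")
    clf = result.model()
    panel = cohort2.markers
    cols = [panel.index(m) for m in result.markers]
    rng = np.random.default_rng(seed)

    scores, labels = [], []
    for s in cohort2.samples:
        group = cohort2.group_of(s.subject_id)
        if group not in ("HD", "cGVHD"):
            continue
        X = s.values[:, cols]
        if (max_cells_per_subject is not None
                and X.shape[0] > max_cells_per_subject):
            take = rng.choice(X.shape[0], size=max_cells_per_subject,
                              replace=False)
            X = X[take]
        scores.append(float(clf.predict_proba(X)[:, 1].mean()))
        labels.append(1 if group == "cGVHD" else 0)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation cohort needs both HD and cGVHD subjects")
    auc = auc_score(np.asarray(scores), labels)
    result.validation_auc = float(auc)
    result.passed_stage2 = auc > auc_cutoff
    if sha256_bytes(result.model_bytes) != result.model_hash:
        raise AssertionError("model mutated during validation")
    return result


def select_final_panel(results: Sequence[MarkerComboResult]
                       ) -> MarkerComboResult:
    """Minimal marker count among stage-2 survivors; ties by higher
    validation AUC, then lexicographic marker names."""
    survivors = [r for r in results if r.passed_stage2]
    if not survivors:
        raise ValueError("no panel meets criteria: no stage-2 survivor")
    return min(survivors,
               key=lambda r: (len(r.markers), -r.validation_auc, r.markers))
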