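"""Study-level modelling interface.

:class:`CGPSStudy` is the model object: it is built from a discovery cohort
and an independent validation cohort and owns the analysis settings.  Its
:meth:`~CGPSStudy.fit` runs the full estimation sequence — preprocess,
cluster discovery, marker ranking, combinatorial panel screening and
validation, gate fitting, per-subject scoring and ROC threshold estimation —
and returns a :class:`CGPSStudyResults` carrying the estimates, their
bootstrap uncertainties and a text ``summary()``.  Scoring of new cohorts
(prospective monitoring) hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import sha256_array, stage_seed
from .cluster import (ClusterResult, MarkerRanking, cluster_cells,
                      identify_disease_cluster, rank_cluster_markers)
from .containers import Cohort
from .gating import (DEFAULT_THRESHOLDS, GateSpec, fit_gates, score_cohort)
from .io import scale_and_regress, transform_cohort
from .panel import (MarkerComboResult, enumerate_combos, results_table,
                    screen_combo, select_final_panel, validate_combo)
from .stats import ContingencySummary, ROCThresholdResult, contingency_eval, \
    roc_with_youden


@dataclass
class CGPSStudy:
    """The two-cohort biomarker discovery model.

    Parameters
    ----------
    discovery, validation : Cohort
        Disjoint cohorts.  Discovery drives clustering and stage-1
        screening; validation drives stage-2 AUC, gate reference and
        threshold estimation.
    combo_sizes : sequence of int
        Marker-subset sizes enumerated during screening.
    cofactor : float
        arcsinh cofactor applied to raw-scale samples.
    covariates : list of str
        Metadata columns regressed out before clustering (batch removal).
    """

    discovery: Cohort
    validation: Cohort
    combo_sizes: Sequence[int] = (2, 3)
    cofactor: float = 150.0
    covariates: Sequence[str] = ("batch",)
    k_neighbors: int = 20
    resolution: float = 0.8
    min_disease_fraction: float = 0.75
    n_candidates: int = 8
    split_fraction: float = 0.70
    class_cap: int = 300
    validate_cells_per_subject: int | None = 1000
    cluster_cells_per_sample: int | None = None
    n_boot: int = 2000

    def __post_init__(self) -> None:
        overlap = (set(s.subject_id for s in self.discovery.samples)
                   & set(s.subject_id for s in self.validation.samples))
        if overlap:
            raise ValueError(f"cohorts share subjects: {sorted(overlap)}")

    def _prepared(self, cohort: Cohort) -> tuple[Cohort, Cohort]:
        """(transformed, batch-regressed-and-scaled) versions of a cohort."""
        transformed = (cohort if cohort.transformed_all()
                       else transform_cohort(cohort, self.cofactor))
        covs = [c for c in self.covariates
                if c in transformed.subjects.columns
                or c in ("batch", "sample_id", "subject_id")]
        usable = []
        for c in covs:
            values = (pd.unique(transformed.subjects[c])
                      if c in transformed.subjects.columns
                      else pd.unique(pd.Series(
                          [s.batch for s in transformed.samples])))
            if len(values) >= 2:
                usable.append(c)
        scaled = scale_and_regress(transformed, usable)
        return transformed, scaled

    def fit(self, seed: int = 0) -> "CGPSStudyResults":
        disc_t, disc_s = self._prepared(self.discovery)
        valid_t, valid_s = self._prepared(self.validation)

        clustering = cluster_cells(
            disc_s, k_neighbors=self.k_neighbors, resolution=self.resolution,
            seed=stage_seed(seed, "cluster"),
            max_cells_per_sample=self.cluster_cells_per_sample)
        disease_cluster = identify_disease_cluster(
            clustering, disease_group="cGVHD",
            min_fraction=self.min_disease_fraction)
        # effect sizes are ranked on the arcsinh axis (interpretable
        # intensity units), on exactly the cells the graph was built from
        blocks = []
        for s in disc_t.samples:
            sel = clustering.meta.loc[
                clustering.meta["sample_id"] == s.sample_id,
                "cell_index"].to_numpy()
            blocks.append(s.values[sel])
        ranking = rank_cluster_markers(disc_t, clustering, disease_cluster,
                                       top_n=self.n_candidates,
                                       values=np.vstack(blocks))
        candidates = ranking.selected
        if len(candidates) < 2:
            raise ValueError("fewer than two candidate markers survived "
                             "the ranking stage")

        combos = enumerate_combos(candidates, self.combo_sizes)
        results: list[MarkerComboResult] = []
        for i, markers in enumerate(combos):
            r = screen_combo(
                disc_s, markers, split_fraction=self.split_fraction,
                seed=stage_seed(seed, "screen", i),
                cluster_result=clustering, cluster_id=disease_cluster,
                class_cap=self.class_cap, n_candidates=len(candidates))
            if r.passed_stage1:
                r = validate_combo(
                    r, valid_s,
                    max_cells_per_subject=self.validate_cells_per_subject,
                    seed=stage_seed(seed, "validate", i))
            results.append(r)
        selected = select_final_panel(results)

        sides = {row["marker"]: ("+" if row["direction"] == "up" else "-")
                 for _, row in ranking.table.iterrows()}
        gates = fit_gates(valid_t, markers=list(selected.markers),
                          sides=sides, seed=stage_seed(seed, "gates"))

        records = score_cohort(valid_t, gates)
        records = records.merge(
            self.validation.subjects[
                [c for c in ("subject_id", "group", "sim_group", "batch",
                             "outcome", "truth")
                 if c in self.validation.subjects.columns]],
            on="subject_id", how="left")

        thresholds_fitted: dict[str, ROCThresholdResult] = {}
        for context, positive in (("nonGVHD", "active"), ("cGVHD", "DP")):
            sub = records[records["group"] == context]
            if len(sub) and sub["outcome"].notna().all() \
                    and len(set(sub["outcome"] == positive)) == 2:
                thresholds_fitted[context] = roc_with_youden(
                    sub["score"].to_numpy(),
                    (sub["outcome"] == positive).to_numpy().astype(int),
                    n_boot=self.n_boot,
                    seed=stage_seed(seed, "thresholds",
                                    0 if context == "nonGVHD" else 1))

        disease_auc = roc_with_youden(
            records.loc[records["group"].isin(["HD", "cGVHD"]), "score"]
                   .to_numpy(),
            (records.loc[records["group"].isin(["HD", "cGVHD"]), "group"]
                    == "cGVHD").to_numpy().astype(int),
            n_boot=self.n_boot, seed=stage_seed(seed, "thresholds", 2)) \
            if {"HD", "cGVHD"} <= set(records["group"]) else None

        return CGPSStudyResults(
            model=self, seed=seed, clustering=clustering,
            disease_cluster=disease_cluster, ranking=ranking,
            combo_results=results, selected=selected, gates=gates,
            records=records, thresholds_fitted=thresholds_fitted,
            disease_roc=disease_auc)


@dataclass
class CGPSStudyResults:
    """Fitted estimates of a :class:`CGPSStudy`."""

    model: CGPSStudy
    seed: int
    clustering: ClusterResult
    disease_cluster: int
    ranking: MarkerRanking
    combo_results: list[MarkerComboResult]
    selected: MarkerComboResult
    gates: GateSpec
    records: pd.DataFrame
    thresholds_fitted: dict[str, ROCThresholdResult]
    disease_roc: ROCThresholdResult | None = None

    # -- derived quantities -------------------------------------------------

    @property
    def selected_markers(self) -> tuple[str, ...]:
        return self.selected.markers

    @property
    def candidate_markers(self) -> list[str]:
        return list(self.ranking.selected)

    def threshold(self, context: str) -> float:
        """Fitted Youden threshold for a context, falling back to the
        published defaults when the retrospective outcome ROC was not
        estimable from the validation cohort."""
        if context in self.thresholds_fitted:
            return float(self.thresholds_fitted[context].youden_threshold)
        return DEFAULT_THRESHOLDS[context]

    def combo_table(self) -> pd.DataFrame:
        return results_table(self.combo_results)

    # -- monitoring ---------------------------------------------------------

    def score_cohort(self, cohort: Cohort,
                     thresholds: Mapping[str, float] | None = None
                     ) -> pd.DataFrame:
        """Gate, score and risk-classify a new cohort with the frozen
        gates; thresholds default to the fitted ones."""
        thresholds = dict(thresholds or {
            c: self.threshold(c) for c in ("nonGVHD", "cGVHD")})
        cohort_t = (cohort if cohort.transformed_all()
                    else transform_cohort(cohort, self.model.cofactor))
        rec = score_cohort(cohort_t, self.gates, thresholds=thresholds)
        keep = [c for c in ("subject_id", "group", "sim_group", "batch",
                            "outcome", "truth")
                if c in cohort.subjects.columns]
        return rec.merge(cohort.subjects[keep], on="subject_id", how="left")

    def evaluate(self, records: pd.DataFrame, context: str,
                 positive_outcome: str | Sequence[str],
                 threshold: float | None = None) -> ContingencySummary:
        """Contingency evaluation of scored records against outcomes."""
        sub = records[records["group"] == context]
        if not len(sub):
            raise ValueError(f"no {context} subjects in records")
        if isinstance(positive_outcome, str):
            positive_outcome = [positive_outcome]
        thr = self.threshold(context) if threshold is None else threshold
        return contingency_eval(sub["score"].to_numpy(),
                                sub["outcome"].isin(positive_outcome)
                                   .to_numpy(),
                                thr)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        lines = []
        w = lines.append
        w("cGPS study results")
        w("=" * 66)
        comp = self.clustering.composition
        n_clusters = comp["cluster"].nunique()
        dc = comp[(comp["cluster"] == self.disease_cluster)
                  & (comp["group"] == "cGVHD")]
        frac = float(dc["fraction"].iloc[0]) if len(dc) else float("nan")
        count = int(dc["count"].iloc[0]) if len(dc) else 0
        w(f"Clusters found:            {n_clusters} "
          f"(k={self.clustering.k_neighbors}, "
          f"resolution={self.clustering.resolution})")
        w(f"Disease-associated cluster: #{self.disease_cluster} "
          f"({100 * frac:.1f}% cGVHD cells, {count} cells)")
        w(f"Candidate markers:         {', '.join(self.candidate_markers)}")
        n1 = sum(r.passed_stage1 for r in self.combo_results)
        n2 = sum(r.passed_stage2 for r in self.combo_results)
        w(f"Combos screened:           {len(self.combo_results)} "
          f"(stage 1 pass: {n1}, stage 2 pass: {n2})")
        w(f"Selected panel:            {'/'.join(self.selected.markers)} "
          f"(validation AUC {self.selected.validation_auc:.3f})")
        if self.disease_roc is not None:
            w(f"cGPS AUC (cGVHD vs HD):    {self.disease_roc.auc:.3f}")
        for ctx, res in self.thresholds_fitted.items():
            lo, hi = res.ci_95["threshold"]
            w(f"{ctx} Youden threshold:   {res.youden_threshold:.3f} "
              f"[95% CI {lo:.3f}, {hi:.3f}] "
              f"(AUC {res.auc:.3f}, sens {res.sensitivity:.2f}, "
              f"spec {res.specificity:.2f})")
        w("")
        w("Per-group cGPS (validation cohort):")
        for group, sub in self.records.groupby("group"):
            w(f"  {group:8s} n={len(sub):3d}  median "
              f"{sub['score'].median():6.2f}  IQR "
              f"[{sub['score'].quantile(.25):.2f}, "
              f"{sub['score'].quantile(.75):.2f}]")
        return "\n".join(lines)

    def manifest(self) -> dict:
        """Hashes of the fitted artefacts, for reproducibility audits."""
        return {
            "seed": self.seed,
            "cluster_labels": sha256_array(self.clustering.labels),
            "disease_cluster": self.disease_cluster,
            "candidates": self.candidate_markers,
            "selected": list(self.selected.markers),
            "selected_model_hash": self.selected.model_hash,
            "gates": self.gates.to_dict(),
            "records_hash": sha256_array(
                self.records["score"].to_numpy()),
            "thresholds": {c: self.threshold(c)
                           for c in ("nonGVHD", "cGVHD")},
        }
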