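"""End-to-end orchestration: simulate → discover → score → evaluate.

Thin wrappers over :class:`~cgps.model.CGPSStudy` that add disk layout, a
reproducibility manifest and a markdown report.  Every random stage consumes
a seed derived deterministically from the single global seed, so a rerun of
the same config is byte-identical (no timestamps enter the manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._utils import sha256_json, stage_seed
from .containers import Cohort
from .io import read_cohort
from .model import CGPSStudy, CGPSStudyResults
from .simulate import SimConfig, generate_cohort, require_group

log = logging.getLogger(__name__)

DISCOVERY_COUNTS = {"HD": 5, "cGVHD_DP": 5}
VALIDATION_COUNTS = {"HD": 17, "nonGVHD_stable": 10, "nonGVHD_active": 5,
                     "cGVHD_nonDP": 20, "cGVHD_DP": 11}


@dataclass
class PipelineConfig:
    """Global seed, cohort design and per-stage analysis parameters."""

    seed: int = 0
    outdir: str = "cgps_run"
    # cohort roles: simulated by default; set paths to use data on disk
    discovery_path: str | None = None
    validation_path: str | None = None
    discovery_counts: dict = field(
        default_factory=lambda: dict(DISCOVERY_COUNTS))
    validation_counts: dict = field(
        default_factory=lambda: dict(VALIDATION_COUNTS))
    cells_per_subject: int = 2000
    outcome_label_noise: float = 0.0
    # analysis parameters
    combo_sizes: tuple = (2, 3)
    k_neighbors: int = 20
    resolution: float = 0.8
    min_disease_fraction: float = 0.75
    n_candidates: int = 8
    split_fraction: float = 0.70
    class_cap: int = 300
    validate_cells_per_subject: int = 1000
    n_boot: int = 2000
    thresholds: dict = field(default_factory=dict)  # override per context

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "combo_sizes" in raw:
            raw["combo_sizes"] = tuple(raw["combo_sizes"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["combo_sizes"] = list(self.combo_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def simulate_role_cohorts(config: PipelineConfig) -> tuple[Cohort, Cohort]:
    """Discovery- and validation-role cohorts from the global seed."""
    sims = []
    for idx, counts in ((0, config.discovery_counts),
                        (1, config.validation_counts)):
        sim = SimConfig(n_subjects=dict(counts),
                        cells_per_subject=config.cells_per_subject,
                        outcome_label_noise=config.outcome_label_noise,
                        seed=stage_seed(config.seed, "simulate", idx))
        sims.append(sim)
    disc, valid = (generate_cohort(s) for s in sims)
    # validation subjects must be disjoint from discovery
    rename = {sid: f"v_{sid}" for sid in valid.subjects["subject_id"]}
    for s in valid.samples:
        new = rename[s.subject_id]
        if valid.cell_truth is not None and s.sample_id in valid.cell_truth:
            valid.cell_truth[new] = valid.cell_truth.pop(s.sample_id)
        s.subject_id = new
        s.sample_id = new
    valid.subjects["subject_id"] = valid.subjects["subject_id"].map(rename)
    return disc, valid


def _load_or_simulate(config: PipelineConfig) -> tuple[Cohort, Cohort]:
    if config.discovery_path and config.validation_path:
        return (read_cohort(config.discovery_path),
                read_cohort(config.validation_path))
    for role, counts in (("discovery", config.discovery_counts),
                         ("validation", config.validation_counts)):
        sim = SimConfig(n_subjects=dict(counts))
        require_group(sim, "HD")
        if role == "validation" and not any(
                counts.get(g, 0) for g in ("cGVHD_nonDP", "cGVHD_DP")):
            raise ValueError("validation role requires cGVHD subjects")
    return simulate_role_cohorts(config)


def _study(config: PipelineConfig, discovery: Cohort,
           validation: Cohort) -> CGPSStudy:
    return CGPSStudy(
        discovery=discovery, validation=validation,
        combo_sizes=config.combo_sizes, k_neighbors=config.k_neighbors,
        resolution=config.resolution,
        min_disease_fraction=config.min_disease_fraction,
        n_candidates=config.n_candidates,
        split_fraction=config.split_fraction, class_cap=config.class_cap,
        validate_cells_per_subject=config.validate_cells_per_subject,
        n_boot=config.n_boot)


def run_discovery(config: PipelineConfig,
                  write: bool = True) -> CGPSStudyResults:
    """Full discovery arm; writes tables plus a manifest when ``write``."""
    stages: list[dict] = []

    def record(stage: str, **info) -> None:
        stages.append({"stage": stage, **info})

    try:
        discovery, validation = _load_or_simulate(config)
        record("simulate", n_discovery=len(discovery),
               n_validation=len(validation),
               seed=stage_seed(config.seed, "simulate", 0))
        study = _study(config, discovery, validation)
        results = study.fit(seed=config.seed)
    except Exception as err:
        done = [s["stage"] for s in stages]
        raise RuntimeError(
            f"discovery pipeline failed after stages {done}: {err}") from err
    record("preprocess", cofactor=study.cofactor,
           covariates=list(study.covariates))
    record("cluster", k=config.k_neighbors, resolution=config.resolution,
           n_clusters=int(results.clustering.composition["cluster"]
                          .nunique()),
           disease_cluster=results.disease_cluster,
           seed=stage_seed(config.seed, "cluster"))
    record("rank_markers", candidates=results.candidate_markers)
    record("screen", n_combos=len(results.combo_results),
           stage1_pass=int(sum(r.passed_stage1
                               for r in results.combo_results)))
    record("validate", stage2_pass=int(sum(r.passed_stage2
                                           for r in results.combo_results)))
    record("select", panel=list(results.selected.markers),
           validation_auc=results.selected.validation_auc)

    manifest = {
        "config": {**dataclasses.asdict(config),
                   "combo_sizes": list(config.combo_sizes)},
        "stages": stages,
        "results": results.manifest(),
    }
    manifest["hash"] = sha256_json(manifest)
    if write:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        results.clustering.composition.to_csv(
            out / "cluster_composition.csv", index=False)
        results.ranking.table.to_csv(out / "marker_ranking.csv", index=False)
        results.combo_table().to_csv(out / "combo_results.csv", index=False)
        results.records.to_csv(out / "cgps_records.csv", index=False)
        with open(out / "gates.yaml", "w") as fh:
            yaml.safe_dump(results.gates.to_dict(), fh)
        with open(out / "thresholds.json", "w") as fh:
            json.dump({c: results.threshold(c)
                       for c in ("nonGVHD", "cGVHD")}, fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
    results.pipeline_manifest = manifest
    return results


def run_monitoring(results: CGPSStudyResults, cohort: Cohort,
                   config: PipelineConfig | None = None,
                   write: bool = True) -> dict:
    """Score a (prospective) cohort and evaluate outcomes when present.

    Returns a dict with the records table and per-context contingency
    summaries; writes ``monitoring_records.csv`` and ``report.md``.
    """
    if not len(cohort.samples):
        raise ValueError("empty cohort")
    config = config or PipelineConfig()
    thresholds = {c: float(config.thresholds.get(c, results.threshold(c)))
                  for c in ("nonGVHD", "cGVHD")}
    missing = cohort.subjects.loc[
        ~cohort.subjects["group"].isin(["HD", "nonGVHD", "cGVHD"]),
        "subject_id"].tolist()
    if missing:
        raise ValueError(f"subjects with unknown context: {missing}")

    records = results.score_cohort(cohort, thresholds=thresholds)
    summaries = {}
    has_outcome = ("outcome" in records.columns
                   and records["outcome"].notna().any())
    if has_outcome:
        for context, positive in (("nonGVHD", ["active"]),
                                  ("cGVHD", ["DP"])):
            sub = records[records["group"] == context]
            if len(sub):
                summaries[context] = results.evaluate(
                    records, context, positive,
                    threshold=thresholds[context])

    report = _render_report(records, summaries, thresholds,
                            overridden=sorted(config.thresholds))
    if write:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "monitoring_records.csv", index=False)
        with open(out / "report.md", "w") as fh:
            fh.write(report)
    return {"records": records, "contingency": summaries,
            "thresholds": thresholds, "report": report}


def _render_report(records: pd.DataFrame, summaries: dict,
                   thresholds: dict, overridden: list[str]) -> str:
    lines = ["# cGPS monitoring report", ""]
    lines.append(f"Subjects scored: {len(records)}")
    for c, t in thresholds.items():
        tag = " (override)" if c in overridden else ""
        lines.append(f"- {c} threshold: {t:.3f}{tag}")
    lines.append("")
    lines.append("| group | n | median cGPS | high risk |")
    lines.append("|---|---|---|---|")
    for group, sub in records.groupby("group"):
        high = int((sub["risk_class"] == "high").sum())
        lines.append(f"| {group} | {len(sub)} | "
                     f"{sub['score'].median():.2f} | {high} |")
    for context, summ in summaries.items():
        lines.append("")
        lines.append(f"## {context} outcome evaluation "
                     f"(threshold {summ.threshold:.3f})")
        a, b = summ.fractions["above_event"]
        c_, d = summ.fractions["below_event"]
        lines.append(f"- above threshold: {a}/{b} with event")
        lines.append(f"- at/below threshold: {c_}/{d} with event")
        lines.append(f"- Fisher exact p = {summ.fisher_p:.3g}")
    lines.append("")
    return "\n".join(lines)
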