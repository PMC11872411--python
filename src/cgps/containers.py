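"""Core data containers: per-sample cell matrices and multi-sample cohorts.

A :class:`CellMatrix` is one sample's cells-by-markers expression table plus
identifying metadata; a :class:`Cohort` bundles one sample per subject with a
subject-level clinical table (group, batch, outcome).  These are the units
that flow through preprocessing, clustering, gating and scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

#: Clinical groups a subject may belong to.
GROUPS = ("HD", "nonGVHD", "cGVHD")
#: Valid outcome labels per group.  Healthy donors carry no outcome.
OUTCOMES = {
    "HD": (None,),
    "nonGVHD": ("stable", "active"),
    "cGVHD": ("DP", "PR", "CR", "SD"),
}


@dataclass
class CellMatrix:
    """One sample's cells × markers expression matrix.

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_markers)
        Expression values. Raw fluorescence scale unless ``transformed``.
    markers : list of str
        Ordered marker (column) names.
    sample_id, subject_id, batch : str
        Identifying metadata.
    transformed : bool
        Whether the arcsinh transform has been applied.  Double
        transformation is a hard error downstream.
    """

    values: np.ndarray
    markers: list[str]
    sample_id: str
    subject_id: str
    batch: str = "batch0"
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells × markers array")
        if self.values.shape[1] != len(self.markers):
            raise ValueError(
                f"column count {self.values.shape[1]} does not match "
                f"{len(self.markers)} marker names")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")
        if np.isnan(self.values).any():
            raise ValueError("missing values in cell matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.markers)

    def marker_column(self, marker: str) -> np.ndarray:
        try:
            j = self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in sample "
                           f"{self.sample_id}") from None
        return self.values[:, j]

    def copy_with(self, **changes) -> "CellMatrix":
        if "values" not in changes:
            changes["values"] = self.values.copy()
        return replace(self, **changes)


@dataclass
class Cohort:
    """A set of samples (one per subject) plus the subject-level table.

    ``subjects`` columns: ``subject_id``, ``group``, ``batch``, ``outcome``
    and, for synthetic cohorts, ``truth`` (the planted disease-subset
    frequency in percent of B cells).
    """

    samples: list[CellMatrix]
    subjects: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: synthetic cohorts only: sample_id -> per-cell template name array
    cell_truth: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("more than one sample per subject_id")
        if len(self.subjects):
            self.subjects = self.subjects.reset_index(drop=True)
            missing = set(ids) - set(self.subjects["subject_id"])
            if missing:
                raise ValueError(f"samples without subject rows: {sorted(missing)}")
            bad = self.subjects.loc[~self.subjects["group"].isin(GROUPS), "group"]
            if len(bad):
                raise ValueError(f"unknown groups: {sorted(set(bad))}")
            for _, row in self.subjects.iterrows():
                allowed = OUTCOMES[row["group"]]
                out = row.get("outcome")
                if out is None or (isinstance(out, float) and np.isnan(out)):
                    out = None
                if row["group"] == "HD":
                    if out is not None:
                        raise ValueError("HD subjects must not carry an outcome")
                elif out is not None and out not in allowed:
                    raise ValueError(
                        f"outcome {out!r} invalid for group {row['group']}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def markers(self) -> list[str]:
        return self.samples[0].markers

    def sample_for(self, subject_id: str) -> CellMatrix:
        for s in self.samples:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def subject_row(self, subject_id: str) -> pd.Series:
        rows = self.subjects[self.subjects["subject_id"] == subject_id]
        if not len(rows):
            raise KeyError(subject_id)
        return rows.iloc[0]

    def group_of(self, subject_id: str) -> str:
        return str(self.subject_row(subject_id)["group"])

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        wanted = list(subject_ids)
        order = {sid: i for i, sid in enumerate(wanted)}
        samples = sorted((s for s in self.samples if s.subject_id in order),
                         key=lambda s: order[s.subject_id])
        if len(samples) != len(wanted):
            missing = set(wanted) - {s.subject_id for s in samples}
            raise KeyError(f"subjects not in cohort: {sorted(missing)}")
        subjects = self.subjects[self.subjects["subject_id"].isin(order)].copy()
        subjects["__o"] = subjects["subject_id"].map(order)
        subjects = subjects.sort_values("__o").drop(columns="__o")
        truth = None
        if self.cell_truth is not None:
            truth = {s.sample_id: self.cell_truth[s.sample_id]
                     for s in samples if s.sample_id in self.cell_truth}
        return Cohort(samples=samples, subjects=subjects, cell_truth=truth)

    def pooled(self, max_cells_per_sample: int | None = None,
               rng: np.random.Generator | None = None
               ) -> tuple[np.ndarray, pd.DataFrame]:
        """Stack cells across samples.

        Returns the pooled matrix and a per-cell metadata frame with
        ``sample_id``, ``subject_id``, ``group``, ``batch`` and the row
        index of each cell within its source sample.
        """
        blocks, metas = [], []
        for s in self.samples:
            idx = np.arange(s.n_cells)
            if max_cells_per_sample is not None and s.n_cells > max_cells_per_sample:
                if rng is None:
                    rng = np.random.default_rng(0)
                idx = np.sort(rng.choice(s.n_cells, size=max_cells_per_sample,
                                         replace=False))
            blocks.append(s.values[idx])
            meta = pd.DataFrame({
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "batch": s.batch,
                "cell_index": idx,
            })
            metas.append(meta)
        X = np.vstack(blocks)
        meta = pd.concat(metas, ignore_index=True)
        if len(self.subjects):
            meta = meta.merge(self.subjects[["subject_id", "group"]],
                              on="subject_id", how="left")
        return X, meta

    def transformed_all(self) -> bool:
        return all(s.transformed for s in self.samples)
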