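"""Gating of the CD27⁺CD86⁺CD20⁻ subset and the cGPS score.

The B-cell denominator is gated on CD19; within it the disease subset is
the intersection CD27 above its cut, CD86 above its cut, CD20 below its
cut.  Cuts are placed automatically from a healthy-donor reference: per
marker a two-component Gaussian mixture is fitted to pooled transformed
intensities and the cut sits at the density minimum between the component
means; when bimodality is not detectable the cut falls back to a reference
percentile.

cGPS maps the gated frequency (percent of B cells) to a 0–100 score.  The
default transform is the identity on the percent scale — the score then *is*
the CD27⁺CD86⁺CD20⁻ frequency — and any monotone non-decreasing transform
can be plugged in without touching gating or thresholding.  Risk
classification is a fixed threshold per clinical context: 1.15 for
monitoring non-GVHD patients, 1.51 for cGVHD patients, the boundary value
itself being low risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .containers import CellMatrix, Cohort

log = logging.getLogger(__name__)

#: default gate polarity of the disease subset
DEFAULT_SIDES = {"CD27": "+", "CD86": "+", "CD20": "-"}
DEFAULT_B_CELL_MARKER = "CD19"
#: decision thresholds on the cGPS scale per clinical context
DEFAULT_THRESHOLDS = {"nonGVHD": 1.15, "cGVHD": 1.51}

MIN_REFERENCE_CELLS = 100
FALLBACK_PERCENTILE = 99.5


@dataclass
class GateSpec:
    """Per-marker cut values and required sides, plus the B-cell gate.

    ``cuts``: marker -> (cut value on the transformed scale, side), side
    ``"+"`` meaning the cell must lie above the cut, ``"-"`` below.
    """

    cuts: dict[str, tuple[float, str]]
    b_cell_gate: tuple[str, str, float] = (DEFAULT_B_CELL_MARKER, "+", 1.0)
    fallback: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker, (cut, side) in self.cuts.items():
            if side not in ("+", "-"):
                raise ValueError(f"side for {marker!r} must be '+' or '-'")
            if not np.isfinite(cut):
                raise ValueError(f"non-finite cut for {marker!r}")
        if self.b_cell_gate[1] not in ("+", "-"):
            raise ValueError("b_cell_gate side must be '+' or '-'")
        if not np.isfinite(self.b_cell_gate[2]):
            raise ValueError("b_cell_gate cut must be finite")

    def to_dict(self) -> dict:
        return {
            "cuts": {m: {"cut": float(c), "side": s}
                     for m, (c, s) in self.cuts.items()},
            "b_cell_gate": {"marker": self.b_cell_gate[0],
                            "side": self.b_cell_gate[1],
                            "cut": float(self.b_cell_gate[2])},
            "fallback": dict(self.fallback),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GateSpec":
        return cls(
            cuts={m: (float(v["cut"]), v["side"])
                  for m, v in d["cuts"].items()},
            b_cell_gate=(d["b_cell_gate"]["marker"],
                         d["b_cell_gate"]["side"],
                         float(d["b_cell_gate"]["cut"])),
            fallback=dict(d.get("fallback", {})))


def _mixture_cut(x: np.ndarray, seed: int) -> tuple[float | None, bool]:
    """Cut at the density minimum of a 2-component mixture.

    Bimodality requires (a) component means at least one pooled standard
    deviation apart and (b) a genuine valley: the mixture density at the
    between-means minimum must fall below half the lower of the two peak
    densities.  Without (b) a unimodal marker gets split down the middle of
    its single mode and the "minimum" lands inside the bulk.  Returns
    ``(None, True)`` when no bimodality is found.
    """
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=2)
    gm.fit(x[:, None])
    mu = np.sort(gm.means_.ravel())
    pooled_sd = float(x.std(ddof=0))
    if (mu[1] - mu[0]) < pooled_sd:
        return None, True
    grid = np.linspace(mu[0], mu[1], 512)
    dens = np.exp(gm.score_samples(grid[:, None]))
    valley = float(dens.min())
    peaks = np.exp(gm.score_samples(mu[:, None]))
    if valley > 0.5 * float(peaks.min()):
        return None, True
    return float(grid[int(np.argmin(dens))]), False


def fit_gates(reference: Cohort, markers: Sequence[str],
              sides: Mapping[str, str] | None = None,
              b_cell_marker: str = DEFAULT_B_CELL_MARKER,
              reference_group: str = "HD",
              max_cells: int = 50_000, seed: int = 0) -> GateSpec:
    """Place per-marker cuts from healthy-donor reference intensities.

    Numerator markers fall back to the 99.5th reference percentile when no
    bimodality is found (positivity is rare in health, so the cut must sit
    above the healthy bulk).  The B-cell denominator marker is the opposite
    situation — B cells *are* the positive bulk of a B-cell matrix — so its
    fallback is the 0.5th percentile, keeping the bulk inside the gate.
    """
    sides = dict(sides or DEFAULT_SIDES)
    ref_ids = reference.subjects.loc[
        reference.subjects["group"] == reference_group, "subject_id"]
    if not len(ref_ids):
        raise ValueError(f"reference cohort has no {reference_group!r} samples")
    ref = reference.subset(ref_ids)
    if not ref.transformed_all():
        raise ValueError("reference samples must be transformed")
    rng = np.random.default_rng(seed)
    per_sample = max(1, max_cells // len(ref))
    X, _ = ref.pooled(max_cells_per_sample=per_sample, rng=rng)

    cuts: dict[str, tuple[float, str]] = {}
    fallback_flags: dict[str, bool] = {}
    for marker in list(markers) + [b_cell_marker]:
        j = ref.markers.index(marker) if marker in ref.markers else None
        if j is None:
            raise KeyError(f"marker {marker!r} not in reference panel")
        x = X[:, j]
        if len(x) < MIN_REFERENCE_CELLS:
            raise ValueError(
                f"only {len(x)} reference cells for {marker!r}; "
                f"need >= {MIN_REFERENCE_CELLS} for a stable fit")
        cut, fb = _mixture_cut(x, seed)
        if fb:
            pct = (100 - FALLBACK_PERCENTILE if marker == b_cell_marker
                   else FALLBACK_PERCENTILE)
            cut = float(np.percentile(x, pct))
            log.warning("marker %s: no bimodality detected; fallback to "
                        "%.1fth reference percentile (cut=%.3f)",
                        marker, pct, cut)
        fallback_flags[marker] = fb
        if marker == b_cell_marker:
            b_gate = (marker, "+", cut)
        else:
            cuts[marker] = (cut, sides.get(marker, "+"))
    return GateSpec(cuts=cuts, b_cell_gate=b_gate, fallback=fallback_flags)


def gated_frequency(sample: CellMatrix, gates: GateSpec) -> float:
    """Percent of B cells inside the full gate intersection."""
    if not sample.transformed:
        raise ValueError(f"sample {sample.sample_id} must be transformed "
                         "before gating")
    bm, bside, bcut = gates.b_cell_gate
    bvals = sample.marker_column(bm)
    denom_mask = bvals > bcut if bside == "+" else bvals < bcut
    denom = int(denom_mask.sum())
    if denom == 0:
        raise ValueError(f"no B cells in sample {sample.sample_id}")
    mask = denom_mask.copy()
    for marker, (cut, side) in gates.cuts.items():
        v = sample.marker_column(marker)
        mask &= (v > cut) if side == "+" else (v < cut)
    return float(100.0 * mask.sum() / denom)


def cgps_score(f: float, transform: Callable[[float], float] | None = None
               ) -> float:
    """Map a gated frequency (percent of B cells) to the 0–100 cGPS.

    ``transform`` must be monotone non-decreasing; the default is the
    identity on the percent scale.  The result is clamped to [0, 100].
    """
    if not (0 <= f <= 100):
        raise ValueError(f"frequency {f} outside [0, 100]")
    score = f if transform is None else float(transform(f))
    return float(min(100.0, max(0.0, score)))


def classify_risk(score: float, context: str,
                  thresholds: Mapping[str, float] | None = None) -> str:
    """``high`` iff the score strictly exceeds the context threshold; the
    threshold value itself is low risk."""
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
    if context not in thresholds:
        raise ValueError(f"unknown context {context!r}; "
                         f"expected one of {sorted(thresholds)}")
    if not (0 <= score <= 100):
        raise ValueError(f"score {score} outside [0, 100]")
    return "high" if score > thresholds[context] else "low"


@dataclass
class CGPSRecord:
    """Per-subject gated frequency, cGPS and risk class."""

    subject_id: str
    frequency: float
    score: float
    context: str | None
    threshold_used: float | None
    risk_class: str | None


def score_cohort(cohort: Cohort, gates: GateSpec,
                 transform: Callable[[float], float] | None = None,
                 thresholds: Mapping[str, float] | None = None
                 ) -> pd.DataFrame:
    """Gate and score every subject; healthy donors get no risk class."""
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
    rows = []
    for s in cohort.samples:
        group = cohort.group_of(s.subject_id)
        f = gated_frequency(s, gates)
        score = cgps_score(f, transform)
        context = group if group in thresholds else None
        rec = CGPSRecord(
            subject_id=s.subject_id, frequency=f, score=score,
            context=context,
            threshold_used=thresholds.get(context) if context else None,
            risk_class=(classify_risk(score, context, thresholds)
                        if context else None))
        rows.append(vars(rec))
    return pd.DataFrame(rows)
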