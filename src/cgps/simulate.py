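"""Synthetic cytometry cohort generator with a planted disease subset.

The generator emulates the structure of a multi-centre cGVHD B-cell study:
per-subject single-cell marker matrices drawn from a mixture of B-cell
subpopulation templates, with a planted plasmablast-like disease subset
(CD19⁺CD20⁻CD27⁺CD38ʰⁱCD86⁺IgD⁻) whose per-subject frequency depends on
clinical group, additive batch shifts between institutes, and outcome labels
coupled to the planted frequency.

Intensities live on the arcsinh-transformed axis as a two-component location
model: a "negative" mode near 0.5, a "positive" mode near 3.0 and a bright
"high" mode near 4.0, with shared Gaussian noise (σ = 0.45).  These values
produce clean per-marker bimodality so that gates are learnable; they are
simulator defaults, not claims about any instrument.

Besides the classical subsets (transitional, naive, IgM/marginal-zone-like
and switched memory, IgD⁻CD27⁻ double-negative B cells, plasmablasts) the
mixture includes three *near-miss* populations that each match the disease
subset on all but one of the eight candidate markers (a CD20⁺ activated
pre-plasmablast, a CD86⁻ resting plasmablast, a CD27⁻ atypical activated
cell).  Their per-subject abundance varies independently of disease status.
They make single markers and marker pairs genuinely ambiguous, so that —
as in the clinical problem — only the full CD20⁻CD27⁺CD86⁺ combination
isolates the disease subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CellMatrix, Cohort

# location of each polarity mode on the arcsinh axis
POLARITY_LOC = {"negative": 0.5, "positive": 3.0, "high": 4.0}
NOISE_SCALE = 0.45

#: simulation group keys -> clinical group label
GROUP_OF = {
    "HD": "HD",
    "nonGVHD_stable": "nonGVHD",
    "nonGVHD_active": "nonGVHD",
    "cGVHD_nonDP": "cGVHD",
    "cGVHD_DP": "cGVHD",
}

#: default per-group planted-frequency distributions, percent of B cells
DEFAULT_FREQ = {
    "HD": (0.3, 0.12),
    "nonGVHD_stable": (0.6, 0.15),
    "nonGVHD_active": (2.0, 0.40),
    "cGVHD_nonDP": (1.0, 0.25),
    "cGVHD_DP": (3.0, 0.50),
}

#: outcome decision boundaries on the planted-frequency axis (percent)
DEFAULT_BOUNDARIES = {"nonGVHD": 1.15, "cGVHD": 1.51}

#: every cGVHD subject keeps a CD19⁺CD20⁻ compartment above this percentage
CGVHD_FLOOR_PCT = 1.0

DISEASE_TEMPLATE = "activated_plasmablast"

#: the eight markers that discriminate the disease subset, and the optimal
#: minimal combination among them
CANDIDATE_MARKERS = ["CD20", "CD268", "CD5", "CD27", "CD38", "CD86",
                     "CD269", "CD319"]
OPTIMAL_COMBO = ("CD20", "CD27", "CD86")


def default_panel() -> list[str]:
    """The 20-marker B-cell phenotyping panel used throughout.

    The first eleven names are fixed by the study design (lineage, the eight
    disease-cluster candidates, IgD/IgM); the remainder are placeholder
    lineage/activation markers standing in for the untranscribed balance of
    the published panel.
    """
    return [
        "CD19", "CD20", "CD27", "CD38", "CD86", "CD5",
        "CD268", "CD269", "CD319", "IgD", "IgM",
        # placeholders:
        "CD21", "CD23", "CD24", "CD10", "CD22", "CD95", "CD71",
        "CD11c", "HLA-DR",
    ]


@dataclass
class SubpopTemplate:
    """One B-cell subpopulation: a polarity per panel marker and its
    baseline share of the non-disease B-cell compartment."""

    name: str
    marker_profile: dict[str, str]
    baseline_fraction: float

    def locations(self, panel: list[str]) -> np.ndarray:
        missing = [m for m in panel if m not in self.marker_profile]
        if missing:
            raise ValueError(
                f"template {self.name!r} lacks polarity for markers {missing}")
        return np.array([POLARITY_LOC[self.marker_profile[m]] for m in panel])


def _profile(panel: list[str], default: str = "negative",
             **overrides: str) -> dict[str, str]:
    prof = {m: default for m in panel}
    for marker, pol in overrides.items():
        key = marker.replace("_", "-") if marker == "HLA_DR" else marker
        if key not in prof:
            raise KeyError(f"unknown marker {key}")
        if pol not in POLARITY_LOC:
            raise ValueError(f"unknown polarity {pol}")
        prof[key] = pol
    return prof


def default_templates(panel: list[str] | None = None) -> list[SubpopTemplate]:
    """Nine templates: six classical subsets, three near-miss populations,
    and the planted disease subset (baseline fraction 0; its per-subject
    share is the planted frequency)."""
    panel = panel or default_panel()
    mk = lambda **kw: _profile(panel, **kw)  # noqa: E731
    t = [
        SubpopTemplate("transitional", mk(
            CD19="positive", CD20="high", CD24="high", CD38="high",
            CD5="positive", CD10="positive", CD22="positive", CD268="high",
            HLA_DR="positive", IgD="positive", IgM="positive"), 0.050),
        SubpopTemplate("naive", mk(
            CD19="positive", CD20="high", CD21="positive", CD23="positive",
            CD24="positive", CD22="positive", CD268="high",
            HLA_DR="positive", IgD="positive", IgM="positive"), 0.330),
        SubpopTemplate("igm_memory", mk(
            CD19="positive", CD20="high", CD21="positive", CD24="positive",
            CD27="positive", CD22="positive", CD95="positive", CD268="high",
            HLA_DR="positive", IgD="positive", IgM="high"), 0.100),
        SubpopTemplate("switched_memory", mk(
            CD19="positive", CD20="high", CD21="positive", CD24="positive",
            CD27="positive", CD22="positive", CD95="positive", CD268="high",
            HLA_DR="positive"), 0.245),
        SubpopTemplate("dn_memory", mk(
            CD19="positive", CD20="high", CD24="positive", CD22="positive",
            CD95="positive", CD11c="positive", CD268="high",
            HLA_DR="positive"), 0.160),
        # near-miss populations: disease phenotype with exactly one
        # candidate marker flipped (plus resolving non-candidate markers)
        SubpopTemplate("plasmablast", mk(  # resting: CD86-negative twin
            CD19="positive", CD27="high", CD38="high", CD5="high",
            CD269="high", CD319="high", HLA_DR="positive"), 0.045),
        SubpopTemplate("pre_plasmablast", mk(  # CD20-positive twin
            CD19="positive", CD20="high", CD27="high", CD38="high",
            CD5="high", CD86="high", CD269="high", CD319="high",
            CD21="positive", CD24="positive", CD95="positive",
            CD71="positive", HLA_DR="positive"), 0.035),
        SubpopTemplate("atypical_activated", mk(  # CD27-negative twin
            CD19="positive", CD38="high", CD5="high", CD86="high",
            CD269="high", CD319="high", CD11c="positive", CD22="positive",
            CD95="positive", CD71="positive", HLA_DR="positive"), 0.035),
        SubpopTemplate(DISEASE_TEMPLATE, mk(
            CD19="positive", CD27="high", CD38="high", CD5="high",
            CD86="high", CD269="high", CD319="high", CD95="positive",
            CD71="positive", HLA_DR="positive"), 0.0),
    ]
    validate_templates(t, panel)
    return t


def validate_templates(templates: list[SubpopTemplate],
                       panel: list[str]) -> None:
    total = sum(t.baseline_fraction for t in templates)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"baseline fractions sum to {total}, expected 1")
    for t in templates:
        t.locations(panel)  # raises on missing markers


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic cohort.

    ``disease_freq`` maps each simulation group to a (mean, sd) pair, in
    percent of B cells, for the Beta-distributed per-subject frequency of
    the planted subset.  ``sd = 0`` is the degenerate (point-mass) case.
    """

    n_subjects: dict[str, int] = field(default_factory=lambda: {
        "HD": 30, "nonGVHD_stable": 30, "nonGVHD_active": 30,
        "cGVHD_nonDP": 30, "cGVHD_DP": 30})
    cells_per_subject: int = 2000
    panel: list[str] = field(default_factory=default_panel)
    disease_freq: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FREQ))
    batch_effects: float = 0.2
    outcome_label_noise: float = 0.0
    seed: int = 0
    batches: list[str] = field(default_factory=lambda: ["institute1",
                                                        "institute2"])
    boundaries: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDARIES))
    subject_variability: float = 60.0  # Dirichlet concentration
    noise_scale: float = NOISE_SCALE
    templates: list[SubpopTemplate] | None = None
    raw_scale: bool = False  # emit raw fluorescence (sinh) instead
    cofactor: float = 150.0

    def __post_init__(self) -> None:
        for g in self.n_subjects:
            if g not in GROUP_OF:
                raise ValueError(f"unknown group {g!r}")
            if self.n_subjects[g] < 0:
                raise ValueError(f"negative subject count for group {g!r}")
        if not any(self.n_subjects.values()):
            raise ValueError("at least one group needs subjects")
        if self.cells_per_subject <= 0:
            raise ValueError("cells_per_subject must be positive")
        if not (0 <= self.outcome_label_noise < 0.5):
            raise ValueError("outcome_label_noise must be in [0, 0.5)")
        for g, (m, s) in self.disease_freq.items():
            if not (0 <= m <= 100) or s < 0:
                raise ValueError(f"invalid frequency distribution for {g!r}")


def require_group(config: SimConfig, group: str) -> None:
    """Explicit error when a downstream stage needs a group that is empty."""
    if config.n_subjects.get(group, 0) <= 0:
        raise ValueError(f"group {group!r} has zero subjects but is required")


def _draw_frequency(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw on the percent scale; degenerate when sd == 0 or mean == 0."""
    if sd == 0 or mean == 0 or mean == 100:
        return float(mean)
    mu, sigma = mean / 100.0, sd / 100.0
    nu = mu * (1 - mu) / sigma**2 - 1
    if nu <= 0:
        raise ValueError("frequency sd too large for a Beta distribution")
    return float(100.0 * rng.beta(mu * nu, (1 - mu) * nu))


def _outcome_from_frequency(sim_group: str, f: float,
                            boundaries: Mapping[str, float],
                            rng: np.random.Generator,
                            noise: float) -> str | None:
    """Outcome labels are a deterministic, monotone function of the planted
    frequency; with ``noise`` > 0 they flip across the boundary."""
    clinical = GROUP_OF[sim_group]
    if clinical == "HD":
        return None
    b = boundaries[clinical]
    if clinical == "nonGVHD":
        out = "active" if f > b else "stable"
        if noise > 0 and rng.random() < noise:
            out = "stable" if out == "active" else "active"
        return out
    # cGVHD: DP above the boundary; below it the response grade improves
    # monotonically as the planted frequency shrinks
    if f > b:
        out = "DP"
    elif f > 0.90 * b:
        out = "SD"
    elif f > 0.75 * b:
        out = "PR"
    else:
        out = "CR"
    if noise > 0 and rng.random() < noise:
        out = "SD" if out == "DP" else "DP"
    return out


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full synthetic cohort; bit-reproducible from ``config.seed``.

    Per subject: the planted-subset frequency is drawn from its group's
    Beta distribution (cGVHD subjects are floored at 1% of B cells, so the
    CD19⁺CD20⁻ compartment of every patient exceeds 1%), subpopulation cell
    counts are multinomial, intensities come from each template's location
    model with shared Gaussian noise, the subject's institute shift is
    added, and the outcome label follows the planted frequency.
    """
    rng = np.random.default_rng(int(config.seed))
    panel = list(config.panel)
    templates = config.templates or default_templates(panel)
    validate_templates(templates, panel)
    disease_idx = next((i for i, t in enumerate(templates)
                        if t.name == DISEASE_TEMPLATE), None)
    if disease_idx is None:
        raise ValueError(f"templates must include {DISEASE_TEMPLATE!r}")
    locs = np.stack([t.locations(panel) for t in templates])
    base = np.array([t.baseline_fraction for t in templates])
    base_other = np.delete(base, disease_idx)
    other_idx = [i for i in range(len(templates)) if i != disease_idx]

    batch_shift = {b: rng.normal(0.0, config.batch_effects, len(panel))
                   for b in config.batches}

    samples: list[CellMatrix] = []
    rows: list[dict] = []
    truth_cells: dict[str, np.ndarray] = {}
    for sim_group in ("HD", "nonGVHD_stable", "nonGVHD_active",
                      "cGVHD_nonDP", "cGVHD_DP"):
        n = config.n_subjects.get(sim_group, 0)
        mean, sd = config.disease_freq[sim_group]
        for i in range(n):
            sid = f"{sim_group}_{i:03d}"
            batch = config.batches[i % len(config.batches)]
            f = _draw_frequency(rng, mean, sd)
            if GROUP_OF[sim_group] == "cGVHD":
                f = max(f, CGVHD_FLOOR_PCT)
            outcome = _outcome_from_frequency(
                sim_group, f, config.boundaries, rng,
                config.outcome_label_noise)

            if config.subject_variability and config.subject_variability > 0:
                mix = rng.dirichlet(base_other * config.subject_variability)
            else:
                mix = base_other
            probs = np.empty(len(templates))
            probs[disease_idx] = f / 100.0
            probs[other_idx] = mix * (1 - f / 100.0)
            counts = rng.multinomial(config.cells_per_subject, probs)

            values = np.empty((config.cells_per_subject, len(panel)))
            labels = np.empty(config.cells_per_subject, dtype=object)
            start = 0
            for t_i, c in enumerate(counts):
                if c == 0:
                    continue
                stop = start + c
                values[start:stop] = locs[t_i] + rng.normal(
                    0.0, config.noise_scale, (c, len(panel)))
                labels[start:stop] = templates[t_i].name
                start = stop
            order = rng.permutation(config.cells_per_subject)
            values, labels = values[order], labels[order]
            values += batch_shift[batch]
            transformed = True
            if config.raw_scale:
                values = np.sinh(values) * config.cofactor
                transformed = False
            samples.append(CellMatrix(
                values=values, markers=panel, sample_id=sid, subject_id=sid,
                batch=batch, transformed=transformed))
            truth_cells[sid] = labels
            rows.append({
                "subject_id": sid, "group": GROUP_OF[sim_group],
                "sim_group": sim_group, "batch": batch, "outcome": outcome,
                "truth": f,
            })
    subjects = pd.DataFrame(rows)
    return Cohort(samples=samples, subjects=subjects, cell_truth=truth_cells)
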