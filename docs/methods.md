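# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the order the pipeline runs them, together with what the
synthetic cohorts do and do not emulate.

## Problem setting

After allogeneic stem-cell transplantation, chronic graft-versus-host
disease (cGVHD) is monitored clinically by organ scoring, which describes
the present state but does not forecast progression. B-cell homeostasis is
disturbed in cGVHD, and an activated plasmablast-like subset
(CD19⁺CD20⁻CD27⁺CD38ʰⁱCD86⁺IgD⁻) expands with disease activity. The package
reconstructs a monitoring workflow around that observation:

1. discover a disease-associated B-cell cluster in pooled single-cell
   cytometry data from a small exploratory cohort;
2. reduce its marker signature to a minimal panel by exhaustive
   combinatorial classification with an independent validation cohort;
3. gate the CD27⁺CD86⁺CD20⁻ fraction of CD19⁺ B cells and report it as the
   cGPS score (0–100);
4. derive ROC/Youden decision thresholds and apply them prospectively.

Patient-level data behind the published study are not deposited, so the
package ships a synthetic cohort generator that plants this structure with
known ground truth; all stochastic claims in the test suite are claims
about recovery of that planted structure.

## Synthetic cohorts (`cgps.simulate`)

Each subject is a mixture of nine B-cell subpopulation templates. Marker
intensities live on the arcsinh-transformed axis and are drawn from a
three-level location model — negative ≈ 0.5, positive ≈ 3.0, bright
("high") ≈ 4.0 — with shared Gaussian noise σ = 0.45 and an additive
per-institute batch shift drawn once per batch from N(0, 0.2). These are
simulator conventions chosen to produce clean per-marker bimodality (so
automatic gates are learnable), not instrument claims. Raw-scale output
(`raw_scale=True`) is `sinh(v)·cofactor` with cofactor 150.

Templates: transitional, naive, IgM/marginal-zone-like memory, switched
memory, IgD⁻CD27⁻ double-negative cells, and the planted disease subset,
plus three *near-miss* populations that match the disease phenotype on all
but one of the eight candidate markers:

| population | flipped marker | biological reading |
|---|---|---|
| resting plasmablast | CD86⁻ | non-activated plasmablast, present in health |
| pre-plasmablast / activated memory | CD20⁺ | activated B cell that has not lost CD20 |
| atypical activated | CD27⁻ | CD11c⁺ atypical/DN2-like activated cell |

The near-miss populations are the load-bearing part of the design: they
make every single marker and every marker *pair* genuinely ambiguous, so
that — as in the clinical data — the minimal unambiguous combination is the
triple CD20⁻CD27⁺CD86⁺. Each also differs from the disease subset on two
non-candidate markers, keeping the populations resolvable by graph
clustering on the full 20-marker panel. Their per-subject abundance varies
independently of disease (Dirichlet concentration 60 over the non-disease
baseline fractions), which is what degrades the subject-level AUC of
ambiguous marker combinations.

Per-subject planted frequencies (percent of B cells) are Beta-distributed
with group means fixed by the study design — HD 0.3, non-GVHD stable 0.6,
non-GVHD active 2.0, cGVHD non-DP 1.0, cGVHD DP 3.0 — and standard
deviations 0.12/0.15/0.40/0.25/0.50. cGVHD subjects are floored at 1% so
every patient keeps a CD19⁺CD20⁻ compartment above 1% of B cells. Outcome
labels are a deterministic, monotone function of the planted frequency
(boundaries 1.15 for non-GVHD stable/active, 1.51 for cGVHD DP/non-DP),
optionally flipped with probability `outcome_label_noise`. The boundaries
bracket the clinical thresholds so that threshold recovery is testable.
Everything is reproducible bit-for-bit from the config seed.

What the generator does **not** emulate: spillover/compensation, doublets
and debris, acquisition drift within a batch, non-B-cell compartments,
inter-marker correlation beyond population structure, and subjects with
insufficient circulating B cells. Passing tests therefore demonstrate that
the pipeline recovers a planted population structure under realistic
frequencies, batch shifts and sampling noise — not that it would match any
particular instrument's raw data.

## Preprocessing (`cgps.io`)

Raw intensities are arcsinh-transformed with a configurable cofactor
(default 150, the usual fluorescence convention; the acquisition-side
normalisation of real data is unknown, hence configurable). A `transformed`
flag makes double transformation a hard error. Before clustering, each
marker is regressed (OLS, pooled cells of the whole cohort) on the batch
indicator columns, replaced by its residuals, then centred and scaled to
unit variance; zero-variance markers become all-zeros with a warning rather
than NaNs. Gating and effect-size ranking use the *unscaled* arcsinh axis,
where cuts and median differences have interpretable units; clustering and
classification use the scaled axis.

## Cluster discovery (`cgps.cluster`)

Cells pooled across the discovery cohort are clustered by Louvain community
detection (igraph, pinned RNG) on the symmetrised k-nearest-neighbour graph
(Euclidean, k = 20, resolution 0.8 — both surfaced in config; the "right"
cluster count is data-dependent and never asserted). The disease-associated
cluster is the one with the largest cGVHD cell fraction, required to reach
`min_fraction` (default 0.75), ties broken by absolute disease cell count.
Markers are ranked by two-sided Wilcoxon rank-sum (tie-corrected normal
approximation at these cell counts) of in-cluster vs out-of-cluster
expression; the candidate set is markers with p < 1e-4 and |median
difference| > 1.0 arcsinh units, capped at the top 8 by effect size. The
selection rule is a reconstruction — published figures show eight markers
and significance stars but no explicit rule.

## Panel screening and validation (`cgps.panel`)

All candidate subsets of sizes 2–3 are enumerated (84 of 8 candidates) in
deterministic lexicographic order. Stage 1 trains a 100-tree random forest
per subset to recognise disease-cluster membership from those markers
alone, with a stratified 70/30 train/test split; accuracy > 0.90 freezes
the model (pickled; SHA-256 hash re-checked at validation, so re-training
after freezing is structurally impossible). Stage 2 scores every cell of
the independent validation cohort with the frozen model, aggregates to
subjects by mean predicted disease probability, and requires subject-level
AUC (cGVHD vs HD) > 0.90. Final selection: fewest markers, then highest
validation AUC, then lexicographic.

Two numerical choices matter and are deliberate:

- **All features at every split** (`max_features=None`): with 2–3 features,
  sqrt-feature subsampling gives trees that never split on the one marker
  separating a near-miss population, leaking probability onto it.
- **Rebalancing with hard-negative mining**: positives (disease-cluster
  cells) are capped at 300 and negatives at twice that; half the negatives
  are drawn uniformly from the nearest-to-positive-centroid pool (nearest
  10% of negatives, at least 3× the hard count) in the candidate subspace.
  Rare look-alike cells are otherwise so sparse in a downsampled training
  matrix that tree bootstraps regularly miss them entirely; the wide pool
  (rather than the strictly nearest band) keeps *every* look-alike
  population represented. A side effect mirroring the published screen is
  that ambiguous combinations now fail the stage-1 accuracy cutoff instead
  of passing vacuously.

Cell-level labels inherited from the subject's clinical group are available
as a fallback, but cannot reach high accuracy at realistic disease
frequencies (most patient cells are phenotypically normal); the cluster
label is the default and is what the screening accuracy refers to.

## Gating and cGPS (`cgps.gating`)

Cuts are fitted per marker on pooled healthy-donor reference intensities: a
2-component Gaussian mixture, cut at the density minimum between the
component means. Bimodality requires both mean separation ≥ 1 pooled SD
*and* a real valley (density minimum < 0.5× the lower peak); without the
valley condition a unimodal marker gets split down the middle of its bulk.
Fallbacks: numerator markers use the 99.5th reference percentile (positive
cells are rare in health); the CD19 denominator marker uses the 0.5th
percentile, because B cells are the positive bulk of a B-cell matrix and a
high-percentile cut would empty the denominator. Cuts are translation
equivariant.

The gated frequency is 100 × (CD27 > cut ∧ CD86 > cut ∧ CD20 < cut) /
(CD19 > cut). cGPS = clamp(transform(f), 0, 100) with the identity on the
percent scale as default transform; the published score formula is not
available in the transcribed text, but the score "ranges 0–100",
"summarises the frequency", and both thresholds sit in the plausible
percent range, so identity is the explicit stand-in and the transform is a
single pluggable monotone function. Risk is `high` iff score > threshold
(1.15 non-GVHD context, 1.51 cGVHD context, both overridable); the
boundary value itself is low risk, matching the clinical group definitions.

## Decision statistics (`cgps.stats`)

The ROC is empirical over all distinct score cuts (cuts at midpoints
between adjacent observed scores; a subject is positive strictly above the
cut). AUC is trapezoidal, identical to the tie-corrected Mann–Whitney
U/(n₁n₀) (asserted against an exhaustive pair-counting oracle). The Youden
operating point maximises sensitivity + specificity − 1; exact ties are
resolved uniformly at random under the caller's seed, mirroring the
"random best policy" convention of common ROC software. Confidence
intervals are percentile bootstrap (default 2000 resamples) over
class-stratified subject resampling; intervals are widened, if necessary,
to contain the point estimate (relevant only in degenerate small samples).

Fisher's exact test is two-sided by the conventional rule (total
probability of tables with point probability ≤ observed). The rank-sum test
enumerates all rank splits exactly for m+n ≤ 12 and otherwise uses the
tie-corrected, continuity-corrected normal approximation; the mode is
recorded. The power calculations use the one-sample/paired noncentral-t
formulation — power(n) = P(|T′| > t₁₋α/₂,ₙ₋₁), T′ noncentral t with
noncentrality d√n — chosen because it reproduces both published numbers
(required n ≈ 33.4 → 34 at d = 0.5, α = 0.05, power 0.8; power ≈ 0.293 at
n = 10) where a two-sample formulation does not.

## Study model and pipeline (`cgps.model`, `cgps.pipeline`)

`CGPSStudy(discovery, validation).fit(seed)` runs the whole discovery arm
and returns a results object with the clustering, marker ranking, combo
table, frozen selected model, fitted gates, per-subject cGPS records,
fitted Youden thresholds with CIs, and a text `summary()`. Gate polarities
for the selected markers come from the ranking's effect directions, so the
gate follows whatever panel was selected. Every random stage consumes a
seed derived from the single global seed through a fixed stage table
(`cgps._utils.stage_seed`), so stages can be rerun in isolation and a rerun
of the same config is byte-identical; the manifest stores parameters,
seeds and SHA-256 hashes of intermediates and contains no timestamps.

## Problem sizes used

Reference experiments (`cgps.experiments`) simulate cohorts of 30 subjects
per group × 2000 cells per subject; the discovery role is 5 healthy donors
plus 5 progressed patients (mirroring a small exploratory arm), everyone
else validates. Stage-2 scoring subsamples 1000 cells per subject — the
binomial noise this adds (≈0.3 pp at a 1% frequency) is small against the
between-group gaps. The test suite runs 20 seeded recovery experiments and
50 threshold-recovery seeds; `scripts/acceptance.py` repeats the recovery
experiment at 5 seeds and reports medians.

## Known limitations

- The identity cGPS transform is a placeholder for an unpublished formula;
  all thresholds are interpreted on the percent scale.
- Stage-1 accuracy filtering is only as selective as the screening matrix
  is hard; with well-separated synthetic populations most of its filtering
  power comes from the mined near-miss negatives.
- Spearman agreement between gated and planted frequency is limited by
  binomial counting noise, not by the gates: at 500 cells/subject the noise
  floor (~0.25–0.6 pp) rivals the within-group spread of the clinical 0–3%
  band, so rank agreement ≥ 0.95 is only observable across a wider
  frequency range (the invariant test spans ~0–20%).
- Subjects with too few B cells raise an explicit error; no imputation or
  rescue strategy is attempted.
- FCS support covers list-mode float/double 3.0/3.1 files only.
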