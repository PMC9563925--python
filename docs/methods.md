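# Methods

This note documents the models and procedures implemented in `rarescope`,
the defaults that matter, what the synthetic data does and does not emulate,
and the numerical choices a maintainer would want written down.

## 1. The measurement model

A slide is the entire nucleated cell fraction of a blood draw plated as a
monolayer and imaged in four fluorescence channels at fixed exposure, so
background intensity is comparable across slides. The first channel is
always DAPI (nuclear); the remaining three are marker channels whose roles
depend on the staining panel (Landscape: CK, Vim, CD45/CD31;
CDX2-targeted: CK, CDX2, CD45). Every quantity reported per mL rests on one
identity:

```
blood volume analyzed (mL) = DAPI nuclei on slide / leukocyte concentration (per mL)
events/mL                  = raw event count / blood volume analyzed
```

The leukocyte concentration is measured at processing; the nuclei count is
whatever the pipeline (or ground truth, in simulation) detects. Rare
nucleated events inflate the nuclei count by ~0.1–1%, which is far below
the counting noise and is ignored.

## 2. Synthetic slides

`rarescope.synthetic` renders frames with the statistical structure the
analysis assumes, not photorealistic optics.

* **Geometry.** 512×512 px frames at 0.5 µm/px. Default 64 frames per
  slide stand in for the instrument's 2304; at the default ~110 leukocytes
  per frame a simulated slide carries ~7×10³ nucleated cells rather than
  3×10⁶. All rates are per frame, so nothing downstream depends on the
  slide scale except the analyzed volume.
* **Populations.** Each `PopulationSpec` draws a Poisson count per frame,
  truncated-normal diameters and aspect ratios, a concentric nucleus of the
  configured area fraction, and per-channel expression with one of three
  textures: *diffuse* (flat fill), *filamentous* (3–8 anti-aliased line
  segments over a 0.35× pedestal), *punctate* (8–25 Gaussian spots of
  σ = 2–3.5 px over a 0.3× pedestal). Expression can be probabilistic
  (`on_prob`), e.g. the endothelial-like phenotype is CK-positive in 46% of
  instances.
* **Defaults.** The Landscape catalogue holds a leukocyte population
  (10 ± 1.2 µm, CD45/CD31 diffuse) and eleven rare phenotypes: Epi.CTC
  (large, CK filamentous), Mes.CTC (CK+Vim filamentous), DAPI-only,
  Vim-only, megakaryocyte-like (20–34 µm, CD45/CD31 punctate, elongated),
  endothelial-like (Vim filamentous + CD45/CD31 punctate, variable CK,
  cluster propensity 0.36), triple-positive cells, and four oncosome
  classes (3.5–10 µm circular DAPI-negative CK-positive vesicles, diffuse
  signal, attachment probability 0.49 so ~51% are isolated). Rare rates are
  0.05–1 per frame and scale jointly through `rare_scale`, the per-sample
  disease-burden dial (log-normal across a cohort, σ = 1). Intensities sit
  60–130 counts above a background of 20 with Gaussian noise σ = 3. These
  values were chosen once as realistic for enrichment-free scans and are
  not tuned per experiment.
* **Placement.** Rejection sampling with ≤30% mask overlap to mimic
  monolayer crowding; an unplaceable density raises `PlacementError` naming
  the population. Vesicle "attached" means the centroid lands at 0.85–1.15×
  the summed radii of a random nucleated cell.
* **Cohorts.** `generate_cohort` yields two draws per patient (a
  configurable number of patients missing Draw 2; default 2 of 10, giving
  18 samples per panel), one Landscape slide per normal donor with tumor
  phenotypes absent or down-weighted, and a survival table. PFS is
  log-normal (median ≈ 6 months) around a latent that mixes the Blom normal
  scores of the linked analyte's Draw-1 concentration with independent
  noise; `strength` = 1 gives Spearman correlation exactly ±1, 0 gives
  independence with uniform p-values.
* **Fast paths.** `sample_enumeration_counts` draws the exact count
  distribution of the renderer's ground truth (Poisson at rate × frames)
  without pixels — used for cohort-scale statistics.
  `draw_phenotype_features` samples the 8 shared features around 8
  archetype mean vectors (5–7% relative spread) — used for clustering
  studies.
* **Not emulated.** Point-spread functions, chromatic aberration, staining
  artifacts, autofluorescent debris beyond the explicit debris class, focus
  variation, and the real 761-parameter feature set. Tests passing on this
  generator demonstrate that the pipeline recovers structure *of the kind
  it assumes*; they do not certify performance on scanner images.

## 3. Segmentation

DAPI is thresholded at max(Otsu, background median + 3 robust SD);
components above 6 µm² are split by watershed on the distance transform
seeded at maxima ≥3 µm apart. Cytoplasm masks grow each nuclear label by at
most 5 µm, restricted to pixels above the marker-channel floor (background
median + 4 robust SD). Marker components that touch no nucleus are
DAPI-negative candidates (kept between 2 and 120 µm²) and are explicitly
excluded from cytoplasm growth — otherwise a vesicle attached to a cell is
absorbed into that cell's mask. Coordinates are 0-based row-major;
masks are stored locally to half-open bounding boxes. Background statistics
(median, 1.4826×MAD) are computed once per frame and channel; this is valid
while events cover well under half the frame.

## 4. Features, positivity, texture

All lengths are µm via the frame scale. DAPI intensity is measured inside
the nucleus, marker intensities inside the cell mask; both raw and
background-subtracted medians are stored. For DAPI-negative events the
nucleus features are zero with a `nucleus_missing` flag, and outline
distances use the cell centroid.

A channel is **positive** when its median intensity inside the mask exceeds
the frame background median by 5 robust SDs. **Texture** is decided on the
mask interior (eroded 3 px — the rim carries edge gradients regardless of
texture): interior contrast (sd of the smoothed signal / median signal
above background) below 0.20 ⇒ diffuse; otherwise a
magnitude-weighted resultant length of gradient orientations (folded mod π)
of at least 0.55 ⇒ filamentous (oriented ridges), else punctate
(isotropic spots). Both thresholds were fixed once against the renderer
(≥94% per-class accuracy) and are exposed in config. Local-maxima counts
(`count_spots`) are reported as a descriptor but do not enter the decision:
in practice spot counts of filamentous and punctate signals overlap, while
orientation concentration separates them cleanly.

## 5. Common/rare detection

Per frame (a per-slide mode exists for tiny slides), the DAPI-positive
events' shape features and all four channel medians are standardized
robustly — median center, 1.4826×MAD scale, winsorized at |z| = 10 — and
projected onto principal components retaining 95% of variance, with a
deterministic sign convention. Robust scaling matters: with mean/sd scaling
a burden of spiked cells inflates the scale of exactly the features that
make them detectable. Winsorizing matters for the opposite reason: an
extreme phenotype (CK at hundreds of robust SDs) would otherwise absorb the
whole variance budget and project milder phenotypes out of the retained
subspace.

Ward/Euclidean clustering is cut at 10 clusters. Any cluster holding more
than 20% of in-scope events is common. A smaller cluster is rare only if
its centroid lies ≥4 RMS spreads from the dominant cluster's centroid (the
common-cell prototype, frozen on the first pass); this displacement gate is
what keeps tail fragments of the homogeneous leukocyte cloud common. Peeled
events are removed and the remainder re-clustered (up to 8 rounds) so that
less extreme phenotypes — DAPI-only cells sit ~10 robust SDs out, CTCs
hundreds — are found in later rounds. The size rule alone, at any fixed
cluster count, either fragments the leukocyte cloud (precision 0.2–0.5) or
swallows the mild phenotypes; the gate plus iteration reaches per-class
recall ≥0.86 at 1–3% leukocyte false-rare rate on default slides.
DAPI-negative events bypass clustering entirely and are rare by definition.
Fewer than 5 in-scope events ⇒ all rare, flagged low-confidence. Events are
processed in event-id order, making the partition invariant to input order.

## 6. Classification

Channel-type labels concatenate the positive non-DAPI channels in fixed
panel order; no positive channel gives `DAPI only` (nucleated) or
`artifact` (non-nucleated). An **oncosome** is DAPI-negative, CK-positive,
circularity ≥0.85 and equivalent diameter ≤12 µm; DAPI-negative CK-positive
events failing the gate (elongated debris, oversized blobs) are routed to
`artifact` so the 12-class-per-panel partition stays exhaustive. A "clearly
defined nucleus" (required for the named CTC subtypes) is operationalized
as nucleus area ≥20 µm² with solidity ≥0.90. CDX2.CTC requires CK and CDX2
regardless of CD45 (the CD45-positive variant keeps its own channel-type
label). The megakaryocyte-candidate flag needs punctate CD45/CD31 (or
punctate third marker) and cell area ≥2× the frame's common-cell median;
the endothelial-candidate flag needs filamentous Vim plus punctate
CD45/CD31 with CK free to vary; `clustered` means another rare event's
centroid within 1.5 cell diameters. Nuclear lobularity is recorded only
through solidity/eccentricity; multilobularity is not itself detected.

## 7. Enumeration and cohort summaries

Per-sample tables carry raw counts, events/mL, a ≥5 events/mL positivity
flag and frequencies that sum to 100% of the sample's profile. Cohort
summaries report, per classification: positivity k/n, mean, standard error
(sd/√n over samples, n = samples not patients), percentage of total
(100 × classification mean / Σ classification means), median and range;
zero-count samples enter as 0 events/mL. The package embeds the published
18-sample reference enumeration tables for both panels
(`rarescope.enumeration.LANDSCAPE_REFERENCE` / `CDX2_REFERENCE`) as fixed
inputs for composition arithmetic; recomputing the percent-of-total column
from the printed means reproduces every printed percentage within ±0.01.
(The printed cohort-total mean differs from the sum of the printed
classification means by ~0.5%; the sum-of-means definition is the one that
reproduces the printed composition.)

## 8. Multi-assay analysis

Rare cells from both panels are pooled on the 8 shared features; vesicles
are excluded, as are cells with nonfinite features, nuclear-to-cell area
ratio outside (0, 1], or cell solidity <0.3 (the automated surrogate for
"aberrant masking"). Features are z-scored over the pooled set — unscaled,
area in µm² would dominate the Euclidean metric. Ward/Euclidean
agglomerative solutions are fitted for every k in 2…16, scored by mean
silhouette in the same z-scored space, and the argmax k returned with ties
broken toward smaller k. Cross-assay association uses Spearman's rho with
two-tailed p on matched samples (≥4 required), reported per class pair with
a p ≤ 0.05 significance mask; constant series yield missing values.

## 9. Clinical statistics

Cohort contrasts use the two-tailed Wilcoxon rank-sum test (exact null for
small tie-free samples, normal approximation otherwise). Analyte–PFS
screening uses Spearman's rho with the t-approximation p-value — the
convention of the scipy stack this mirrors; at n = 9 and rho = 0.70 it
gives p ≈ 0.036–0.037 — with an exact-permutation option for n ≤ 9.
Screening keeps analytes at raw p ≤ 0.05; no multiplicity correction by
default (a Benjamini–Hochberg option exists) because the workflow is a
hypothesis-generating screen. Kaplan–Meier stratification splits at the
cohort median: strictly above for concentration levels, ≥ for kinetics
deltas (both exposed); all provided PFS times are treated as observed
progressions unless an explicit censoring flag says otherwise. Kinetics is
Draw 2 − Draw 1 events/mL, computed only for patients with both draws and
reporting the exclusion count. `km_product_limit` is a closed-form
product-limit implementation kept deliberately separate from the
lifelines-backed curves as an internal cross-check.

## 10. Problem sizes and determinism

Default test and acceptance problem sizes — 6–16 frames per slide, 18 vs 50
count-level samples, 500 null simulations, 20 clustering seeds — were
chosen so the whole suite runs in a few minutes on one CPU while keeping
every Monte-Carlo margin (e.g. ±2 SE on a 5% rejection rate over 500
simulations) comfortably inside the asserted bands. Every stochastic
component takes an explicit seed; frame rendering derives its stream from
(sample seed, frame index), so any frame can be regenerated independently
and two runs of the same configuration are byte-identical.

## 11. Known limitations

* The renderer's phenotypes are well-separated by construction; real rare
  events grade into leukocyte morphology, and the displacement-gate
  threshold (4 RMS) would need recalibration on scanner data.
* Texture thresholds are frozen against the renderer's three texture
  operators, not against stain chemistry.
* The ~40-feature set is a stand-in for the production 761-parameter
  extraction; only the 8 shared features are treated as a stable contract.
* The multi-assay cluster count is recovered on synthetic archetypes; the
  published 8-cluster solution on the real 5661-cell pool is not
  reproducible without that data.
* Per-frame clustering needs tens of events per frame; slides sparser than
  ~20 events per frame should use the per-slide detection scope.
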