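# Methods

## Model

A subject's brain, already skull-stripped and affinely registered to a
common atlas space, is partitioned by an integer label atlas into named
regions (default schema: 113 regions — 48 cortical per hemisphere plus 17
subcortical structures). Each region is reduced to the empirical
distribution of its voxel gray levels, on the premise that MR intensity
tracks tissue composition, so a loss of dense (neuronal) tissue shows up as
a shift of probability mass along the intensity axis. All spatial detail
inside a region is deliberately discarded: the method is designed to be
robust to the small regional displacements an affine-only registration
leaves behind, because a slightly shifted region boundary barely changes
the intensity distribution even when it changes voxel-wise correspondence.

Distances between regions are Earth Mover's Distances between their
histograms. The healthy baseline is the medoid of the control group under
the subject-level distance δ, and every subject is featurized as its vector
of per-region EMDs to that medoid. The direction-free nature of this
representation is the point: patients who depart from the baseline in
different anatomical directions still all move *away* from it.

## Pipeline assumptions

- Volumes and atlas have identical grid dimensions; no resampling is done.
- Background (atlas label 0) is never sampled. Zero-intensity voxels
  *inside* labelled regions (skull-strip holes) are retained; the
  center-of-mass alignment removes constant background-level differences,
  which is the stated purpose of that alignment, so pre-filtering them
  would double-correct.
- Probabilistic atlases are collapsed to a maximum-probability label map at
  load time, ties to the lowest label id.
- A Dice overlap between each subject's nonzero-intensity mask and the
  atlas brain mask is reported as registration QC, warning below 0.90.

## Histograms

- `bins` (default 64): equal-width bins over a per-subject robust range,
  the [0.5, 99.5] percentiles of all labelled voxels, shared by all of that
  subject's regions so regional histograms stay mutually comparable.
  A fixed global range can be configured instead.
- Out-of-range values are clipped into the end bins; histograms are
  normalized to unit mass.
- Alignment shifts each histogram by the integer offset
  round(central_bin − center_of_mass); for even bin counts the central bin
  is index bins/2 (0-based). Integer shifting keeps the operation lossless
  for pure offsets that map bins to bins; mass pushed past either end is
  clipped and the histogram renormalized, with a warning when the clipped
  fraction exceeds 5%. Circular wrapping was rejected because it would
  teleport mass across the intensity axis, which has no physical meaning.
- Normalization is applied after shifting.

## EMD

Two implementations of the same quantity:

- `emd_closed_form` — Σₖ |CDF_S(k) − CDF_C(k)| / total mass, O(n). This is
  the production path.
- `emd_lp` — the transportation linear program with cost |i − j|, solved by
  HiGHS through `scipy.optimize.linprog`; returns the optimal plan for
  inspection. It exists as the independent oracle and for transport-plan
  introspection; the two agree to ~1e-14 on random pairs and the test suite
  additionally cross-checks against `scipy.stats.wasserstein_distance`.

Equal total mass is required within 1e-9 (histograms are normalized first).
Distances are in dimensionless bin units.

## Population metrics

- δ(a, b) aggregates per-region EMDs; the default is the unweighted sum
  (configurable to mean or max — with a complete region set all three give
  the same medoid, but they differ once regions are missing). Regions
  missing in either subject are excluded from δ and logged.
- The medoid minimizes the summed distance over the control group; exact
  ties resolve to the lexicographically smallest subject id so the result
  is deterministic.
- Feature entries for missing regions are NaN; stumps abstain on NaN at
  scoring time and abstentions cost half a sample's weight during fitting.
- The fitted reference (its full histogram set plus a hash of the histogram
  configuration) is serialized to JSON so a second cohort can be featurized
  against it; a configuration mismatch is a hard error, because distances
  computed under different binning are not comparable.

## Classification

- Weak learner: single-region threshold stump. Candidate thresholds are
  midpoints between consecutive distinct sorted feature values; ties in
  weighted error resolve to the lowest region index, then the lowest
  threshold, then positive polarity. A region with all-identical values
  yields a degenerate (constant) stump, flagged as such.
- RUSBoost (`rounds` default 100): each round undersamples the majority
  class to the minority size (without replacement, seeded), fits the stump
  on that balanced subset under the current weights, then computes the
  weighted error ε on the **full** cohort — full-sample evaluation keeps
  α = ½ ln((1−ε)/ε) meaningful for the whole population. ε is clamped to
  [1e-10, 0.5 − 1e-10]; training stops early only when ε ≥ 0.5. Weights
  update multiplicatively (AdaBoost rule) and renormalize. One consequence
  of the clamp worth knowing: a stump that separates the cohort perfectly
  receives α ≈ 11.5, an order of magnitude above an ordinary stump, so a
  perfectly separating region dominates the importance ranking whenever one
  exists.
- Importance: per ensemble, a region's raw relevance is the sum of α over
  the stumps that threshold it; shares are averaged across the
  leave-one-out models and scaled to percentages summing to 100. Redundant
  copies of an informative feature split this relevance rather than adding
  to it, matching the interpretation that a low-ranked region may be
  informative but redundant.
- Evaluation: leave-one-out cross-validation; the n out-of-fold scores are
  pooled into a single ROC (per-fold seeds derive deterministically from
  the master seed). AUC is the trapezoid rule — equal to the Mann–Whitney
  statistic with ties counted ½ — and the equal error rate is read off the
  ROC where FPR = FNR, linearly interpolating between adjacent vertices.
- CN is the negative class; the positive class defaults to AD and is
  configurable.

## Synthetic phantoms

The generator emulates exactly the ingredients the analysis consumes and
nothing more:

- Geometry: an ellipsoidal "brain" (45% of the grid per semi-axis) inside a
  background shell, tessellated into contiguous regions by seeded
  nearest-centroid assignment (centroids resampled, deterministically,
  until every region has ≥ `min_region_voxels`, default 50).
- Tissue: each region draws voxel intensities from a two-component Gaussian
  mixture — "dense" tissue at 700 and "rarefied" at 400 arbitrary units,
  common spread 60, baseline dense fraction 0.6. The patient effect reduces
  the dense fraction in the designated affected regions by `effect_size`
  (default 0.3), the mixture analogue of neuronal loss.
- Between-subject variability: every subject-region jitters its dense
  fraction by N(0, `biological_sd`) with `biological_sd` = 0.12, clipped to
  [0.02, 0.98]. This makes the control group a compact but non-degenerate
  cluster and a single affected region informative but imperfect (the 0.3
  shift is 2.5 standard deviations of the normal variability), which is
  what lets boosting spread relevance across redundant affected regions
  instead of crediting one of them in full. Without this term every
  affected region separates every subsample perfectly and the lowest-index
  tie-break hands one region 100% of the importance.
- Scanner gain: one global additive intensity offset per subject,
  N(0, 20) units — removed downstream by center-of-mass alignment.
- Cohort presets: `small` = 30 CN + 12 patients on a 32³ grid with 20
  regions (3 affected), sized so a full leave-one-out evaluation runs in
  seconds; `oasis-like` = 66 CN + 20 patients on 48³, mirroring a typical
  control/patient imbalance.

What the phantoms do **not** emulate: anatomy (no real brain geometry or
region shapes), registration error fields, bias fields, partial-volume
effects, multimodal tissue classes, or any spatial correlation of
intensities within a region. Passing the synthetic end-to-end checks
therefore demonstrates that the pipeline recovers planted
distribution-shift signal under class imbalance — not that it would reach
the same numbers on real MR data.

## Numerical choices

- Equal-mass precondition for EMD: 1e-9 after normalization; closed form vs
  LP agreement asserted at 1e-9.
- Histogram normalization asserted to 1e-12.
- Medoid ties, stump ties, and probabilistic-atlas ties all have declared
  deterministic tie-breaks (see above), so every pipeline output is
  reproducible bit-for-bit from (inputs, config, master seed); the test
  suite checks byte-identity of repeated runs.
- Problem sizes used by the test suite and the acceptance script — 16³–32³
  grids, 6–20 regions, cohorts of 12–42, 10 master seeds per condition —
  were chosen so the phantom studies are statistically meaningful at
  desk scale while the whole suite stays fast.

## Known limitations

- The subject-level δ weights every region equally; a large region and a
  tiny one contribute the same way. Sum/mean/max are provided, but no
  volume- or reliability-weighted aggregation.
- Pooled-LOOCV AUC at small n has wide seed-to-seed variance (null-cohort
  AUC sd ≈ 0.11 at 30 vs 12); single-cohort AUCs should be read with that
  in mind.
- With the ε clamp at 1e-10, perfect separators dominate importance (see
  above); on real, noisy cohorts this regime is unlikely, but on clean
  synthetic data it compresses the ranking.
- No multi-class classification; the two binary tasks (controls vs each
  patient group) are run separately.
- Registration, bias-field correction, and skull stripping are upstream
  responsibilities; the package only QCs overlap after the fact.
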