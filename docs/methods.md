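# Methods

This note records the models the package implements, the assumptions and
defaults behind them, and the choices made where the design was open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Enhancement kinetics

The three-phase DCE model is purely semi-quantitative: percent
enhancement `PE = (S1 − S0)/S0 × 100` and signal enhancement ratio
`SER = (S1 − S0)/(S2 − S0)`, computed voxelwise over the whole volume
(tumor VOI and contralateral breast share one map computation).

Degenerate denominators are handled so both maps are total functions:

- voxels with `S0 ≤ noise_floor` are marked invalid (air/background);
  the default floor is `1e-6 × max(S0)`;
- where `|S2 − S0| ≤ noise_floor` but the early phase enhanced, SER is
  set to `ser_cap` (default 10) — the washout/plateau limit.  Only the
  *sign* of SER enters the FTV threshold, so the cap value can never
  change FTV membership;
- where both differences vanish, SER = 0.

## Functional tumor volume

FTV is pure thresholding inside the VOI: valid voxels with
`PE ≥ pe_min` (default 70%) and `SER ≥ ser_min` (default 0), inclusive
comparisons, voxel volumes summed in cm³.  No connectivity filtering or
hole-filling is applied — the mask is exactly the threshold set, and an
empty mask (FTV = 0) is a legal result.  Per-patient threshold
adjustments are supported via config overrides and are held fixed
across a patient's timepoints.

## Sphericity

`SPH = SA_sphere/SA_tumor` with `SA_sphere = (36π)^(1/3) V^(2/3)`.
The tumor surface is a marching-cubes isosurface at level 0.5 with voxel
spacing applied.  Meshing the *raw binary* mask carries a staircase
artifact that inflates the surface area of a digitized sphere by ~9%
(a radius-20-voxel sphere would score ~0.92 instead of 1.0), biasing
every sphericity downward.  The mask is therefore mildly anti-aliased
with a Gaussian kernel, sigma 0.7 voxels, before meshing: a
radius-20-voxel sphere then scores ≈ 0.99, and flat faces stay
effectively flat (an 80-voxel cube scores within 2% of the analytic
`(π/6)^(1/3) ≈ 0.806`; the corner-rounding bias of the smoothing decays
like 1/L with cube side L).  The kernel lives in voxel units, so
uniform spacing rescaling leaves SPH exactly invariant.

Known behavior at small volumes: masks of only tens of voxels mesh into
compact blobs whose surface is *under*-estimated, so SPH can exceed 1
slightly.  Sphericity is unreliable at minimal residual volume — it is
reported as undefined (not an error) below `min_voxels` (default 10,
configurable), and such exams are excluded downstream.  Disconnected
masks are meshed as-is with their component surface areas summed, which
is why SPH does not distinguish multi-centric disease; the package
reproduces rather than repairs this.

## Background parenchymal enhancement

BPE is the mean PE of contralateral fibroglandular tissue (FGT), fully
automated in three stages.

**Breast segmentation** is a functional stand-in for published
segmentation methods, not a replication of any: multi-Otsu foreground
threshold on S0 (lowest of two cuts, so partially suppressed parenchyma
stays in), morphological closing, largest connected component on the
requested lateral half, then a posterior cutoff keeping the anterior
`chest_wall_fraction` (default 0.85) of the component's anteroposterior
extent.  An empty result sets a `segmentation_failure` flag instead of
raising.  Two further quality flags — insufficient fat suppression
(bright/dark intensity modes inside the breast nearly indistinguishable)
and coil inhomogeneity (breast rind much brighter than core) — are
deliberately simple heuristics that mark exams for exclusion, mirroring
the categories a reading-room QC step produces.

**FGT classification** is standard fuzzy c-means (Bezdek) on the 1-D
pre-contrast intensities inside the breast mask: memberships
`u ∝ d^(−2/(m−1))` normalized per sample, centroids as `u^m`-weighted
means, iterated to a centroid-shift tolerance; deterministic given a
seed.  Defaults: c = 2 clusters, fuzziness m = 2, membership cut 0.5,
FGT = the lower-intensity cluster (fat-suppressed convention; a
polarity flag flips this for non-suppressed protocols).

**Averaging**: BPE is the mean PE of valid FGT voxels over the
`n_slices` (default 5) contiguous axial slices centered at the
geometric midpoint of the breast mask's superior–inferior extent, ties
broken toward the inferior slice; a breast spanning fewer slices uses
all of them.  No FGT in the stack ⇒ BPE undefined (a value, not an
error), mirroring how unreliable segmentations are excluded.

## Cohort assembly

Model variables are each feature's baseline plus percent change from
baseline at T1/T2/T3, `100 × (x_t − x_0)/x_0`; a zero or missing
baseline makes the trend variable missing.  Analysis is restricted to
patients with all 16 variables available; everyone else is excluded
with a single first-applicable reason in the precedence order
*missing outcome > missing exam > SPH undefined > BPE undefined > other
missing feature* (the precedence is a package choice; the categories
are fixed).  Included count plus per-reason exclusions always equals
the input count.

Cohort-characteristic comparisons use the Wilcoxon rank-sum test for
continuous variables and Fisher's exact test for categorical ones —
exact (hypergeometric) for 2×2, a seeded Monte-Carlo simulated p-value
for larger tables, where exhaustive enumeration is impractical.

Units are fixed here (FTV cm³, LD cm, BPE %, SPH unitless); only
percent changes enter the models for trend variables, so unit choices
do not affect the modeling.

## Modeling

Logistic regressions are ordinary maximum-likelihood fits.
Non-convergence, (quasi-)complete separation (likelihood at its
supremum or all fitted probabilities at a boundary) and rank-deficient
designs are flagged on the result, never silently accepted;
rank-deficient designs are fitted with a gradient method, which still
attains the maximum likelihood.

Cross-validated AUC uses outcome-stratified k-fold assignment (5 folds,
100 repeats by default).  Per repeat the AUC is computed on the pooled
out-of-fold predicted probabilities, then averaged over repeats —
pooling per repeat is stable for small strata, where per-fold AUCs are
noisy.  Model optimization searches candidate subsets for the highest
CV-AUC: exhaustively for ≤ 8 candidates (a single feature's 4 variables
→ 15 subsets), greedy forward selection with a no-improvement stop for
the combined 16-variable search (an exhaustive flag exists; 2^16
subsets × repeated CV is disproportionate as a default).  All subsets
within one optimization are scored on the *same* per-repeat folds, so
selection cannot leak test folds; ties break toward fewer variables,
then lexicographically.  For full-cohort models, subtype enters every
candidate model as a forced reference-coded categorical covariate.

The 95% CI of a cross-validated AUC is a percentile bootstrap (1,000
resamples) over patients: each patient carries their out-of-fold score
averaged across repeats and their label, and (score, label) pairs are
resampled with replacement.  The CI is reported unavailable when either
outcome class has fewer than 5 patients — a formalization of "too few
outcomes for a reliable interval" (no published cutoff exists; 5 per
class is this package's rule).  AUC differences between two models on
the same patients use a paired bootstrap (2,000 resamples) of the AUC
difference with a two-sided tail p-value.  Per-variable p-values are
likelihood-ratio chi-squared tests (df 1) of the selected model with
and without the variable.  Significance is nominal at p < 0.05, no
multiplicity correction.  One master seed fans out deterministically to
every (stratum, model) combination, so full runs are byte-reproducible.

## The phantom

The image phantom is the simplest model in which every feature has
analytic truth: piecewise-constant tissue classes with
`S1 = S0(1 + PE/100)`, `S2 = S0 + (S1 − S0)/SER` and optional additive
Gaussian noise (clipped at zero to keep intensities physical), truth
recorded pre-noise.

Geometry, axes `(superior→inferior, anterior→posterior, right→left)`:
two half-ellipsoid breast envelopes whose flat faces sit on a
chest-wall plane, a fat-intensity chest slab behind that plane, a
connected central FGT blob per breast (volume fraction `fgt_fraction`,
optional scattered islands for patchy parenchyma), and a tumor
(sphere, ellipsoid, or rim-enhancing shell) in the designated breast.
The chest slab is sized so the segmenter's default posterior cutoff
(85% of the anteroposterior foreground extent) lands at the anatomical
chest-wall plane — without posterior tissue the cutoff would truncate
the breast itself, which is not what it models.  Class intensities put
FGT darker than fat on S0 (fat-suppressed convention, matching the
clustering default).  LD truth is the maximum caliper diameter of the
tumor mask — a geometric surrogate for a radiologist measurement,
which keeps the LD variable exercised without claiming reader realism.

Default kinetics: tumor PE 130%/SER 1.2 (strong washout), FGT PE
30%/SER 0.8, fat PE 5% — values in the ranges a breast DCE protocol
produces for malignant tissue, parenchyma and suppressed fat.

## The cohort generator

The synthetic cohort emulates the composition of the reference analysis
population: subtype proportions (162, 60, 30, 132)/384 for HR+/HER2−,
HR+/HER2+, HR−/HER2+, HR−/HER2−, and subtype pCR probabilities 24/162,
19/60, 20/30, 51/132 (overall expectation 29.7%).  Feature
distributions are *not* published anywhere; the generative defaults are
package choices: log-normal baselines (FTV median 10 cm³, LD 3.5 cm,
BPE 25%; SPH clipped normal 0.70 ± 0.08), and pCR-conditional mean
percent changes at T1–T3 that are more negative for responders
(monotone shrinkage), e.g. FTV (−45, −75, −88)% for pCR versus
(−30, −55, −70)% for non-pCR.  Percent-change noise combines a shared
per-patient response latent with feature-specific noise
(`response_correlation` 0.6), so the four features are correlated the
way serial response measurements are; the mean shifts were chosen to
give single-feature CV-AUCs in a clinically plausible 0.7–0.9 band
rather than perfect separation.

A second outcome mechanism supports controlled experiments: when
`feature_effects` (per-variable log-odds coefficients) is supplied,
trajectories are drawn unconditionally and pCR comes from a logistic
model on the standardized named variables — signals land exactly where
planted, which is what the variable-selection and combined-vs-single
tests rely on.

**What the phantom and generator do not emulate** — and hence what
passing tests do not show about trial data: MR physics (coil profiles,
fat-suppression failure, motion), reader variability in LD and VOI
placement, drug-arm effects, non-monotone or heteroscedastic response
trajectories, and the true joint distribution of the four features.
Clinical AUC values are not reproducible from synthetic data and are
not targets of this package.

## Problem sizes

Defaults mirror the reference analysis (100×5 CV, 1,000/2,000 bootstrap
resamples, n = 384).  The test suite and examples run reduced
configurations — 2–20 CV repeats, 100–1,000 bootstrap resamples,
cohorts of 40–2,000, phantom grids of 56×64×64 voxels at 1.5 mm — sizes
chosen so the full suite exercises every code path at desk scale while
Monte-Carlo tolerances (e.g. permuted-outcome CV-AUC 0.50 ± 0.03,
bootstrap CI coverage 95 ± 3 points over 300 replicates) remain
meaningful.

## Known limitations

- The breast segmenter is a deliberately simple stand-in; on real exams
  its Dice against expert masks would be far below the phantom's.
- Fuzzy c-means on 1-D intensities cannot separate tissues with
  overlapping intensity distributions; the QC flags are coarse.
- SPH inflation at small residual volumes (above) means late-timepoint
  SPH values near or above 1 should be read as "minimal residual", not
  "perfectly spherical".
- Forward selection is greedy; with strongly collinear candidates it
  can settle on a near-optimal rather than optimal subset.
- The percentile bootstrap mildly undercovers at small n; the CI
  unavailability rule (< 5 per class) is a guard, not a fix.
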