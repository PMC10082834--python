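# Methods

## Scope and data model

The pipeline quantifies therapy response from reconstructed 3-D PET
volumes; reconstruction itself (MLEM, scatter/attenuation correction)
is upstream and out of scope. All arrays are ordered `(z, y, x)` with
0-based indices; physical quantities are in millimetres, Bq and grams;
coordinates refer to voxel centers. NIfTI-1 is the canonical on-disk
format (float64 scalars, uint8 masks — both round-trip exactly); a
DICOM-series importer applies rescale slope/intercept and sorts slices
by patient position.

## SUV conversion

`SUV = c / A × w` with activity concentration `c` (Bq/mL), injected
activity `A` (Bq) and body weight `w` (g) — the body-weight convention,
dimensionless on the g/mL scale. Decay correction is **off** by
default: the plain formula carries no decay term, and uptake-period
handling varies between sites. When enabled, the injected activity is
decayed from injection to scan time with the ¹⁸F half-life
(109.77 min, configurable for other nuclides), which requires both
timestamps. SUV is linear in activity; that linearity is what makes
percent-change endpoints insensitive to the PSF (a scan pair with
identical geometry and a pure uptake change measures the prescribed
change exactly on noise-free data).

## MTV segmentation

The operator provides a coarse bounding box; everything else is
deterministic:

1. **Seed slice** — the axial slice containing the box's maximum SUV;
   ties break toward the lowest `(z, y, x)` index.
2. **2-D region growing** — 4-connected growth from the slice maximum,
   admitting voxels at or above `rg_fraction` (default 0.40, standard
   PET practice) of the slice maximum. This gives a rough,
   user-independent in-slice contour.
3. **3-D active surface** — the contour is extruded ±`extrude_slices`
   (default 2) slices to give the surface cross-slice support, then
   evolved with a two-phase, edge-free (Chan–Vese-type) morphological
   update: voxels adjacent to the current boundary are reassigned by
   comparing `(I − c₁)²` against `(I − c₂)²`, where `c₁` is the mean
   SUV inside the current mask and `c₂` the mean over the rest of the
   image. Convergence is an unchanged mask over
   `ac_converged_window` = 3 consecutive iterations, with a hard cap of
   `ac_max_iter` = 500. The final mask is the single 26-connected
   component containing the seed voxel.

Design choices worth stating:

* **Background statistic from the whole image, not the box.** Using the
  box would couple the converged surface to how generously the operator
  drew it; the global out-of-mask mean makes the fixed point identical
  for any box that contains the lesion with a small margin. This is the
  operator-independence property, and it is tested bitwise.
* **`ac_smoothing` defaults to 0.** The optional smoothing step is a
  3×3×3 binary median filter (a morphological curvature flow). On
  noiseless uniform objects any curvature step rounds discretization
  corners and breaks the exact equivalence between the converged
  surface and the intensity level set, which is a property we maintain
  and test; on high-contrast, PSF-smoothed PET data the two-phase
  region statistics are regularization enough. The parameter exists for
  noisy scans.
* **Connectivity conventions:** 4-connected in-slice growth,
  26-connected 3-D component selection. Fixed, stated once, tested.
* The update is a deterministic function of the current mask, so a mask
  unchanged for one iteration is a true fixed point; the 3-iteration
  window is kept as a cheap guard. The iteration cap also bounds the
  (rare) possibility of a period-2 oscillation of boundary voxels.

Volumetric accuracy: on unblurred uniform lesions the converged surface
equals thresholding at mid-contrast, i.e. the exact object. Under PSF
blur the surface lands on a level set of the blurred profile, which for
lesions near the resolution limit systematically overshoots the true
boundary (the blurred halo is included); sub-resolution *volumes* are
not recoverable by any thresholding-genre method. That bias is the
partial-volume effect; the pipeline corrects its impact on SUV (below),
not on volume.

## Lesion QC

Two gates decide eligibility for the recovery-coefficient correction,
mirroring the geometry the calibration is valid for:

* **Sphericity** — principal diameters are peak-to-peak extents of the
  voxel-coordinate cloud along its covariance eigenvectors, padded by
  the voxel footprint along each axis (a single voxel therefore reports
  one voxel edge). The gate is `100·(d_max − d_min)/d_max < 50` with
  the boundary value failing (strict reading). Principal-axis extents
  were chosen over maximum pairwise surface distance because they are
  rotation-tolerant, cheap, and testable against analytic ellipsoids.
* **Uptake uniformity** — the in-mask SUV histogram (16 equal-width
  bins over the in-mask range) is smoothed with a Gaussian of 1.5 bins
  and peaks with prominence ≥ 0.20 of the tallest smoothed bin are
  counted; uniform ⇔ exactly one peak, and a constant-valued lesion
  counts as one. The smoothing and floor operationalize a qualitative
  visual judgment: the raw bin comb of a noise-free voxelized lesion is
  ragged (shells of equal-value voxels produce spurious spikes), and
  the envelope — what a reader actually judges — is the smoothed
  histogram. The defaults were chosen so that uniform lesions, crisp or
  PSF-blurred, across the 2–8 mm range count one peak while two-level
  (core/shell or half-and-half) constructions count two; both
  parameters are exposed.

The uniformity verdict is invariant under affine rescaling of SUVs
(bins are relative to the in-mask range), and sphericity is invariant
under rigid rotation and isotropic scaling up to discretization, both
property-tested.

## Partial-volume correction and metrics

`MTV` is exact arithmetic: voxel count × voxel volume. The
sphere-equivalent diameter `d = (6·MTV/π)^{1/3}` indexes a recovery
coefficient table (default: 0.04, 0.19, 0.41, 0.54, 0.70 at 1–5 mm) —
a scanner calibration treated as fixed constants, replaceable via
config for other scanners. Lookup is exact at tabulated diameters,
linearly interpolated between them, 1.0 above 5 mm where the effect is
considered irrelevant (this is a deliberate step discontinuity at
5 mm: the no-correction rule, not the interpolant, governs there), and
clamped to RC(1 mm) with a warning below the table rather than
extrapolating toward implausible values. Corrected SUV = SUV / RC;
correction is skipped (RC = 1, warning recorded) when QC fails.
`TLG = SUVmean × MTV`, by default using the corrected mean when a
correction was applied (the flag `use_corrected_for_tlg` exposes the
choice). MTV and TLG are exact products, reproducible bitwise.

With the default phantom PSF (σ = 0.8 mm) the measured in-truth-mask
recovery of uniform spheres is ≈ 0.09/0.24/0.45/0.56/0.64 at
d = 1…5 mm — the same regime as the default table, which is why
dividing by the tabulated RC moves the measured SUVmean toward truth
for every blurred lesion whose measured `d_equiv` is within the
correction range (a directional property; exact recovery is not claimed
since the table is a scanner calibration, not a property of the
synthetic PSF).

## Response assessment

`ΔX = 100·(X_post − X_pre)/X_pre` for SUVmean, MTV, TLG (baseline must
be positive). Classification uses ΔSUV only: > +25 % progressive,
< −15 % partial response, otherwise stable. The printed thresholds are
strict on all branches, leaving the exact boundary values unassigned;
they are assigned to *stable* (closed-interval convention) and that
choice is tested. ΔSUV is computed on corrected SUVmeans only when both
scans carry a real correction, so a QC failure on one scan cannot
masquerade as a metabolic change.

Cohort comparisons follow the conventional pretest tree: Shapiro–Wilk
per group, then Levene (the homogeneity test is not pinned by
convention; a Levene-type test at α = 0.05 was chosen and isolated
behind one function), then t-test / one-way ANOVA + Holm–Šidák or
Kruskal–Wallis. Groups with < 3 observations (or constant values) make
normality untestable and drop to the nonparametric branch with a
warning. The bespoke content is the branch logic; the test statistics
themselves come from scipy/statsmodels. Under a simulated null the
tree's overall type-I error stays near the nominal 0.05 (the pretests
perturb it only slightly), verified by simulation.

## Histopathology scoring

Counts (mitotic, apoptotic, Ki-67⁺) are summarized per 10 HPF: sum of
the first 10 fields, mean×10 when more fields are provided and
averaging is requested, and scaled extrapolation with an explicit flag
and warning below 10 fields. Staining is scored as IS (0–3) × ES (0–4)
= IRS (0–12). The printed ES categories are integer anchors with
real-valued gaps (e.g. 30–31 %); cut points at 5, 30.5, 50.5 and
75.5 % make the bins a partition of [0, 100] while every printed anchor
stays in its printed bin. Scoring operates on counted tables — the
counting itself is manual microscopy, not image analysis.

## Synthetic phantoms

`make_phantom` voxelizes uniform spheres/ellipsoids (voxel-center
inclusion) on a low uniform background, records truth (crisp masks,
exact voxelized volumes, true SUVs) *before* degradation, then blurs
with an isotropic Gaussian PSF (reflect-padded convolution; total
activity conserved to < 0.1 %) and optionally adds Gaussian or scaled-
Poisson noise from a seeded generator (identical spec + seed ⇒
bit-identical volume). Defaults: 128³ grid at 0.5 mm isotropic spacing
(test fixtures use 64³ to stay desk-scale), background SUV 0.1,
PSF σ 0.8 mm — chosen to put 1–5 mm lesions squarely in the
partial-volume regime the RC table addresses. Noise defaults off;
every stochastic test carries an explicit seed.

`make_response_pair` scales the follow-up lesion's true SUV by
`1 + ΔSUV/100` and its radius by `(1 + ΔMTV/100)^{1/3}`, recording both
prescribed and realized (voxelized) changes. `make_qc_negative` builds
lesions that fail exactly one gate: a 2.5:1 ellipsoid (sphericity) or a
hot core (0.72 r, 3.5× uptake) inside a cooler shell (uniformity); the
bimodal construction needs the shell to stay resolvable against the
PSF — with σ = 0.8 mm that means lesion radii of ~4 mm unblurred or
≥ 5 mm through the segmented mask.

What the phantoms do **not** emulate: reconstruction artifacts and
spatially correlated noise, anatomical background structure, respiratory
motion, spill-in from adjacent hot organs, and non-uniform tracer
uptake within real tumors. Passing tests therefore demonstrate the
correctness and determinism of the algorithms under their stated
assumptions, not scanner-grade accuracy on animal data.

## Problem sizes used in validation

The recovery batch uses 20 unblurred, noiseless spheres with equivalent
diameters 2–10 mm on 64³ grids ("noise-free" meaning no degradation at
all: on blurred data near-resolution volumes are not recoverable, see
above); the PVE-direction check uses blurred spheres at d = 2–5 mm; the
statistics null uses 1000 replicates of two n = 8 normal groups. These
sizes make the full suite and the acceptance script run in well under a
minute each while keeping every check non-trivial.

## Known limitations

* The active-surface energy is a faithful-genre reconstruction (region
  -based two-phase with morphological updates); the original
  formulation behind the workflow is not published in enough detail to
  reproduce term by term.
* RC correction assumes sphere-like, uniform lesions — hence the QC
  gates; irregular or necrotic lesions pass through uncorrected with a
  warning.
* Segmented volumes of lesions at or below ~2× PSF FWHM are
  systematically inflated; treat MTV of sub-resolution lesions as
  semi-quantitative.
* The DICOM importer handles plain single-frame series with rescale
  tags; vendor-specific SUV private tags are not parsed.
* EORTC-style classification here uses SUVmean-based ΔSUV; PERCIST-type
  SUVpeak analysis is out of scope.
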