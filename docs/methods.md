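# Methods

`synthct` implements an MRI-driven synthetic-CT (sCT) workflow for adaptive
proton therapy, together with the digital-phantom validation stack used to
qualify it. This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic validation does and
does not demonstrate.

## The sCT model

Interfractional anatomical change is captured by a deformable image
registration (DIR) between the reference MRI (acquired at planning time) and
a verification MRI (acquired during the treatment course). The resulting
displacement vector field (DVF) is transferred to the planning CT and used to
warp it, producing a CT-valued volume that shows the verification anatomy —
the synthetic CT. Proton dose can then be recomputed on the sCT and compared
with the plan, driving a replanning decision, without exposing the patient to
a repeat X-ray CT.

Conventions. All geometry is world LPS millimetres; voxel indices are
0-based with the origin at the center of voxel (0,0,0); world position of
index `i` is `origin + orientation @ (i * spacing)`. Displacement fields use
the *pull-back* convention: a field `d` on grid G warps a volume `v` as
`out(x) = v(x + d(x))` for `x` on G. This makes sCT synthesis a single
interpolation pass on the planning-CT grid. Metric math (TRE, gamma, search
radii) is done in millimetres, never voxels, because the CT, MRI and dose
grids have heterogeneous spacings.

Pipeline (`make_synthetic_ct`):

1. **Rigid link CT↔MRI.** A rigid transform mapping planning-CT world points
   into the reference-MRI frame, estimated by mutual-information rigid
   registration (SimpleITK, regular deterministic sampling). Same-modality
   pairs use mean squares.
2. **Deformable MRI↔MRI.** Registration direction is fixed =
   verification MRI, moving = reference MRI, so the pull-back field lives in
   the verification frame and directly synthesizes verification anatomy.
3. **Frame adaptation.** With a rigid link `T(y) = R y + t` mapping
   destination-frame points into the field's frame, the conjugated field is
   `d'(y) = R⁻¹ d(R y + t)`. This is implemented exactly (the field's grid is
   mapped into the destination frame; every vector is rotated by `R⁻¹`), and
   only the subsequent resampling onto the planning-CT grid interpolates
   (componentwise trilinear). Deformable links are applied as resampling
   only, never conjugated.
4. **Warp.** `sCT(y) = refCT(y + d'(y))`, trilinear, fill −1000 HU.

## The deformable registration

A symmetric-forces, demons-style iteration on a coarse-to-fine pyramid. It
stands in for the proprietary constrained-deformation module of a commercial
TPS; the workflow's acceptance surface is metric-based (landmark TRE, contour
Dice), not algorithm-identical, so any well-behaved regularized intensity DIR
qualifies.

Per iteration on level grid L (force, in mm):

    u = −(m∘φ − f) · J / (|J|² + ((m∘φ − f)/s)²),   J = ½(∇f + ∇(m∘φ))

with `s = step_size` (default 2 mm; the normalization caps |u| at s/2 per
iteration). The force field is smoothed with a Gaussian of width
`regularization_sigma_mm` (fluid-like), added to the accumulated field, which
is then smoothed at half that width (elastic-like). Flat-intensity regions
receive zero force and are filled in by the regularization — the known
failure mode of intensity DIR in low-contrast regions is therefore graceful
(the field interpolates smoothly) rather than noisy.

Controlling ROIs (pairs of corresponding masks on fixed and moving) add a
demons force computed on Gaussian-softened (σ = 2 mm) mask level-sets, scaled
by a configurable weight (default 0.5, an open choice: the clinical module
states that ROIs drive the deformation but publishes no weighting). A focus
ROI multiplies the update by a softened indicator, suppressing updates
outside. Cross-modality deformable registration is supported through a
`local_correlation` similarity (intensities locally normalized at σ = 6 mm);
mean-squares registration of mixed CT/MRI inputs is a contract error.

Defaults: 3 pyramid levels (downsampling 4/2/1, anti-alias smoothing before
decimation), iterations (150, 80, 30), regularization σ = 3.5 mm,
convergence when the mean update norm drops below 0.001 mm. These values
were calibrated on the phantom acceptance criteria — they balance recovery
of smooth, large-scale deformations (which favor stronger regularization)
against the sharp 2–4.5 mm boundary motion of the shrinking tumor (which
favors weaker). The registration records a full-resolution mean-squares
history per level so the pyramid's monotone improvement is testable.

Determinism: the DIR is pure NumPy/SciPy with no random sampling; the rigid
stage uses SimpleITK's REGULAR sampling strategy. Two runs with identical
inputs produce bitwise-identical reports (hashes are checked in the tests).

## The validation phantom

Paired CT/MRI 3D Shepp–Logan-type phantoms: a soft-tissue body ellipsoid, a
bony shell, a brain, two ventricles, a small (~0.97 cm³) cyst, and a tumor.
Voxel value = value of the last ellipsoid containing the voxel center
(painting order resolves overlaps unambiguously); background −1000 HU / 0 a.u.
Gaussian smoothing (default σ = 1 mm; no width is published for the original
filtering, so it is a free parameter) is applied after painting; ROI masks
are cut from the unsmoothed geometry and landmarks sit at ellipsoid centers.

The MRI channel differs from the CT channel in three deliberate ways:

- **Intensities.** A T1-weighted-like map (scalp 240, brain 160, tumor 100,
  CSF/cyst 40, bone 20, air 0 a.u.). Only the ordering/contrast matters for
  intensity-based DIR, not absolute values.
- **Distortion.** Every ellipsoid's main axes are scaled by exactly +1%
  about its own center, emulating MRI spatial distortion.
- **Grid.** Finer and anisotropic (default 0.8 × 0.8 × 1.5 mm vs 1 mm
  isotropic CT), mimicking clinical MRI voxel ranges.

Interfractional change: the tumor's full axes (30.8, 27.7, 25.0 mm) shrink
by (4.0, 6.5, 9.0 mm) in the verification time point, i.e. by 13%, 23.5% and
36% per axis — the published shrinkage extremes 13–36% (4–9 mm) with the
middle axis interpolated. The verification volumes are rendered directly
from the shrunken specification, so the verification CT is exact ground
truth for the sCT.

What the phantom does *not* emulate: MRI acquisition physics (k-space, bias
fields, sequence-specific distortion at air–bone interfaces), noise (an
additive Gaussian term exists but is off by default and requires an explicit
seed), detailed anatomy, or CT artifacts. Passing the phantom gates
therefore demonstrates the correctness of the geometry/registration/dose
chain, not clinical registration accuracy on real images.

## The toy dose engine

An analytic proton pencil-beam model used only to exercise the gamma/DVH
chain end-to-end: water-equivalent path length (WEPL) by fine ray sampling
(step ≤ 0.5 × min spacing) of a two-segment HU→relative-stopping-power
lookup (RSP = max(0.001, 1 + HU/1000) below 100 HU, 1.1 + 0.0005·(HU−100)
above — a documented non-clinical calibration anchored at water and air),
then per beam a Gaussian-peak Bragg depth dose
`plateau + (1−plateau)·exp(−(wepl−R)²/2σ²)` cut to zero beyond R+3σ, times a
Gaussian lateral profile. Beam weights are fractions of the prescription at
the native peak; the default plan is a 10-range spread-out peak (weights from
a nonnegative least-squares fit to a flat profile over the tumor's WEPL span)
giving V95 ≈ 100% of the target at 54 GyRBE. The model is linear in beam
weight and anatomy-sensitive: upstream density changes shift the distal
fall-off by the WEPL difference, which the tests verify against ray-traced
WEPL. No Monte Carlo transport, nuclear halo, or RBE modeling beyond the
fixed 1.1 implied by the GyRBE label.

## Metrics

- **TRE**: per-label Euclidean distances after mapping the landmark set that
  lives in the field's frame through `x → x + d(x)`; mean, RMSE
  (RMSE² = mean of squares, exactly), max.
- **Dice**: `2|A∩B|/(|A|+|B|)` on a shared grid; the degenerate
  empty-vs-empty case is defined as 1.0.
- **Gamma index** (global): for each reference voxel at/above the dose
  threshold, minimize `√(ΔD²/dd² + |Δr|²/dta²)` over a fine offset lattice
  (step dta/10, radius 3·dta) with trilinear interpolation of the evaluated
  dose. Offsets are visited in ascending |Δr| and each voxel stops once the
  pure spatial term exceeds its current best, so the search is exhaustive on
  the lattice (it equals the brute-force scan by construction, verified
  per-voxel to 1e-3 in the tests) yet near-constant-cost when distributions
  agree. Defaults 2 mm/2% with a 5% threshold; both the dose-difference
  normalization and the threshold are relative to the prescription (the
  published criteria state the threshold is prescription-relative; the dd
  normalization is assumed likewise, with `global_max` available as a
  switch). The pass-rate denominator counts only evaluated (above-threshold)
  reference voxels. Gamma is asymmetric in the ref/eval roles by definition.
- **DVH**: statistics from the voxel dose multiset within a mask, descending
  sort with fractional-voxel linear interpolation on the cumulative volume;
  Dx% (dose to the hottest x% of volume), Dxcc (hottest x cm³ — near-maximum
  "D2" reports are ambiguous between D2% and D2cc in clinical tables, so
  both are computed and labelled explicitly), Vx% relative to prescription.
- **Replan trigger**: fires when V95 of the target drops by ≥ 5 *percentage
  points* between the reference-plan and sCT evaluations (the conventional
  absolute reading of the adaptive-radiotherapy trigger).

Validation gates enforced by the workflow: TRE < 3 mm; Dice > 0.85 per ROI,
relaxed to > 0.8 for structures smaller than 1 cm³.

## Problem sizes and numerical choices

The default study runs at 128³ voxels / 1 mm CT and ~160×160×86 MRI — the
scale at which the registration gates are evaluated; unit tests use a
half-resolution (64³ / 2 mm) variant of the same phantom. Dose is computed
on a 2 mm grid covering the CT extent. Field inversion (used only for
inverse-consistency checks) is a fixed-point iteration, 20 iterations,
0.05 mm tolerance. Interpolation is trilinear for images and fields, nearest
for masks/labels (trilinear on labels is a contract error). Out-of-extent
fills are physically neutral: −1000 HU (air) for CT, 0 for MRI and dose;
DVF resampling zeroes and flags out-of-extent voxels.

## Known limitations

- The DIR is a generic regularized demons scheme, not a reimplementation of
  any commercial algorithm; point controlling structures are not supported.
- The exact frame-adaptation math of the clinical workflow is unpublished;
  the rigid conjugation used here is the standard choice.
- The dose engine is qualitative; absolute dosimetry and robustness
  scenarios (setup/density perturbations) are out of scope.
- The phantom's verification CT is rendered, not acquired: real vCT-vs-sCT
  comparisons include imaging noise and artifacts that this desk-scale
  validation cannot probe.
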