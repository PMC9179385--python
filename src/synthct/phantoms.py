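"""Paired CT/MRI Shepp-Logan-type digital phantoms.

The validation inputs of the synthetic-CT workflow are generated here: a
head-like arrangement of ellipsoids rendered once with CT numbers (HU) and
once with T1-weighted-like MRI intensities (a.u.).  The MRI rendering mimics
scanner distortion by scaling every ellipsoid's main axes by a small factor
(default +1%) about its own center, and uses a finer, anisotropic grid.  The
interfractional anatomical change is a shrinkage of one designated "tumor"
ellipsoid in the verification time point.  ROI masks are cut from the
unsmoothed geometry; landmarks sit at the ellipsoid centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core_images import (
    Grid3,
    ImageVolume,
    LandmarkSet,
    Modality,
    ROIMask,
)

__all__ = [
    "EllipsoidSpec",
    "PhantomSpec",
    "PhantomCase",
    "render_phantom",
    "derive_verification_spec",
    "build_case",
    "default_phantom_spec",
]

BACKGROUND_HU = -1000.0
BACKGROUND_AU = 0.0


@dataclass(frozen=True)
class EllipsoidSpec:
    """One ellipsoid: center/semi-axes in world mm, per-channel intensities."""

    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    ct_value: float
    mri_value: float
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"ellipsoid {self.name!r}: semi-axes must be positive")
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError(f"ellipsoid {self.name!r}: rotation must be orthonormal")

    def inside(self, points: np.ndarray, axis_scale: float = 1.0) -> np.ndarray:
        """Boolean inside-test for world points (..., 3); axes scaled about center."""
        rel = (np.asarray(points, float) - np.asarray(self.center)) @ self.rotation
        u = rel / (np.asarray(self.semi_axes) * axis_scale)
        return np.einsum("...i,...i->...", u, u) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom recipe: painted ellipsoids (later entries override earlier),
    per-channel grids, smoothing width, MRI distortion and tumor shrinkage."""

    ellipsoids: tuple[EllipsoidSpec, ...]
    ct_grid: Grid3
    mri_grid: Grid3
    smoothing_sigma_mm: float = 1.0
    mri_axis_scale: float = 1.01
    tumor_name: str = "tumor"
    tumor_axis_reduction_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    extra_landmarks: tuple[tuple[str, tuple[float, float, float]], ...] = ()
    noise_sigma: float = 0.0
    noise_seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "ellipsoids", tuple(self.ellipsoids))
        names = [e.name for e in self.ellipsoids]
        if len(set(names)) != len(names):
            raise ValueError("ellipsoid names must be unique")
        if self.tumor_name not in names:
            raise ValueError(f"tumor_name {self.tumor_name!r} is not an ellipsoid name")
        if self.smoothing_sigma_mm < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.mri_axis_scale < 1.0:
            raise ValueError("mri_axis_scale must be >= 1")
        tum = self.tumor()
        for red, sa in zip(self.tumor_axis_reduction_mm, tum.semi_axes):
            if red < 0 or red >= 2 * sa:
                raise ValueError("axis reduction must lie in [0, full axis length)")
        if self.noise_sigma > 0 and self.noise_seed is None:
            raise ValueError("noise requires an explicit seed")

    def tumor(self) -> EllipsoidSpec:
        return next(e for e in self.ellipsoids if e.name == self.tumor_name)


@dataclass
class PhantomCase:
    """Paired reference/verification CT+MRI with per-time-point masks and landmarks."""

    ref_ct: ImageVolume
    ref_mri: ImageVolume
    verif_ct: ImageVolume
    verif_mri: ImageVolume
    masks_ref: dict[str, ROIMask]
    masks_verif: dict[str, ROIMask]
    landmarks_ref: LandmarkSet
    landmarks_verif: LandmarkSet


# -- rendering ----------------------------------------------------------------

def render_phantom(spec: PhantomSpec, channel: str):
    """Render one channel of the phantom.

    Returns ``(volume, masks, landmarks)``.  Voxel value = value of the last
    ellipsoid containing the voxel center (painting order resolves overlaps);
    background is -1000 HU / 0 a.u.  The MRI channel uses ``mri_value``
    intensities, semi-axes scaled by ``mri_axis_scale`` about each center and
    the (typically finer) ``mri_grid``.  Gaussian smoothing with
    ``smoothing_sigma_mm`` is applied last; masks are cut from the unsmoothed,
    unscaled geometry.
    """
    if channel not in ("CT", "MRI"):
        raise ValueError(f"channel must be 'CT' or 'MRI', got {channel!r}")
    is_ct = channel == "CT"
    grid = spec.ct_grid if is_ct else spec.mri_grid
    scale = 1.0 if is_ct else spec.mri_axis_scale
    pts = grid.voxel_centers()

    vox = np.full(grid.shape, BACKGROUND_HU if is_ct else BACKGROUND_AU, dtype=float)
    masks: dict[str, ROIMask] = {}
    for ell in spec.ellipsoids:
        inside = ell.inside(pts, axis_scale=scale)
        vox[inside] = ell.ct_value if is_ct else ell.mri_value
        # ROI geometry is the nominal (unscaled, unsmoothed) ellipsoid
        masks[ell.name] = ROIMask(grid, ell.inside(pts).astype(np.uint8), ell.name)

    if spec.smoothing_sigma_mm > 0:
        sigma_vox = [spec.smoothing_sigma_mm / s for s in grid.spacing]
        vox = ndimage.gaussian_filter(vox, sigma=sigma_vox)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.noise_seed)
        vox = vox + rng.normal(0.0, spec.noise_sigma, size=vox.shape)

    labels = [e.name for e in spec.ellipsoids] + [n for n, _ in spec.extra_landmarks]
    points = [e.center for e in spec.ellipsoids] + [p for _, p in spec.extra_landmarks]
    lms = LandmarkSet(labels, np.asarray(points, dtype=float))

    modality = Modality.CT_HU if is_ct else Modality.MRI_AU
    return ImageVolume(grid, vox, modality), masks, lms


def derive_verification_spec(ref: PhantomSpec) -> tuple[PhantomSpec, tuple[float, ...]]:
    """Shrink the tumor ellipsoid for the verification time point.

    Full axis lengths are reduced by ``tumor_axis_reduction_mm`` (the center is
    unchanged).  Returns the new spec and the per-axis fractional shrinkage.
    """
    tum = ref.tumor()
    red = np.asarray(ref.tumor_axis_reduction_mm, dtype=float)
    full = 2.0 * np.asarray(tum.semi_axes)
    if np.any(red >= full):
        raise ValueError("axis reduction must be smaller than the full axis length")
    new_semi = (full - red) / 2.0
    fractions = tuple(float(f) for f in red / full)
    new_tum = replace(tum, semi_axes=tuple(new_semi))
    ells = tuple(new_tum if e.name == tum.name else e for e in ref.ellipsoids)
    return replace(ref, ellipsoids=ells), fractions


def build_case(ref_spec: PhantomSpec) -> PhantomCase:
    """Render the full four-volume case (ref/verif x CT/MRI) with masks and landmarks.

    Deterministic unless noise is configured (which requires an explicit seed).
    """
    verif_spec, _ = derive_verification_spec(ref_spec)
    if ref_spec.noise_sigma > 0:
        # decorrelate the four renders while staying reproducible
        verif_spec = replace(verif_spec, noise_seed=ref_spec.noise_seed + 1)

    ref_ct, masks_ct_ref, lms_ref = render_phantom(ref_spec, "CT")
    ref_mri, _, _ = render_phantom(ref_spec, "MRI")
    verif_ct, masks_ct_verif, lms_verif = render_phantom(verif_spec, "CT")
    verif_mri, _, _ = render_phantom(verif_spec, "MRI")
    return PhantomCase(
        ref_ct=ref_ct,
        ref_mri=ref_mri,
        verif_ct=verif_ct,
        verif_mri=verif_mri,
        masks_ref=masks_ct_ref,
        masks_verif=masks_ct_verif,
        landmarks_ref=lms_ref,
        landmarks_verif=lms_verif,
    )


# -- default study phantom ----------------------------------------------------

def default_phantom_spec(
    ct_shape=(128, 128, 128),
    ct_spacing=(1.0, 1.0, 1.0),
    mri_spacing=(0.8, 0.8, 1.5),
    smoothing_sigma_mm: float = 1.0,
    tumor_axis_reduction_mm=(4.0, 6.5, 9.0),
) -> PhantomSpec:
    """The default head-like validation phantom.

    A soft-tissue body with a bony shell, brain, two ventricles, a small
    (~0.97 cm^3) cyst and a tumor whose full axes (30.8, 27.7, 25.0) mm shrink
    by (4.0, 6.5, 9.0) mm between time points, i.e. by 13%, 23.5% and 36% per
    axis.  MRI intensities are T1-weighted-like (bright scalp, dark bone/CSF).
    """
    ct_grid = Grid3.centered(ct_shape, ct_spacing)
    extent = np.asarray(ct_shape) * np.asarray(ct_spacing)
    mri_shape = tuple(int(np.ceil(e / s)) for e, s in zip(extent, mri_spacing))
    mri_grid = Grid3.centered(mri_shape, mri_spacing)

    ells = (
        EllipsoidSpec("body", (0, 0, 0), (52, 62, 56), ct_value=40, mri_value=240),
        EllipsoidSpec("bone", (0, 0, 0), (46, 56, 50), ct_value=700, mri_value=20),
        EllipsoidSpec("brain", (0, 0, 0), (41, 51, 45), ct_value=30, mri_value=160),
        EllipsoidSpec("ventricle_left", (-14, 10, 0), (6, 14, 10), ct_value=10, mri_value=40),
        EllipsoidSpec("ventricle_right", (10, 14, 4), (5, 12, 9), ct_value=10, mri_value=40),
        EllipsoidSpec("cyst", (-18, -22, 6), (6.15, 6.15, 6.15), ct_value=20, mri_value=40),
        EllipsoidSpec("tumor", (22, -12, 0), (15.4, 13.85, 12.5), ct_value=100, mri_value=100),
    )
    return PhantomSpec(
        ellipsoids=ells,
        ct_grid=ct_grid,
        mri_grid=mri_grid,
        smoothing_sigma_mm=smoothing_sigma_mm,
        mri_axis_scale=1.01,
        tumor_name="tumor",
        tumor_axis_reduction_mm=tuple(tumor_axis_reduction_mm),
    )
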