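"""Rigid pre-alignment and multi-resolution deformable registration.

The deformable algorithm is a symmetric-forces, demons-style iteration with
Gaussian regularization on a coarse-to-fine pyramid.  It stands in for the
proprietary constrained-deformation module of a commercial treatment planning
system: the acceptance surface of the workflow is metric-based (landmark TRE,
contour Dice), not algorithm-identical, so any well-behaved regularized
intensity DIR qualifies.  Contoured ROIs can participate as *controlling*
structures (an extra force aligning corresponding mask level-sets) and as a
*focus* region (updates suppressed outside).

Displacement convention (pull-back): the field ``d`` lives on the fixed grid
and ``warped(x) = moving(x + d(x))`` in world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core_images import (
    DEFAULT_FILL,
    Grid3,
    ImageVolume,
    Modality,
    ROIMask,
    _to_sitk,
)

__all__ = [
    "RigidTransform",
    "RegistrationParams",
    "DeformationField",
    "register_rigid",
    "register_deformable",
]


@dataclass(frozen=True)
class RigidTransform:
    """x_moving = rotation @ x_fixed + translation (world mm, both frames LPS)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        R = self.rotation
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be a proper rotation (det=+1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


@dataclass
class RegistrationParams:
    """Tunables of the deformable registration.

    ``regularization_sigma_mm`` controls the Gaussian smoothing of the force
    field (fluid-like) and, at half width, of the accumulated displacement
    field (elastic-like), applied every iteration.  ``step_size`` caps the
    per-iteration update magnitude at ``step_size / 2`` mm through the demons
    normalization term.
    """

    pyramid_levels: int = 3
    iterations_per_level: tuple[int, ...] = (150, 80, 30)
    regularization_sigma_mm: float = 3.5
    similarity: str = "mean_squares"  # or "local_correlation"
    controlling_masks: tuple[tuple[ROIMask, ROIMask, float], ...] = ()
    focus_mask: ROIMask | None = None
    step_size: float = 2.0
    convergence_tol: float = 0.001

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        self.iterations_per_level = tuple(int(n) for n in self.iterations_per_level)
        if len(self.iterations_per_level) != self.pyramid_levels:
            raise ValueError("iterations_per_level length must equal pyramid_levels")
        if self.regularization_sigma_mm <= 0:
            raise ValueError("regularization_sigma_mm must be > 0")
        if self.similarity not in ("mean_squares", "local_correlation"):
            raise ValueError(f"unknown similarity {self.similarity!r}")


@dataclass(eq=False)
class DeformationField:
    """Per-voxel displacement vectors (mm) on a grid, pull-back convention."""

    grid: Grid3
    displacements: np.ndarray  # shape grid.shape + (3,)
    provenance: str = ""
    converged: bool = True
    warning: str | None = None
    out_of_extent: np.ndarray | None = None  # set by DVF resampling
    metric_history: tuple[float, ...] = ()  # full-res MSE after each pyramid level

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=float)
        if tuple(self.displacements.shape) != self.grid.shape + (3,):
            raise ValueError("displacement array shape must be grid.shape + (3,)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")

    @classmethod
    def zero(cls, grid: Grid3, provenance: str = "identity") -> "DeformationField":
        return cls(grid, np.zeros(grid.shape + (3,)), provenance)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)

    def sample_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear displacement vectors at world points (..., 3); 0 outside."""
        idx = self.grid.world_to_index(points)
        coords = np.moveaxis(idx, -1, 0)
        out = np.empty(points.shape[:-1] + (3,))
        for c in range(3):
            out[..., c] = ndimage.map_coordinates(
                self.displacements[..., c], coords, order=1, mode="constant", cval=0.0
            )
        return out


# -- rigid --------------------------------------------------------------------

def register_rigid(fixed: ImageVolume, moving: ImageVolume,
                   sampling_fraction: float = 0.2) -> RigidTransform:
    """Estimate a rigid transform mapping fixed-frame points into the moving frame.

    Mean-squares similarity for same-modality pairs, Mattes mutual information
    across modalities (e.g. CT vs MRI).  Deterministic (regular sampling).
    """
    f = sitk.Cast(_to_sitk(fixed), sitk.sitkFloat32)
    m = sitk.Cast(_to_sitk(moving), sitk.sitkFloat32)
    initial = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    if fixed.modality == moving.modality:
        reg.SetMetricAsMeanSquares()
    else:
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    # fixed seed: the default is wall-clock, which breaks run-to-run determinism
    reg.SetMetricSamplingPercentage(sampling_fraction, 12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200, relaxationFactor=0.5
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        tx = reg.Execute(f, m)
    except RuntimeError as exc:
        raise RuntimeError(
            f"rigid registration failed (fields of view may not overlap): {exc}"
        ) from exc
    tx = sitk.Euler3DTransform(sitk.CompositeTransform(tx).GetNthTransform(0))
    R = np.asarray(tx.GetMatrix()).reshape(3, 3)
    center = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    # sitk: y = R (x - c) + c + t  ->  translation = c + t - R c
    return RigidTransform(R, center + t - R @ center)


# -- deformable ---------------------------------------------------------------

def _world_gradient(arr: np.ndarray, grid: Grid3) -> np.ndarray:
    """Spatial gradient in world mm of an array on ``grid``, shape (..., 3)."""
    gi = np.stack(np.gradient(arr), axis=-1)  # d/d(index)
    Ainv_T = np.linalg.inv(grid.affine)  # (d idx / d x)^T rows
    return gi @ Ainv_T


def _local_normalize(arr: np.ndarray, sigma_vox) -> np.ndarray:
    mean = ndimage.gaussian_filter(arr, sigma_vox)
    var = ndimage.gaussian_filter((arr - mean) ** 2, sigma_vox)
    return (arr - mean) / np.sqrt(var + 1e-6)


def _level_grid(grid: Grid3, factor: int) -> Grid3:
    if factor == 1:
        return grid
    shape = tuple(max(2, int(np.ceil(n / factor))) for n in grid.shape)
    spacing = tuple(s * factor for s in grid.spacing)
    # keep the center of voxel (0,0,0) block-aligned with the fine grid
    shift = (factor - 1) / 2.0 * np.asarray(grid.spacing)
    origin = np.asarray(grid.origin) + grid.orientation @ shift
    return Grid3(shape, spacing, tuple(origin), grid.orientation)


def _smoothed(arr: np.ndarray, sigma_vox: float) -> np.ndarray:
    return ndimage.gaussian_filter(arr.astype(float), sigma_vox) if sigma_vox > 0 else arr.astype(float)


def _sample_array(arr: np.ndarray, grid: Grid3, points: np.ndarray, fill: float) -> np.ndarray:
    idx = grid.world_to_index(points)
    return ndimage.map_coordinates(
        arr, np.moveaxis(idx, -1, 0), order=1, mode="constant", cval=fill
    )


def _demons_force(diff: np.ndarray, J: np.ndarray, step: float) -> np.ndarray:
    """Normalized symmetric demons force; |force| <= step/2 by construction."""
    j2 = np.einsum("...i,...i->...", J, J)
    denom = j2 + (diff / step) ** 2
    scale = np.where(denom > 1e-12, -diff / np.maximum(denom, 1e-12), 0.0)
    return scale[..., None] * J


def register_deformable(fixed: ImageVolume, moving: ImageVolume,
                        params: RegistrationParams | None = None) -> DeformationField:
    """Multi-resolution demons-style DIR; returns the field on the fixed grid.

    Same-modality inputs are required for ``mean_squares``; cross-modality
    pairs must use ``local_correlation`` (locally normalized intensities).
    Deterministic for fixed inputs and parameters.
    """
    params = params or RegistrationParams()
    if fixed.modality != moving.modality and params.similarity != "local_correlation":
        raise ValueError(
            "modality mismatch: use similarity='local_correlation' for cross-modality DIR"
        )
    mov_fill = DEFAULT_FILL[moving.modality.value]
    mov_arr = moving.voxels.astype(float)

    # controlling-structure level sets on their native grids (soft edges)
    ctrl = []
    for fm, mm, w in params.controlling_masks:
        sig_f = [2.0 / s for s in fm.grid.spacing]
        sig_m = [2.0 / s for s in mm.grid.spacing]
        ctrl.append((
            ndimage.gaussian_filter(fm.voxels.astype(float), sig_f), fm.grid,
            ndimage.gaussian_filter(mm.voxels.astype(float), sig_m), mm.grid,
            float(w),
        ))

    fix_full = fixed.voxels.astype(float)
    X_full = fixed.grid.voxel_centers()
    if params.similarity == "local_correlation":
        fix_full_cmp = _local_normalize(fix_full, [6.0 / s for s in fixed.grid.spacing])
    else:
        fix_full_cmp = fix_full

    def full_res_mse(d_arr, grid):
        dd = d_arr if grid.same_geometry(fixed.grid) else _resample_field_array(d_arr, grid, fixed.grid)
        warped = _sample_array(mov_arr, moving.grid, X_full + dd, mov_fill)
        if params.similarity == "local_correlation":
            warped = _local_normalize(warped, [6.0 / s for s in fixed.grid.spacing])
        return float(np.mean((warped - fix_full_cmp) ** 2))

    levels = params.pyramid_levels
    d = None
    prev_grid = None
    converged = True
    history = []
    for lev in range(levels):
        factor = 2 ** (levels - 1 - lev)
        grid = _level_grid(fixed.grid, factor)
        aa_sigma = factor / 2.0 if factor > 1 else 0.0

        fix_arr = _smoothed(fixed.voxels, aa_sigma)
        f_lev = _sample_array(fix_arr, fixed.grid, grid.voxel_centers(),
                              DEFAULT_FILL[fixed.modality.value])
        mov_lev = _smoothed(mov_arr, aa_sigma * min(fixed.grid.spacing) / min(moving.grid.spacing))

        sigma_vox_local = [6.0 / s for s in grid.spacing]
        if params.similarity == "local_correlation":
            f_lev = _local_normalize(f_lev, sigma_vox_local)

        X = grid.voxel_centers()
        if d is None:
            d = np.zeros(grid.shape + (3,))
        else:
            d = _resample_field_array(d, prev_grid, grid)
        prev_grid = grid

        grad_f = _world_gradient(f_lev, grid)
        fluid_vox = [params.regularization_sigma_mm / s for s in grid.spacing]
        elastic_vox = [0.5 * params.regularization_sigma_mm / s for s in grid.spacing]

        focus = None
        if params.focus_mask is not None:
            fsig = [1.0 / s for s in params.focus_mask.grid.spacing]
            fsoft = ndimage.gaussian_filter(params.focus_mask.voxels.astype(float), fsig)
            focus = _sample_array(fsoft, params.focus_mask.grid, X, 0.0)

        ctrl_lev = []
        for fm_arr, fm_grid, mm_arr, mm_grid, w in ctrl:
            cf = _sample_array(fm_arr, fm_grid, X, 0.0)
            ctrl_lev.append((cf, _world_gradient(cf, grid), mm_arr, mm_grid, w))

        n_iter = params.iterations_per_level[lev]
        level_converged = n_iter == 0
        for _ in range(n_iter):
            pts = X + d
            warped = _sample_array(mov_lev, moving.grid, pts, mov_fill)
            if params.similarity == "local_correlation":
                warped = _local_normalize(warped, sigma_vox_local)
            J = 0.5 * (grad_f + _world_gradient(warped, grid))
            update = _demons_force(warped - f_lev, J, params.step_size)

            for cf, cgrad, mm_arr, mm_grid, w in ctrl_lev:
                cw = _sample_array(mm_arr, mm_grid, pts, 0.0)
                Jc = 0.5 * (cgrad + _world_gradient(cw, grid))
                update = update + w * _demons_force(cw - cf, Jc, params.step_size)

            if focus is not None:
                update = update * focus[..., None]
            for c in range(3):
                update[..., c] = ndimage.gaussian_filter(update[..., c], fluid_vox)
            d = d + update
            for c in range(3):
                d[..., c] = ndimage.gaussian_filter(d[..., c], elastic_vox)
            if float(np.mean(np.linalg.norm(update, axis=-1))) < params.convergence_tol:
                level_converged = True
                break
        converged = converged and level_converged
        history.append(full_res_mse(d, grid))

    if prev_grid is not None and not prev_grid.same_geometry(fixed.grid):
        d = _resample_field_array(d, prev_grid, fixed.grid)
    return DeformationField(
        fixed.grid, d,
        provenance=f"DIR fixed={fixed.modality.value} moving={moving.modality.value}",
        converged=converged,
        warning=None if converged else "finest level did not reach convergence tolerance",
        metric_history=tuple(history),
    )


def _resample_field_array(d: np.ndarray, src: Grid3, dst: Grid3) -> np.ndarray:
    """Componentwise trilinear resampling of a displacement array between grids."""
    pts = dst.voxel_centers()
    idx = src.world_to_index(pts)
    coords = np.moveaxis(idx, -1, 0)
    out = np.empty(dst.shape + (3,))
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            d[..., c], coords, order=1, mode="nearest"
        )
    return out
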