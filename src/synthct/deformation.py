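"""Deformation-field frame adaptation, warping, and synthetic-CT assembly.

The deformation captured between the reference and verification MRI lives in
the MRI frame of reference; to synthesize a CT it must be expressed in the
frame and on the grid of the planning CT.  With a rigid link ``T(y) = R y + t``
mapping destination-frame points into the field's frame, the geometrically
equivalent field in the destination frame is the conjugation
``d'(y) = R^-1 d(R y + t)``; the synthetic CT is then a single pull-back
interpolation ``sCT(y) = refCT(y + d'(y))`` on the planning-CT grid.
"""

from __future__ import annotations

import numpy as np

from .core_images import (
    DEFAULT_FILL,
    Grid3,
    ImageVolume,
    Modality,
    ROIMask,
    sample_at_world,
)
from .registration import (
    DeformationField,
    RegistrationParams,
    RigidTransform,
    register_deformable,
    register_rigid,
)

__all__ = [
    "resample_dvf",
    "change_frame",
    "warp_volume",
    "invert_field",
    "propagate_mask",
    "make_synthetic_ct",
]


def _extents_overlap(a: Grid3, b: Grid3) -> bool:
    def corners(g: Grid3) -> np.ndarray:
        n = np.asarray(g.shape) - 1
        idx = np.array([[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])])
        return g.index_to_world(idx)

    ca, cb = corners(a), corners(b)
    return bool(np.all(ca.max(0) >= cb.min(0)) and np.all(cb.max(0) >= ca.min(0)))


def resample_dvf(field: DeformationField, target: Grid3) -> DeformationField:
    """Componentwise trilinear resampling of a DVF onto ``target``.

    Target voxels outside the source extent get zero displacement and are
    flagged in ``out_of_extent``.
    """
    if target.same_geometry(field.grid):
        return DeformationField(target, field.displacements.copy(), field.provenance,
                                field.converged, field.warning)
    if not _extents_overlap(field.grid, target):
        raise ValueError("target grid extent is disjoint from the field extent")
    pts = target.voxel_centers()
    idx = field.grid.world_to_index(pts)
    inside = np.all((idx >= 0) & (idx <= np.asarray(field.grid.shape) - 1), axis=-1)
    disp = field.sample_at(pts)
    disp[~inside] = 0.0
    out = DeformationField(target, disp, field.provenance, field.converged, field.warning)
    out.out_of_extent = ~inside
    return out


def change_frame(field: DeformationField, link: RigidTransform) -> DeformationField:
    """Express a DVF in a new frame of reference connected by a rigid link.

    ``link`` maps destination-frame points into the field's frame.  The
    returned field ``d'(y) = R^-1 d(R y + t)`` sits on the field's grid mapped
    into the destination frame (exact conjugation, no interpolation), so that
    pull-back warping in the destination frame is geometrically equivalent.
    """
    R = link.rotation
    Rinv = R.T
    new_grid = Grid3(
        shape=field.grid.shape,
        spacing=field.grid.spacing,
        origin=tuple(Rinv @ (np.asarray(field.grid.origin) - link.translation)),
        orientation=Rinv @ field.grid.orientation,
    )
    disp = field.displacements @ Rinv.T  # rotate every vector by R^-1
    return DeformationField(new_grid, disp, field.provenance + " | frame-adapted",
                            field.converged, field.warning)


def warp_volume(vol: ImageVolume, field: DeformationField, interp: str = "trilinear",
                fill: float | None = None) -> ImageVolume:
    """Pull-back warp: ``out(x) = vol(x + d(x))`` on the field's grid."""
    if interp not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if vol.modality is Modality.LABEL and interp == "trilinear":
        raise ValueError("LABEL volumes must be warped with nearest interpolation")
    if fill is None:
        fill = DEFAULT_FILL[vol.modality.value]
    pts = field.grid.voxel_centers() + field.displacements
    order = 0 if interp == "nearest" else 1
    out = sample_at_world(vol, pts, order=order, fill=fill)
    if vol.modality is Modality.LABEL:
        out = np.rint(out).astype(vol.voxels.dtype)
    return ImageVolume(field.grid, out, vol.modality)


def invert_field(field: DeformationField, iterations: int = 20,
                 tol_mm: float = 0.05) -> DeformationField:
    """Numerical inverse by fixed-point iteration: d_inv(x) = -d(x + d_inv(x))."""
    X = field.grid.voxel_centers()
    d_inv = np.zeros_like(field.displacements)
    for _ in range(iterations):
        new = -field.sample_at(X + d_inv)
        delta = float(np.max(np.linalg.norm(new - d_inv, axis=-1)))
        d_inv = new
        if delta < tol_mm:
            break
    return DeformationField(field.grid, d_inv, field.provenance + " | inverted")


def propagate_mask(mask: ROIMask, field: DeformationField) -> ROIMask:
    """Propagate a binary ROI through the field (nearest-neighbour pull-back)."""
    warped = warp_volume(mask.as_volume(), field, interp="nearest", fill=0.0)
    return ROIMask(field.grid, warped.voxels, mask.name)


def make_synthetic_ct(
    ref_ct: ImageVolume,
    ref_mri: ImageVolume,
    verif_mri: ImageVolume,
    params: RegistrationParams | None = None,
    link: RigidTransform | None = None,
    deformable_link: DeformationField | None = None,
) -> tuple[ImageVolume, DeformationField]:
    """Synthesize a CT showing the verification anatomy.

    Pipeline: (1) rigid link between the planning CT and the reference MRI
    (estimated by mutual-information rigid registration unless supplied);
    (2) deformable registration with fixed=verification MRI, moving=reference
    MRI, capturing the interfractional anatomical change as a DVF; (3) frame
    adaptation + resampling of the DVF onto the planning-CT grid; (4) pull-back
    warp of the planning CT.  Returns the sCT (on the planning-CT grid) and the
    CT-frame DVF.

    ``deformable_link`` optionally refines the rigid CT-MRI link with a
    pull-back residual field on the planning-CT grid (CT point ``y`` maps to
    MRI point ``link(y) + deformable_link(y)``).  It is applied as resampling
    only — the MRI-frame DVF is sampled at the deformably mapped points and
    its vectors rotated by the rigid rotation — never conjugated.
    """
    try:
        if link is None:
            link = register_rigid(ref_ct, ref_mri)
    except Exception as exc:
        raise RuntimeError(f"synthetic-CT stage 'rigid CT-MRI link' failed: {exc}") from exc
    try:
        dvf_mri = register_deformable(verif_mri, ref_mri, params)
    except Exception as exc:
        raise RuntimeError(f"synthetic-CT stage 'deformable MRI-MRI' failed: {exc}") from exc
    try:
        if deformable_link is None:
            dvf_ct = resample_dvf(change_frame(dvf_mri, link), ref_ct.grid)
        else:
            Y = ref_ct.grid.voxel_centers()
            pts = link.apply(Y) + deformable_link.sample_at(Y)
            disp = dvf_mri.sample_at(pts) @ link.rotation  # rotate by R^-1
            dvf_ct = DeformationField(
                ref_ct.grid, disp,
                dvf_mri.provenance + " | frame-adapted (deformable link)",
                dvf_mri.converged, dvf_mri.warning,
            )
        sct = warp_volume(ref_ct, dvf_ct, interp="trilinear")
    except Exception as exc:
        raise RuntimeError(f"synthetic-CT stage 'DVF adaptation/warp' failed: {exc}") from exc
    return sct, dvf_ct
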