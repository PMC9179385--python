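"""Shared fixtures: small phantoms for unit tests and the full-scale
validation runs (computed once per session) for the end-to-end checks."""

import numpy as np
import pytest

from synthct.core_images import Grid3
from synthct.deformation import make_synthetic_ct, propagate_mask, warp_volume
from synthct.metrics import compute_dice, compute_tre
from synthct.phantoms import build_case, default_phantom_spec, render_phantom
from synthct.registration import (
    DeformationField,
    RegistrationParams,
    RigidTransform,
    register_deformable,
)
from synthct.workflow import default_registration_params


def small_phantom_spec(**kwargs):
    """Half-resolution study phantom (64^3 at 2 mm) for fast unit tests."""
    kwargs.setdefault("ct_shape", (64, 64, 64))
    kwargs.setdefault("ct_spacing", (2.0, 2.0, 2.0))
    kwargs.setdefault("mri_spacing", (1.6, 1.6, 2.0))
    return default_phantom_spec(**kwargs)


@pytest.fixture(scope="session")
def small_case():
    return build_case(small_phantom_spec())


@pytest.fixture(scope="session")
def small_run(small_case):
    """Small-scale sCT pipeline result: (case, sct, dvf, dice-per-roi, tre)."""
    case = small_case
    params = default_registration_params(case)
    sct, dvf = make_synthetic_ct(
        case.ref_ct, case.ref_mri, case.verif_mri, params=params,
        link=RigidTransform.identity(),
    )
    dice = {
        name: compute_dice(propagate_mask(mask, dvf), case.masks_verif[name])
        for name, mask in case.masks_ref.items()
    }
    tre = compute_tre(case.landmarks_verif, case.landmarks_ref, field=dvf)
    return case, sct, dvf, dice, tre


@pytest.fixture(scope="session")
def full_run():
    """Full-scale (128^3 / 1 mm) phantom validation run, incl. the estimated
    rigid CT-MRI link; shared by the acceptance-level checks."""
    spec = default_phantom_spec()
    case = build_case(spec)
    params = default_registration_params(case)
    sct, dvf = make_synthetic_ct(case.ref_ct, case.ref_mri, case.verif_mri, params=params)
    dice = {
        name: compute_dice(propagate_mask(mask, dvf), case.masks_verif[name])
        for name, mask in case.masks_ref.items()
    }
    tre = compute_tre(case.landmarks_verif, case.landmarks_ref, field=dvf)
    return case, sct, dvf, dice, tre


def gaussian_bump_field(grid: Grid3, amp=(4.0, -3.0, 2.5),
                        center=(10.0, -5.0, 5.0), sigma_mm=25.0) -> DeformationField:
    """Smooth synthetic ground-truth deformation (|d| <= ~5.6 mm)."""
    X = grid.voxel_centers()
    r2 = np.sum((X - np.asarray(center)) ** 2, axis=-1)
    disp = np.exp(-r2 / (2 * sigma_mm**2))[..., None] * np.asarray(amp)
    return DeformationField(grid, disp, provenance="synthetic ground truth")


@pytest.fixture(scope="session")
def recovery_run():
    """Full-scale recovery of a known smooth deformation.

    Returns (spec, true MRI-frame field, recovered field, body mask on MRI
    grid, sct, ground-truth-warped CT, body mask on CT grid).
    """
    spec = default_phantom_spec()
    mri, masks_mri, _ = render_phantom(spec, "MRI")
    ct, masks_ct, _ = render_phantom(spec, "CT")

    d_true_mri = gaussian_bump_field(mri.grid)
    verif_mri = warp_volume(mri, d_true_mri)

    recovered = register_deformable(verif_mri, mri, RegistrationParams())
    sct, _ = make_synthetic_ct(ct, mri, verif_mri, RegistrationParams(),
                               link=RigidTransform.identity())
    gt_warped_ct = warp_volume(ct, gaussian_bump_field(ct.grid))
    return (spec, d_true_mri, recovered, masks_mri["body"], sct, gt_warped_ct,
            masks_ct["body"])
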