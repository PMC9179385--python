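"""End-to-end orchestration: phantom -> sCT -> dose -> metrics -> QA report.

The validation suite mirrors the clinical data flow at desk scale: the
directly rendered verification CT plays the role of the repeat X-ray CT
(ground truth), the synthetic CT is produced from the planning CT and the
MRI-to-MRI deformation, the same beam plan is computed on both, and the QA
report collects TRE, per-ROI Dice, the gamma comparison, DVH statistics per
structure per CT, and the replanning decision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core_images import (
    Grid3,
    ImageVolume,
    Modality,
    ROIMask,
    resample_mask,
    write_landmarks,
    write_volume,
)
from .deformation import make_synthetic_ct, propagate_mask
from .dose_toy import BeamSpec, DoseGrid, compute_dose
from .metrics import (
    DVHStats,
    GammaCriteria,
    GammaResult,
    TREStats,
    compute_dice,
    compute_dvh,
    compute_gamma,
    compute_tre,
    replan_decision,
)
from .phantoms import (
    EllipsoidSpec,
    PhantomCase,
    PhantomSpec,
    build_case,
    default_phantom_spec,
)
from .registration import RegistrationParams, RigidTransform

__all__ = [
    "QAReport",
    "run_validation_suite",
    "default_registration_params",
    "default_plan",
    "default_dose_grid",
    "load_config",
    "spec_from_config",
    "params_from_config",
    "plan_from_config",
    "criteria_from_config",
]

log = logging.getLogger("synthct")

TOOL_VERSION = "0.1.0"

# QA gates from the validation protocol
TRE_GATE_MM = 3.0
DSC_GATE = 0.85
DSC_GATE_SMALL = 0.8
SMALL_ROI_CC = 1.0


@dataclass
class QAReport:
    """Versioned, JSON-serializable record of one validation run."""

    case_id: str
    registration: dict
    tre: dict
    dice: dict[str, float]
    gamma: dict
    dvh: dict[str, dict[str, dict[str, float]]]  # ct_name -> structure -> stats
    replan: dict
    gates: dict
    config_snapshot: dict
    volume_hashes: dict[str, str]
    tool_version: str = TOOL_VERSION
    schema_version: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def default_registration_params(case: PhantomCase | None = None) -> RegistrationParams:
    """Default DIR parameters; body and bone ROIs act as controlling
    structures and the body ROI as the focus region when a case is given."""
    ctrl = ()
    focus = None
    if case is not None:
        ctrl = tuple(
            (case.masks_verif[name], case.masks_ref[name], 0.5)
            for name in ("body", "bone")
            if name in case.masks_verif and name in case.masks_ref
        )
        focus = case.masks_verif.get("body")
    return RegistrationParams(controlling_masks=ctrl, focus_mask=focus)


def default_plan(spec: PhantomSpec) -> tuple[list[BeamSpec], float]:
    """Spread-out-Bragg-peak beam bundle aimed at the tumor from the +x side.

    Range/weight pairs form a flat (±5%) spread-out peak over the tumor's
    water-equivalent depth span (~14-52 mm-WET on the default phantom), giving
    V95 ~ 100% of the target at a 54 GyRBE prescription.
    """
    tum = spec.tumor()
    iso = tuple(float(c) for c in tum.center)
    sobp = (
        (14.0, 0.265), (17.0, 0.130), (20.0, 0.064), (23.0, 0.019),
        (26.0, 0.043), (29.0, 0.132), (32.0, 0.131), (41.0, 0.190),
        (44.0, 0.387), (59.0, 0.845),
    )
    beams = [
        BeamSpec(direction=(-1.0, 0.0, 0.0), isocenter=iso, range_mm_wet=r,
                 peak_sigma_mm=7.0, lateral_sigma_mm=60.0, plateau_fraction=0.3,
                 weight=w)
        for r, w in sobp
    ]
    return beams, 54.0


def default_dose_grid(ct_grid: Grid3, spacing_mm: float = 2.0) -> Grid3:
    extent = np.asarray(ct_grid.shape) * np.asarray(ct_grid.spacing)
    shape = tuple(int(np.ceil(e / spacing_mm)) for e in extent)
    return Grid3.centered(shape, (spacing_mm,) * 3, ct_grid.orientation)


def _hash_volume(vol: ImageVolume) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(vol.voxels).tobytes())
    h.update(np.asarray(vol.grid.spacing).tobytes())
    h.update(np.asarray(vol.grid.origin).tobytes())
    return h.hexdigest()[:16]


def _dvh_summary(stats: DVHStats) -> dict[str, float]:
    return {
        "Dmean_gyrbe": stats.Dmean,
        "Dmax_gyrbe": stats.Dmax,
        "D1pct_gyrbe": stats.Dpct(1.0),
        "D2pct_gyrbe": stats.Dpct(2.0),
        "D2cc_gyrbe": stats.Dcc(2.0) if stats.volume_cc >= 2.0 else stats.Dmin,
        "D95pct_gyrbe": stats.Dpct(95.0),
        "V95pct_pct": stats.Vpct(95.0),
        "volume_cc": stats.volume_cc,
    }


def run_validation_suite(
    spec: PhantomSpec | None = None,
    reg: RegistrationParams | None = None,
    plan: list[BeamSpec] | None = None,
    criteria: GammaCriteria | None = None,
    prescription_gyrbe: float | None = None,
    target_roi: str | None = None,
    link: RigidTransform | None = None,
    out_dir=None,
    case_id: str = "shepp-logan-default",
    seed: int | None = None,
) -> QAReport:
    """Run the full desk-scale validation pipeline and assemble a QA report.

    Builds the phantom case, synthesizes the sCT, computes dose with the same
    plan on the reference CT, the verification CT (ground truth) and the sCT,
    and evaluates TRE, per-ROI Dice, the gamma comparison of the vCT and sCT
    doses, DVH statistics and the replanning trigger on the target ROI.
    """
    t0 = time.time()
    spec = spec or default_phantom_spec()
    if seed is not None and spec.noise_sigma > 0 and spec.noise_seed is None:
        spec = dataclasses.replace(spec, noise_seed=int(seed))
    if plan is None:
        plan, default_rx = default_plan(spec)
    else:
        default_rx = 54.0
    rx = prescription_gyrbe if prescription_gyrbe is not None else default_rx
    criteria = criteria or GammaCriteria()
    target_roi = target_roi or spec.tumor_name

    log.info("building phantom case %s", case_id)
    case = build_case(spec)
    reg = reg if reg is not None else default_registration_params(case)

    log.info("synthesizing sCT (rigid link + deformable MRI-MRI DIR)")
    t_reg = time.time()
    sct, dvf_ct = make_synthetic_ct(case.ref_ct, case.ref_mri, case.verif_mri,
                                    params=reg, link=link)
    log.info("registration + synthesis took %.1f s", time.time() - t_reg)

    body = case.masks_verif.get("body")
    sel = body.voxels.astype(bool) if body is not None else np.ones(sct.grid.shape, bool)
    final_mse = float(np.mean((sct.voxels[sel] - case.verif_ct.voxels[sel]) ** 2))
    registration_summary = {
        "pyramid_levels": reg.pyramid_levels,
        "iterations_per_level": list(reg.iterations_per_level),
        "regularization_sigma_mm": reg.regularization_sigma_mm,
        "similarity": reg.similarity,
        "converged": dvf_ct.converged,
        "final_mse_sct_vs_vct_in_body_hu2": final_mse,
        "max_displacement_mm": float(dvf_ct.magnitude().max()),
    }

    # landmark TRE: verification landmarks mapped through the CT-frame field
    tre = compute_tre(case.landmarks_verif, case.landmarks_ref, field=dvf_ct)
    tre_dict = {
        "per_landmark_mm": {lab: float(v) for lab, v in zip(tre.labels, tre.per_landmark_mm)},
        "mean_mm": tre.mean_mm,
        "rmse_mm": tre.rmse_mm,
        "max_mm": tre.max_mm,
    }

    # contour propagation Dice per ROI
    dice: dict[str, float] = {}
    for name, ref_mask in case.masks_ref.items():
        prop = propagate_mask(ref_mask, dvf_ct)
        dice[name] = compute_dice(prop, case.masks_verif[name])

    # dose on the three CTs with the same plan
    log.info("computing dose on rCT / vCT / sCT")
    dgrid = default_dose_grid(case.ref_ct.grid)
    dose_rct = compute_dose(case.ref_ct, plan, dgrid, rx)
    dose_vct = compute_dose(case.verif_ct, plan, dgrid, rx)
    dose_sct = compute_dose(sct, plan, dgrid, rx)

    gamma = compute_gamma(dose_vct, dose_sct, criteria)
    gamma_dict = {
        "criteria": dataclasses.asdict(criteria),
        "pass_rate_pct": gamma.pass_rate_pct,
        "mean_gamma": gamma.mean_gamma,
        "sd_gamma": gamma.sd_gamma,
        "evaluated_voxels": gamma.evaluated_voxels,
    }

    # DVH per structure per CT: planning contours on rCT, ground-truth contours
    # on vCT, propagated contours on sCT
    masks_sct = {name: propagate_mask(m, dvf_ct) for name, m in case.masks_ref.items()}
    dvh: dict[str, dict[str, dict[str, float]]] = {"rCT": {}, "vCT": {}, "sCT": {}}
    dvh_stats: dict[str, dict[str, DVHStats]] = {"rCT": {}, "vCT": {}, "sCT": {}}
    for ct_name, dose, masks in (
        ("rCT", dose_rct, case.masks_ref),
        ("vCT", dose_vct, case.masks_verif),
        ("sCT", dose_sct, masks_sct),
    ):
        for name, mask in masks.items():
            m = resample_mask(mask, dgrid)
            if not m.voxels.any():
                dvh[ct_name][name] = {"skipped": 1.0}
                continue
            stats = compute_dvh(dose, m)
            dvh_stats[ct_name][name] = stats
            dvh[ct_name][name] = _dvh_summary(stats)

    trigger, line = replan_decision(dvh_stats["rCT"][target_roi], dvh_stats["sCT"][target_roi])
    replan = {"target": target_roi, "trigger": bool(trigger), "report": line}

    small = {n: m.volume_cc < SMALL_ROI_CC for n, m in case.masks_verif.items()}
    gates = {
        "tre_max_mm_lt_3": tre.max_mm < TRE_GATE_MM,
        "dsc_per_roi_pass": {
            n: (d > (DSC_GATE_SMALL if small[n] else DSC_GATE)) for n, d in dice.items()
        },
        "dsc_average": float(np.mean(list(dice.values()))),
        "dsc_average_gt_0p85": float(np.mean(list(dice.values()))) > DSC_GATE,
    }

    config_snapshot = {
        "phantom": _spec_to_config(spec),
        "registration": {
            "pyramid_levels": reg.pyramid_levels,
            "iterations_per_level": list(reg.iterations_per_level),
            "regularization_sigma_mm": reg.regularization_sigma_mm,
            "similarity": reg.similarity,
            "step_size": reg.step_size,
            "convergence_tol": reg.convergence_tol,
            "controlling_masks": [[fm.name, mm.name, w] for fm, mm, w in reg.controlling_masks],
            "focus_mask": reg.focus_mask.name if reg.focus_mask is not None else None,
        },
        "plan": {
            "prescription_gyrbe": rx,
            "beams": [dataclasses.asdict(b) for b in plan],
        },
        "criteria": dataclasses.asdict(criteria),
        "seed": seed,
        "target_roi": target_roi,
    }

    hashes = {
        "ref_ct": _hash_volume(case.ref_ct),
        "verif_ct": _hash_volume(case.verif_ct),
        "sct": _hash_volume(sct),
        "dose_vct": _hash_volume(dose_vct.volume),
        "dose_sct": _hash_volume(dose_sct.volume),
    }

    report = QAReport(
        case_id=case_id,
        registration=registration_summary,
        tre=tre_dict,
        dice=dice,
        gamma=gamma_dict,
        dvh=dvh,
        replan=replan,
        gates=gates,
        config_snapshot=config_snapshot,
        volume_hashes=hashes,
    )

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_volume(case.ref_ct, os.path.join(out_dir, "ref_ct.nii.gz"))
        write_volume(case.ref_mri, os.path.join(out_dir, "ref_mri.nii.gz"))
        write_volume(case.verif_ct, os.path.join(out_dir, "verif_ct.nii.gz"))
        write_volume(case.verif_mri, os.path.join(out_dir, "verif_mri.nii.gz"))
        write_volume(sct, os.path.join(out_dir, "sct.nii.gz"))
        write_volume(dose_vct.volume, os.path.join(out_dir, "dose_vct.nii.gz"))
        write_volume(dose_sct.volume, os.path.join(out_dir, "dose_sct.nii.gz"))
        write_landmarks(case.landmarks_ref, os.path.join(out_dir, "landmarks_ref.txt"))
        write_landmarks(case.landmarks_verif, os.path.join(out_dir, "landmarks_verif.txt"))
        report.to_json(os.path.join(out_dir, "report.json"))
        try:
            save_overlay_png(sct, case.verif_ct, os.path.join(out_dir, "sct_vs_vct.png"))
        except Exception as exc:  # plotting is best-effort
            log.warning("overlay rendering skipped: %s", exc)

    log.info("validation suite finished in %.1f s", time.time() - t0)
    return report


def save_overlay_png(a: ImageVolume, b: ImageVolume, path) -> None:
    """Orthogonal mid-slice difference overlays of two volumes on one grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diff = a.voxels.astype(float) - b.voxels.astype(float)
    cx, cy, cz = (n // 2 for n in a.grid.shape)
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, sl, title in (
        (axes[0], diff[cx, :, :], "sagittal"),
        (axes[1], diff[:, cy, :], "coronal"),
        (axes[2], diff[:, :, cz], "transversal"),
    ):
        im = ax.imshow(sl.T, origin="lower", cmap="RdBu_r", vmin=-200, vmax=200)
        ax.set_title(title)
        ax.axis("off")
    fig.colorbar(im, ax=axes, label="difference")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


# -- config files -------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _spec_to_config(spec: PhantomSpec) -> dict:
    return {
        "ct_shape": list(spec.ct_grid.shape),
        "ct_spacing": list(spec.ct_grid.spacing),
        "mri_shape": list(spec.mri_grid.shape),
        "mri_spacing": list(spec.mri_grid.spacing),
        "smoothing_sigma_mm": spec.smoothing_sigma_mm,
        "mri_axis_scale": spec.mri_axis_scale,
        "tumor_name": spec.tumor_name,
        "tumor_axis_reduction_mm": list(spec.tumor_axis_reduction_mm),
        "ellipsoids": [
            {
                "name": e.name,
                "center": list(e.center),
                "semi_axes": list(e.semi_axes),
                "ct_value": e.ct_value,
                "mri_value": e.mri_value,
            }
            for e in spec.ellipsoids
        ],
    }


def spec_from_config(cfg: dict) -> PhantomSpec:
    """Build a PhantomSpec from a config mapping; missing keys take the
    default study phantom's values."""
    base = default_phantom_spec()
    if cfg is None:
        return base
    ells = base.ellipsoids
    if "ellipsoids" in cfg:
        ells = tuple(
            EllipsoidSpec(
                name=e["name"],
                center=tuple(e["center"]),
                semi_axes=tuple(e["semi_axes"]),
                ct_value=float(e["ct_value"]),
                mri_value=float(e["mri_value"]),
            )
            for e in cfg["ellipsoids"]
        )
    ct_grid = base.ct_grid
    if "ct_shape" in cfg or "ct_spacing" in cfg:
        ct_grid = Grid3.centered(
            cfg.get("ct_shape", list(base.ct_grid.shape)),
            cfg.get("ct_spacing", list(base.ct_grid.spacing)),
        )
    mri_grid = base.mri_grid
    if "mri_shape" in cfg or "mri_spacing" in cfg:
        mri_grid = Grid3.centered(
            cfg.get("mri_shape", list(base.mri_grid.shape)),
            cfg.get("mri_spacing", list(base.mri_grid.spacing)),
        )
    return PhantomSpec(
        ellipsoids=ells,
        ct_grid=ct_grid,
        mri_grid=mri_grid,
        smoothing_sigma_mm=float(cfg.get("smoothing_sigma_mm", base.smoothing_sigma_mm)),
        mri_axis_scale=float(cfg.get("mri_axis_scale", base.mri_axis_scale)),
        tumor_name=cfg.get("tumor_name", base.tumor_name),
        tumor_axis_reduction_mm=tuple(
            cfg.get("tumor_axis_reduction_mm", base.tumor_axis_reduction_mm)
        ),
        noise_sigma=float(cfg.get("noise_sigma", 0.0)),
        noise_seed=cfg.get("noise_seed"),
    )


def params_from_config(cfg: dict | None) -> RegistrationParams:
    if not cfg:
        return RegistrationParams()
    kwargs = {
        k: cfg[k]
        for k in (
            "pyramid_levels", "iterations_per_level", "regularization_sigma_mm",
            "similarity", "step_size", "convergence_tol",
        )
        if k in cfg
    }
    if "iterations_per_level" in kwargs:
        kwargs["iterations_per_level"] = tuple(kwargs["iterations_per_level"])
    return RegistrationParams(**kwargs)


def plan_from_config(cfg: dict | None) -> tuple[list[BeamSpec], float]:
    if not cfg:
        spec = default_phantom_spec()
        return default_plan(spec)
    beams = [
        BeamSpec(
            direction=tuple(b["direction"]),
            isocenter=tuple(b["isocenter"]),
            range_mm_wet=float(b["range_mm_wet"]),
            peak_sigma_mm=float(b.get("peak_sigma_mm", 5.0)),
            lateral_sigma_mm=float(b.get("lateral_sigma_mm", 10.0)),
            plateau_fraction=float(b.get("plateau_fraction", 0.3)),
            weight=float(b.get("weight", 1.0)),
        )
        for b in cfg["beams"]
    ]
    return beams, float(cfg.get("prescription_gyrbe", 54.0))


def criteria_from_config(cfg: dict | None) -> GammaCriteria:
    if not cfg:
        return GammaCriteria()
    return GammaCriteria(
        dose_diff_pct=float(cfg.get("dose_diff_pct", 2.0)),
        dta_mm=float(cfg.get("dta_mm", 2.0)),
        threshold_pct=float(cfg.get("threshold_pct", 5.0)),
        normalization=cfg.get("normalization", "prescription"),
    )
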