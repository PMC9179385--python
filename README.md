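# synthct

MRI-driven synthetic-CT generation for adaptive proton therapy, with a full
desk-scale validation stack on digital phantoms.

## The problem

Proton dose distributions are exquisitely sensitive to anatomy: tumor
shrinkage, weight loss or oedema along a beam path shifts the Bragg peak and
can degrade target coverage or spill dose into organs at risk. Verifying the
anatomy mid-treatment with repeat X-ray CTs adds radiation exposure — a real
concern for pediatric patients. MRI is exposure-free, but treatment planning
needs CT numbers.

`synthct` implements the deformation-transfer answer: capture the anatomical
change with a **deformable image registration (DIR)** between the reference
MRI and a verification MRI, adapt the resulting **displacement vector field
(DVF)** to the frame and grid of the planning CT, and warp the planning CT
into a **synthetic CT (sCT)** that shows the current anatomy. Dose
recomputed on the sCT then drives a replanning decision — a new CT is
indicated when V95 of the target drops by ≥ 5 percentage points.

The package is aimed at medical-physics and image-analysis developers who
need a transparent, fully scriptable reference implementation of this
workflow and of its QA metrics, exercised entirely on synthetic data (no
patient data is required or included).

## What is inside

| Module | Contents |
| --- | --- |
| `synthct.core_images` | `Grid3`/`ImageVolume`/`ROIMask`/`LandmarkSet`, NIfTI + MetaImage I/O, world-mm resampling |
| `synthct.phantoms` | Paired CT/MRI 3D Shepp–Logan-type phantoms: T1-like intensities, +1% MRI axis distortion, anisotropic MRI grid, tumor shrinkage (13–36% / 4–9 mm per axis), ROI masks, landmarks |
| `synthct.registration` | Rigid pre-alignment (mutual information / mean squares) and multi-resolution symmetric-demons DIR with controlling-ROI and focus-ROI support |
| `synthct.deformation` | DVF resampling, rigid frame conjugation `d'(y) = R⁻¹ d(Ry + t)`, pull-back warping, sCT assembly |
| `synthct.dose_toy` | Analytic proton pencil-beam model: WEPL ray tracing + Gaussian Bragg peak (non-clinical, for exercising the dose-QA chain) |
| `synthct.metrics` | Landmark TRE, Dice, global 3D gamma index (2 mm/2%, 5% threshold), DVH statistics (Dmean, Dmax, Dx%, Dxcc, Vx%), V95 replan trigger |
| `synthct.workflow` | End-to-end validation suite with a versioned JSON QA report |
| `synthct.cli` | `synthct phantom | register | sct | dose | compare | validate` |

The key formulas, in the field's standard notation:

- **DSC** = 2|A∩B| / (|A| + |B|) for propagated vs ground-truth contours.
- **TRE** = ‖(x + d(x)) − y‖ per landmark pair (x, y), reported as mean/RMSE/max.
- **gamma** (global): γ(x) = min over r of √(ΔD²/dd² + ‖r − x‖²/dta²), with
  ΔD in % of prescription; pass = γ ≤ 1 among voxels above the dose threshold.
- **Vp%** = fraction of a structure receiving ≥ p% of the prescription;
  **Dx%** = minimum dose to the hottest x% of it.

## Worked example

Run the validation pipeline on a half-resolution (64³ / 2 mm) variant of the
default phantom — reference and verification CT+MRI are generated, the sCT
is synthesized via rigid link + MRI↔MRI DIR + DVF transfer, dose is computed
on all three CTs with the same spread-out-Bragg-peak plan, and all QA
metrics are evaluated:

```python
from synthct import run_validation_suite
from synthct.phantoms import default_phantom_spec

spec = default_phantom_spec(ct_shape=(64, 64, 64), ct_spacing=(2, 2, 2),
                            mri_spacing=(1.6, 1.6, 2.0))
report = run_validation_suite(spec=spec, case_id="demo")
print("average DSC :", round(report.gates["dsc_average"], 3))
print("tumor DSC   :", round(report.dice["tumor"], 3))
print("TRE mean/max:", round(report.tre["mean_mm"], 2), "/",
      round(report.tre["max_mm"], 2), "mm")
print("gamma pass  :", round(report.gamma["pass_rate_pct"], 1), "%")
print(report.replan["report"])
```

prints

```
average DSC : 0.986
tumor DSC   : 0.909
TRE mean/max: 0.48 / 0.86 mm
gamma pass  : 100.0 %
V95[tumor]: reference 100.0% -> synthetic CT 100.0% (drop 0.0 pp) => no replanning indicated
```

Reading: every static ROI is propagated essentially perfectly; the shrinking
tumor (4–9 mm of boundary motion, 57% volume loss) is recovered with DSC
0.91 at this half resolution (0.95 at the full 1 mm study resolution);
landmark registration error stays well below the 3 mm gate; and because the
tumor barely perturbs proton stopping power here, the vCT-vs-sCT dose
comparison passes gamma everywhere and no replan is indicated.

The same run from the shell:

```sh
synthct validate --defaults --out validation_out/   # full 128³ study phantom
```

which writes the volumes, a difference overlay PNG and `report.json`.

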