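"""Minimal analytic proton pencil-beam dose model.

Water-equivalent ray tracing through the CT plus a Gaussian-peak Bragg depth
dose and a Gaussian lateral profile.  This is deliberately a *toy* engine —
a two-segment HU-to-stopping-power lookup and an analytic peak instead of a
Monte Carlo transport — sufficient to make dose distributions respond to
anatomy (range shifts with upstream density changes) so the gamma/DVH chain
can be exercised end-to-end on phantoms.  Not for clinical use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_images import Grid3, ImageVolume, Modality

__all__ = ["BeamSpec", "DoseGrid", "hu_to_rsp", "wepl_along_ray", "compute_dose"]


@dataclass(frozen=True)
class BeamSpec:
    """One pencil-beam bundle: direction, isocenter and Bragg-curve shape."""

    direction: tuple[float, float, float]
    isocenter: tuple[float, float, float]
    range_mm_wet: float
    peak_sigma_mm: float = 5.0
    lateral_sigma_mm: float = 10.0
    plateau_fraction: float = 0.3
    weight: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("beam direction must be unit-norm")
        if self.range_mm_wet <= 0 or self.peak_sigma_mm <= 0 or self.lateral_sigma_mm <= 0:
            raise ValueError("range and sigmas must be positive")
        if not (0.0 < self.plateau_fraction < 1.0):
            raise ValueError("plateau_fraction must be in (0, 1)")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(eq=False)
class DoseGrid:
    """Dose distribution (GyRBE) with its prescription level."""

    volume: ImageVolume
    prescription_gyrbe: float

    def __post_init__(self):
        if self.volume.modality is not Modality.DOSE_GYRBE:
            raise ValueError("DoseGrid volume must have DOSE_GYRBE modality")
        if self.prescription_gyrbe <= 0:
            raise ValueError("prescription must be > 0")

    @property
    def grid(self) -> Grid3:
        return self.volume.grid

    @property
    def voxels(self) -> np.ndarray:
        return self.volume.voxels


def hu_to_rsp(hu):
    """Two-segment toy HU -> relative-stopping-power calibration (non-clinical).

    RSP = max(0.001, 1 + HU/1000) for HU <= 100, and 1.1 + 0.0005*(HU - 100)
    above; monotone, water (0 HU) -> 1.0, air (-1000 HU) -> 0.001 floor.
    """
    hu = np.asarray(hu, dtype=float)
    rsp = np.where(hu <= 100.0, np.maximum(0.001, 1.0 + hu / 1000.0),
                   1.1 + 0.0005 * (hu - 100.0))
    return rsp if rsp.ndim else float(rsp)


def _sample_hu(ct: ImageVolume, pts: np.ndarray) -> np.ndarray:
    idx = ct.grid.world_to_index(pts)
    return ndimage.map_coordinates(
        ct.voxels.astype(float), np.moveaxis(idx, -1, 0), order=1,
        mode="constant", cval=-1000.0,
    )


def wepl_along_ray(ct: ImageVolume, entry, direction, point) -> float:
    """Water-equivalent path length from ``entry`` to ``point`` along a ray (mm-WET).

    Uniform fine sampling (step <= 0.5 * min spacing) of RSP(HU) along the
    segment; ``point`` must lie on the ray, not behind the entry.
    """
    entry = np.asarray(entry, dtype=float)
    direction = np.asarray(direction, dtype=float)
    point = np.asarray(point, dtype=float)
    length = float((point - entry) @ direction)
    if length < -1e-9:
        raise ValueError("point lies behind the entry along the beam direction")
    if length <= 0:
        return 0.0
    step = 0.5 * min(ct.grid.spacing)
    n = max(2, int(np.ceil(length / step)) + 1)
    s = np.linspace(0.0, length, n)
    pts = entry[None, :] + s[:, None] * direction[None, :]
    rsp = hu_to_rsp(_sample_hu(ct, pts))
    return float(np.trapezoid(rsp, s))


def _beam_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


def compute_dose(ct: ImageVolume, beams: list[BeamSpec], grid: Grid3,
                 prescription_gyrbe: float = 1.0) -> DoseGrid:
    """Analytic dose on ``grid`` from the beam list traced through ``ct``.

    Per beam and voxel: depth dose ``plateau + (1 - plateau) *
    exp(-(wepl - range)^2 / (2 peak_sigma^2))`` for ``wepl <= range + 3
    peak_sigma`` (zero beyond), times a Gaussian of the lateral distance to the
    beam axis, times the beam weight.  The native on-axis Bragg peak of a
    unit-weight beam in water is 1 and the summed distribution is multiplied
    by the prescription — beam weights are fractions of the prescription
    delivered at the native peak, so a spread-out peak is built by choosing
    weights that sum to ~1 over the staggered ranges.  Deterministic.
    """
    if not beams:
        raise ValueError("beam list must be non-empty")
    if ct.modality is not Modality.CT_HU:
        raise ValueError("dose computation requires a CT_HU volume")

    X = grid.voxel_centers()  # (nx, ny, nz, 3)
    total = np.zeros(grid.shape)
    corners_idx = np.array(
        [[i, j, k] for i in (0, grid.shape[0] - 1)
         for j in (0, grid.shape[1] - 1) for k in (0, grid.shape[2] - 1)]
    )
    corners = grid.index_to_world(corners_idx)

    for beam in beams:
        e3 = np.asarray(beam.direction, dtype=float)
        iso = np.asarray(beam.isocenter, dtype=float)
        u, v = _beam_frame(e3)

        rel_c = corners - iso
        s_c, u_c, v_c = rel_c @ e3, rel_c @ u, rel_c @ v
        s0 = float(s_c.min()) - 1.0  # entry plane just upstream of the volume

        h = 0.5 * min(ct.grid.spacing)
        n_s = int(np.ceil((s_c.max() - s0) / h)) + 2
        lat_step = min(ct.grid.spacing)
        u_lo, u_hi = float(u_c.min()) - 1.0, float(u_c.max()) + 1.0
        v_lo, v_hi = float(v_c.min()) - 1.0, float(v_c.max()) + 1.0
        n_u = int(np.ceil((u_hi - u_lo) / lat_step)) + 2
        n_v = int(np.ceil((v_hi - v_lo) / lat_step)) + 2

        s_ax = s0 + h * np.arange(n_s)
        u_ax = u_lo + lat_step * np.arange(n_u)
        v_ax = v_lo + lat_step * np.arange(n_v)
        S, U, V = np.meshgrid(s_ax, u_ax, v_ax, indexing="ij")
        pts = iso + S[..., None] * e3 + U[..., None] * u + V[..., None] * v
        rsp = hu_to_rsp(_sample_hu(ct, pts))
        # cumulative trapezoid along depth -> WEPL(s, u, v)
        wepl = np.zeros_like(rsp)
        wepl[1:] = np.cumsum(0.5 * (rsp[1:] + rsp[:-1]) * h, axis=0)

        rel = X - iso
        s_x = rel @ e3
        u_x = rel @ u
        v_x = rel @ v
        coords = np.stack(
            [(s_x - s0) / h, (u_x - u_lo) / lat_step, (v_x - v_lo) / lat_step], axis=0
        )
        w_x = ndimage.map_coordinates(wepl, coords, order=1, mode="nearest")

        depth = beam.plateau_fraction + (1.0 - beam.plateau_fraction) * np.exp(
            -((w_x - beam.range_mm_wet) ** 2) / (2.0 * beam.peak_sigma_mm**2)
        )
        depth = np.where(w_x <= beam.range_mm_wet + 3.0 * beam.peak_sigma_mm, depth, 0.0)
        lateral = np.exp(-(u_x**2 + v_x**2) / (2.0 * beam.lateral_sigma_mm**2))
        total += beam.weight * depth * lateral

    if sum(b.weight for b in beams) <= 0:
        raise ValueError("total beam weight must be positive")
    total *= prescription_gyrbe
    vol = ImageVolume(grid, total, Modality.DOSE_GYRBE)
    return DoseGrid(vol, prescription_gyrbe)
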