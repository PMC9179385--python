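"""Geometric image-volume model and standard-format I/O.

All geometry is expressed in world LPS millimetres.  Voxel indices are
0-based with the origin at the *center* of voxel (0, 0, 0); the world
position of index ``i`` is ``origin + orientation @ (i * spacing)``.
Arrays are stored in ``(x, y, z)`` index order with x fastest-varying,
normalised at read time so NIfTI and MetaImage inputs behave identically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Modality",
    "Grid3",
    "ImageVolume",
    "ROIMask",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "read_landmarks",
    "write_landmarks",
]

_ORTHO_TOL = 1e-6

# Physically neutral out-of-field fill values per modality.
DEFAULT_FILL = {"CT_HU": -1000.0, "MRI_AU": 0.0, "DOSE_GYRBE": 0.0, "LABEL": 0.0}


class Modality(str, enum.Enum):
    CT_HU = "CT_HU"
    MRI_AU = "MRI_AU"
    DOSE_GYRBE = "DOSE_GYRBE"
    LABEL = "LABEL"


@dataclass(frozen=True, eq=False)
class Grid3:
    """Regular 3D sampling grid: shape, spacing (mm), origin (mm), direction cosines."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        R = self.orientation
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("orientation must be a 3x3 orthonormal matrix")

    # -- coordinate transforms ------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        """3x3 matrix mapping index offsets to world offsets (columns = voxel steps)."""
        return self.orientation * np.asarray(self.spacing)

    def index_to_world(self, idx) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine.T + np.asarray(self.origin)

    def world_to_index(self, pts) -> np.ndarray:
        """Map world mm points, shape (..., 3), to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) @ np.linalg.inv(self.affine).T

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        ii = np.indices(self.shape, dtype=float)
        idx = np.stack([ii[0], ii[1], ii[2]], axis=-1)
        return self.index_to_world(idx)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "Grid3", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.orientation, other.orientation, atol=tol)
        )

    @classmethod
    def centered(cls, shape, spacing, orientation=None) -> "Grid3":
        """Grid whose world-center coincides with the world origin."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        R = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
        half = (np.asarray(shape) - 1) / 2.0 * np.asarray(spacing)
        origin = -(R @ half)
        return cls(shape, spacing, tuple(origin), R)


@dataclass(eq=False)
class ImageVolume:
    """Scalar 3D image (CT, MRI, dose or label) on a :class:`Grid3`."""

    grid: Grid3
    voxels: np.ndarray
    modality: Modality = Modality.CT_HU

    def __post_init__(self):
        self.modality = Modality(self.modality)
        self.voxels = np.asarray(self.voxels)
        if tuple(self.voxels.shape) != self.grid.shape:
            raise ValueError(
                f"voxel array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )
        if self.modality is Modality.CT_HU and not np.all(np.isfinite(self.voxels)):
            raise ValueError("CT volumes must be finite")
        if self.modality is Modality.DOSE_GYRBE and np.any(self.voxels < 0):
            raise ValueError("dose volumes must be non-negative")

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.grid, self.voxels.copy(), self.modality)


@dataclass(eq=False)
class ROIMask:
    """Binary region-of-interest mask on a :class:`Grid3`."""

    grid: Grid3
    voxels: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if tuple(self.voxels.shape) != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def volume_cc(self) -> float:
        return float(self.voxels.sum()) * self.grid.voxel_volume_mm3 / 1000.0

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.grid, self.voxels.astype(np.uint8), Modality.LABEL)


@dataclass
class LandmarkSet:
    """Labelled fiducial points in world mm."""

    labels: list[str]
    points: np.ndarray  # (N, 3) world mm

    def __post_init__(self):
        self.labels = list(self.labels)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("landmark labels must be unique")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def point(self, label: str) -> np.ndarray:
        return self.points[self.labels.index(label)]


# -- SimpleITK bridge ---------------------------------------------------------

def _to_sitk(vol: ImageVolume) -> sitk.Image:
    # internal (x, y, z) -> sitk array layout (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.grid.origin))
    img.SetDirection(tuple(vol.grid.orientation.flatten()))
    return img


def _from_sitk(img: sitk.Image, modality: Modality) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    grid = Grid3(
        shape=img.GetSize(),
        spacing=img.GetSpacing(),
        origin=img.GetOrigin(),
        orientation=np.asarray(img.GetDirection()).reshape(3, 3),
    )
    return ImageVolume(grid, arr, modality)


def read_volume(path, modality: Modality | str = Modality.CT_HU) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Geometry (spacing, origin, direction cosines) is taken from the header;
    the voxel array is normalised to the internal (x, y, z) axis order.
    """
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - message passthrough
        raise IOError(f"cannot read volume {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{path!r}: expected a 3D image, got {img.GetDimension()}D")
    return _from_sitk(img, Modality(modality))


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume; format chosen from the file extension."""
    try:
        sitk.WriteImage(_to_sitk(vol), str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot write volume {path!r}: {exc}") from exc


# -- resampling ---------------------------------------------------------------

def sample_at_world(vol: ImageVolume, points: np.ndarray, order: int = 1,
                    fill: float | None = None) -> np.ndarray:
    """Interpolate the volume at world-mm points of shape (..., 3)."""
    if fill is None:
        fill = DEFAULT_FILL[vol.modality.value]
    pts = np.asarray(points, dtype=float)
    idx = vol.grid.world_to_index(pts)
    coords = np.moveaxis(idx, -1, 0)
    out = ndimage.map_coordinates(
        vol.voxels.astype(float), coords, order=order, mode="constant", cval=float(fill)
    )
    return out


def resample_to_grid(vol: ImageVolume, target: Grid3, interp: str = "trilinear",
                     fill: float | None = None) -> ImageVolume:
    """Resample a volume onto ``target``; out-of-extent points take ``fill``."""
    if interp not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if vol.modality is Modality.LABEL and interp == "trilinear":
        raise ValueError("LABEL volumes must be resampled with nearest interpolation")
    if target.same_geometry(vol.grid):
        return ImageVolume(target, vol.voxels.copy(), vol.modality)
    order = 0 if interp == "nearest" else 1
    out = sample_at_world(vol, target.voxel_centers(), order=order, fill=fill)
    if vol.modality is Modality.LABEL:
        out = np.rint(out).astype(vol.voxels.dtype)
    return ImageVolume(target, out, vol.modality)


def resample_mask(mask: ROIMask, target: Grid3) -> ROIMask:
    """Nearest-neighbour resampling of a binary mask onto ``target``."""
    vol = resample_to_grid(mask.as_volume(), target, interp="nearest", fill=0.0)
    return ROIMask(target, vol.voxels, mask.name)


# -- landmark files -----------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Read a 4-column landmark text file: ``label x y z`` (mm), '#' comments."""
    labels, pts = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed landmark line: {line!r}")
            labels.append(parts[0])
            pts.append([float(v) for v in parts[1:4]])
    return LandmarkSet(labels, np.asarray(pts))


def write_landmarks(lms: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# label x_mm y_mm z_mm\n")
        for lab, p in zip(lms.labels, lms.points):
            fh.write(f"{lab} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
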