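"""Volume data model, I/O, resampling, HU→density conversion and image metrics.

All world coordinates are LPS millimetres.  A volume's ``origin`` is the world
position of the centre of voxel ``(0, 0, 0)``; arrays are indexed ``[i, j, k]``
with world position ``origin + orientation @ (spacing * (i, j, k))``.  After
:func:`resample_isotropic` a volume is axis-aligned (identity orientation).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import (
    DimensionalityError,
    EmptyMaskError,
    FormatError,
    GridMismatchError,
)

AIR_HU = -1000.0
WATER_HU = 0.0

#: Default two-segment piecewise-linear HU→density calibration.  The knots are
#: anchored at air (−1000 HU, 0.00121 g/cm³), water (0 HU, 1.000 g/cm³) and
#: dense bone (+1000 HU, 1.59 g/cm³); the table is a configurable stand-in for
#: a scanner-specific calibration and can be replaced from YAML/JSON.
DEFAULT_HU_DENSITY_TABLE = ((-1000.0, 0.00121), (0.0, 1.0), (1000.0, 1.59))


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class CTVolume:
    """A HU-valued 3D grid with physical metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Hounsfield units.
    spacing : tuple of float
        Voxel size (sx, sy, sz) in mm.
    origin : tuple of float
        World position (mm) of the centre of voxel (0, 0, 0).
    orientation : (3, 3) ndarray
        Direction cosines (columns = world directions of the index axes).
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"CTVolume requires a 3D array, got {self.values.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be 3x3")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-6):
            raise ValueError("orientation must be orthonormal")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTVolume values must be finite")

    # -- grid helpers ------------------------------------------------------

    @property
    def shape(self):
        return self.values.shape

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-4)
            and np.allclose(self.orientation, other.orientation, atol=1e-6)
        )

    def index_to_world(self, idx):
        """Map (n, 3) continuous voxel indices to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.orientation @ (idx * self.spacing).T).T + self.origin

    def world_to_index(self, pts):
        """Map (n, 3) world mm points to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (self.orientation.T @ (pts - self.origin).T).T / self.spacing

    def voxel_centres_world(self):
        """World coordinates of every voxel centre; three (nx,ny,nz) arrays."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        w = self.index_to_world(idx).reshape(self.shape + (3,))
        return w[..., 0], w[..., 1], w[..., 2]

    def sample_world(self, pts, order=1, cval=AIR_HU):
        """Interpolate the volume at world points (trilinear by default)."""
        idx = self.world_to_index(pts)
        return ndimage.map_coordinates(
            self.values.astype(np.float64, copy=False),
            idx.T,
            order=order,
            mode="constant",
            cval=cval,
        )

    def with_values(self, values):
        return replace(self, values=values)


@dataclass
class Mask:
    """Boolean voxel mask sharing its parent volume's grid."""

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise DimensionalityError("Mask requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)

    @property
    def shape(self):
        return self.values.shape

    @classmethod
    def like(cls, vol, values):
        values = np.asarray(values).astype(bool)
        if values.shape != vol.shape:
            raise GridMismatchError(
                f"mask shape {values.shape} != volume shape {vol.shape}"
            )
        return cls(values, vol.spacing, vol.origin, vol.orientation)

    def count(self) -> int:
        return int(self.values.sum())

    def same_grid(self, other) -> bool:
        return CTVolume.same_grid(self, other)

    # reuse coordinate helpers
    index_to_world = CTVolume.index_to_world
    world_to_index = CTVolume.world_to_index


@dataclass
class DensityVolume:
    """Physical density (g/cm³) on a CT grid."""

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if np.any(self.values < 0):
            raise ValueError("density must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    index_to_world = CTVolume.index_to_world
    world_to_index = CTVolume.world_to_index
    same_grid = CTVolume.same_grid


class RigidTransform:
    """Rigid world transform: ``x_fixed = R @ x_moving + t`` (LPS mm)."""

    def __init__(self, rotation=None, translation=(0.0, 0.0, 0.0)):
        self.rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
        self.translation = np.asarray(translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls):
        return cls()

    @classmethod
    def from_euler(cls, angles_deg, translation=(0, 0, 0), centre=(0, 0, 0)):
        """Euler XYZ rotation (deg) about ``centre``, then translation (mm)."""
        ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        r = rz @ ry @ rx
        centre = np.asarray(centre, dtype=float)
        t = np.asarray(translation, dtype=float) + centre - r @ centre
        return cls(r, t)

    def apply(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self):
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other):
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_dict(self):
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
            "convention": "moving->fixed, LPS mm",
        }

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["rotation"], float).reshape(3, 3), d["translation"])

    def __repr__(self):
        return f"RigidTransform(t={self.translation.round(3).tolist()})"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sitk_to_volume(img: sitk.Image) -> CTVolume:
    if img.GetDimension() != 3:
        raise DimensionalityError(f"expected a 3D image, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return CTVolume(values, img.GetSpacing(), img.GetOrigin(), direction)


def read_volume(path) -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - message varies
        raise FormatError(f"unreadable image file {path}: {exc}") from exc
    return _sitk_to_volume(img)


def write_volume(vol, path, dtype=None) -> None:
    """Write a CTVolume or Mask to disk (format from extension; NIfTI canonical).

    Masks are written as uint8; HU volumes as float32 unless ``dtype`` given.
    """
    path = os.fspath(path)
    if isinstance(vol, Mask):
        values = vol.values.astype(np.uint8)
    else:
        values = vol.values.astype(dtype or np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(np.asarray(vol.orientation, float).ravel()))
    try:
        sitk.WriteImage(img, path)
    except RuntimeError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_mask(path) -> Mask:
    v = read_volume(path)
    return Mask(v.values > 0, v.spacing, v.origin, v.orientation)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_isotropic(vol, spacing_mm=1.5, interpolation="trilinear", fill=AIR_HU):
    """Resample onto an axis-aligned isotropic grid covering the same extent.

    ``trilinear`` for HU/dose, ``nearest`` for masks.  The output origin is the
    minimum-corner voxel centre of the input's world bounding box.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    order = {"trilinear": 1, "nearest": 0}[interpolation]
    is_mask = isinstance(vol, Mask)
    values = vol.values.astype(np.float32) if is_mask else vol.values

    # world bounding box over the 8 corner voxel centres
    n = np.asarray(vol.shape)
    corners = np.array(
        [[i, j, k] for i in (0, n[0] - 1) for j in (0, n[1] - 1) for k in (0, n[2] - 1)]
    )
    w = CTVolume.index_to_world(vol, corners)
    lo, hi = w.min(axis=0), w.max(axis=0)
    dims = np.maximum(np.floor((hi - lo) / spacing_mm + 1e-9).astype(int) + 1, 1)

    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spacing_mm + lo
    idx = CTVolume.world_to_index(vol, pts)
    out = ndimage.map_coordinates(
        values.astype(np.float64, copy=False),
        idx.T,
        order=order,
        mode="constant",
        cval=0.0 if is_mask else fill,
    ).reshape(tuple(dims))

    spacing = (spacing_mm,) * 3
    if is_mask:
        return Mask(out > 0.5, spacing, tuple(lo), np.eye(3))
    return CTVolume(out.astype(np.float32), spacing, tuple(lo), np.eye(3))


# ---------------------------------------------------------------------------
# HU → density
# ---------------------------------------------------------------------------


class HUDensityCalibration:
    """Piecewise-linear HU→density calibration, clamped at the table ends."""

    def __init__(self, table=DEFAULT_HU_DENSITY_TABLE):
        table = sorted((float(h), float(d)) for h, d in table)
        self.hu = np.array([h for h, _ in table])
        self.density = np.array([d for _, d in table])
        if len(self.hu) < 2:
            raise ValueError("calibration table needs at least two knots")
        if np.any(np.diff(self.density) < 0):
            raise ValueError("calibration must be monotone non-decreasing")

    @classmethod
    def from_file(cls, path):
        import json

        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
        if isinstance(data, dict):
            data = data["table"]
        return cls(data)

    def __call__(self, hu):
        return np.interp(np.asarray(hu, dtype=float), self.hu, self.density)


def hu_to_density(hu, calibration: HUDensityCalibration | None = None):
    """Convert HU (scalar, array or CTVolume) to physical density (g/cm³)."""
    cal = calibration or HUDensityCalibration()
    if isinstance(hu, CTVolume):
        return DensityVolume(cal(hu.values), hu.spacing, hu.origin, hu.orientation)
    out = cal(hu)
    return float(out) if np.isscalar(hu) else out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def rms_hu_difference(a: CTVolume, b: CTVolume, mask: Mask) -> float:
    """Root-mean-square HU difference between two volumes over a mask."""
    if not (a.same_grid(b) and a.same_grid(mask)):
        raise GridMismatchError("a, b and mask must share one grid")
    m = mask.values
    if not m.any():
        raise EmptyMaskError("rms_hu_difference over an empty mask is undefined")
    d = a.values[m].astype(np.float64) - b.values[m].astype(np.float64)
    return float(np.sqrt(np.mean(d * d)))


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap of two masks on the same grid."""
    if a.shape != b.shape:
        raise GridMismatchError("masks must share a grid")
    inter = np.logical_and(a.values, b.values).sum()
    denom = a.values.sum() + b.values.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * inter / denom)


def _warn(msg):
    warnings.warn(msg, stacklevel=3)
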