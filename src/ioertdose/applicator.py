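"""Applicator geometry: the collimating tube and its 6-DOF pose.

An IOERT applicator is a rigid PMMA tube docked to the LINAC.  Its distal end
is cut by the *bevel plane* at ``bevel_angle`` to the tube cross-section so the
exit face can conform to tilted surfaces.  Conventions used throughout:

* ``axis`` is a unit vector pointing distally (into the tissue).
* ``bevel_centre`` is the centre of the elliptical exit face (on the axis).
* ``roll`` is the angular position (deg, about the axis) of the *shorter edge*
  (the most proximal rim point).  Parameterising a rim point at angle ``theta``
  about the axis, its axial offset from the bevel centre is
  ``s(theta) = -R * tan(bevel) * cos(theta - roll)``.
* The bevel-plane unit normal is ``m = cos(b)*axis + sin(b)*e(roll)`` with
  ``e(roll) = cos(roll)*u + sin(roll)*v`` for a deterministic transverse frame
  ``(u, v)``.  Points with ``(p - centre) . m > 0`` are distal (beam side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError


def transverse_frame(axis):
    """Deterministic right-handed orthonormal frame (u, v) ⟂ axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(a @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ a) * a
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return u, v


@dataclass
class ApplicatorSpec:
    """Physical applicator: aperture diameter (cm), bevel angle (deg), wall."""

    diameter_cm: float = 7.0
    bevel_angle_deg: float = 30.0
    wall_thickness_mm: float = 5.0
    tube_length_mm: float = 100.0
    wall_hu: float = 120.0

    def __post_init__(self):
        if self.diameter_cm <= 0:
            raise ValueError("diameter must be positive")
        if not (0.0 <= self.bevel_angle_deg <= 60.0):
            raise ValueError("bevel angle must be in [0, 60] deg")

    @property
    def inner_radius_mm(self) -> float:
        return self.diameter_cm * 10.0 / 2.0

    @property
    def outer_radius_mm(self) -> float:
        return self.inner_radius_mm + self.wall_thickness_mm


@dataclass
class ApplicatorPose:
    """6-DOF placement of the applicator (bevel centre, distal axis, roll)."""

    bevel_centre: np.ndarray
    axis: np.ndarray
    roll_deg: float = 0.0
    roll_undefined: bool = False
    fitted_diameter_mm: float | None = None

    def __post_init__(self):
        self.bevel_centre = np.asarray(self.bevel_centre, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise GeometryError("axis must be a nonzero vector")
        self.axis = self.axis / n
        self.roll_deg = float(self.roll_deg) % 360.0

    def frame(self):
        return transverse_frame(self.axis)

    def bevel_normal(self, spec: ApplicatorSpec):
        """Unit normal of the bevel plane, pointing distally."""
        b = np.deg2rad(spec.bevel_angle_deg)
        u, v = self.frame()
        r = np.deg2rad(self.roll_deg)
        e = np.cos(r) * u + np.sin(r) * v
        return np.cos(b) * self.axis + np.sin(b) * e

    def to_dict(self):
        return {
            "bevel_centre_mm": [float(x) for x in self.bevel_centre],
            "axis": [float(x) for x in self.axis],
            "roll_deg": float(self.roll_deg),
            "roll_undefined": bool(self.roll_undefined),
            "fitted_diameter_mm": (
                None if self.fitted_diameter_mm is None else float(self.fitted_diameter_mm)
            ),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            d["bevel_centre_mm"],
            d["axis"],
            d.get("roll_deg", 0.0),
            d.get("roll_undefined", False),
            d.get("fitted_diameter_mm"),
        )


def axis_coordinates(points, pose: ApplicatorPose):
    """Axial (s, distal positive) and radial (r) coords relative to the pose."""
    p = np.atleast_2d(np.asarray(points, dtype=float)) - pose.bevel_centre
    s = p @ pose.axis
    radial = p - np.outer(s, pose.axis)
    r = np.linalg.norm(radial, axis=1)
    return s, r


def signed_bevel_distance(points, pose: ApplicatorPose, spec: ApplicatorSpec):
    """Signed distance to the bevel plane (positive = distal/beam side)."""
    m = pose.bevel_normal(spec)
    p = np.atleast_2d(np.asarray(points, dtype=float)) - pose.bevel_centre
    return p @ m


def axial_gap_distance(points, pose: ApplicatorPose, spec: ApplicatorSpec):
    """Distance from each point to the bevel plane *measured along the axis*.

    Positive distally.  This is the paper-style "distance from the applicator
    end" for air-gap depth reporting.
    """
    m = pose.bevel_normal(spec)
    denom = float(pose.axis @ m)
    p = np.atleast_2d(np.asarray(points, dtype=float)) - pose.bevel_centre
    return (p @ m) / denom
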