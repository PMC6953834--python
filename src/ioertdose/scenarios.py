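"""Construct the five CT volumes whose dose distributions are compared.

* ``intraCT`` — the intraoperative image (gold standard geometry), applicator
  interior blanked to air as a treatment planning system would.
* ``preCT`` — the registered preoperative image, interior blanked: includes
  tissue heterogeneity but not the air gap.
* ``preCT_water`` — the conventional assumption: patient tissue set to water
  and a flat water medium starting at the applicator end (no air gap).
* ``preCT_water_air`` — water-equivalent tissues plus the segmented air gap.
* ``preCT_air`` — the registered preoperative image plus the segmented air gap
  (heterogeneity and air gap).

HU edits follow the protocol constants: air = −1000 HU, water = 0 HU; the air
gap is applied after waterising, so gap voxels always end at −1000 HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .applicator import ApplicatorPose, ApplicatorSpec, signed_bevel_distance
from .core import AIR_HU, WATER_HU, CTVolume, Mask
from .errors import GridMismatchError

SCENARIO_NAMES = ("intraCT", "preCT_water", "preCT", "preCT_water_air", "preCT_air")


def blank_applicator_interior(vol: CTVolume, pose: ApplicatorPose,
                              spec: ApplicatorSpec) -> CTVolume:
    """Set voxels strictly inside the tube, proximal to the bevel plane, to air."""
    x, y, z = vol.voxel_centres_world()
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    d = pts - pose.bevel_centre
    s = d @ pose.axis
    r2 = np.einsum("ij,ij->i", d, d) - s * s
    plane = signed_bevel_distance(pts, pose, spec)
    interior = (
        (r2 < spec.inner_radius_mm**2) & (plane <= 0) & (s >= -spec.tube_length_mm)
    ).reshape(vol.shape)
    values = vol.values.astype(np.float32).copy()
    values[interior] = AIR_HU
    return vol.with_values(values)


def apply_air_gap(vol: CTVolume, gap: Mask) -> CTVolume:
    """Set the segmented air-gap voxels to the air value (−1000 HU)."""
    if vol.shape != gap.shape:
        raise GridMismatchError("gap mask must share the volume grid")
    values = vol.values.astype(np.float32).copy()
    values[gap.values] = AIR_HU
    return vol.with_values(values)


def waterize(vol: CTVolume, body: Mask) -> CTVolume:
    """Set patient-tissue voxels to the water value (0 HU)."""
    if vol.shape != body.shape:
        raise GridMismatchError("body mask must share the volume grid")
    values = vol.values.astype(np.float32).copy()
    values[body.values] = WATER_HU
    return vol.with_values(values)


def _flood_distal_water(vol: CTVolume, pose, spec) -> CTVolume:
    """Water half-space distal to the bevel plane (conventional assumption)."""
    x, y, z = vol.voxel_centres_world()
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    distal = (signed_bevel_distance(pts, pose, spec) > 0).reshape(vol.shape)
    values = vol.values.astype(np.float32).copy()
    values[distal] = WATER_HU
    return vol.with_values(values)


@dataclass
class ScenarioSet:
    """The five labelled CT volumes feeding the dose engine (shared grid)."""

    intraCT: CTVolume
    preCT_water: CTVolume
    preCT: CTVolume
    preCT_water_air: CTVolume
    preCT_air: CTVolume
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        for name in SCENARIO_NAMES:
            yield name, getattr(self, name)

    def comparisons(self):
        """Scenario names compared against the intraCT gold standard."""
        return SCENARIO_NAMES[1:]


def build_scenarios(intra: CTVolume, pre_registered: CTVolume, gap: Mask,
                    pose: ApplicatorPose, spec: ApplicatorSpec,
                    body_pre: Mask, provenance=None) -> ScenarioSet:
    """Assemble the five scenario volumes from the processed case inputs."""
    for other in (pre_registered,):
        if not intra.same_grid(other):
            raise GridMismatchError("intra and registered pre volumes must share a grid")
    if intra.shape != gap.shape or intra.shape != body_pre.shape:
        raise GridMismatchError("masks must share the common grid")

    intra_ct = blank_applicator_interior(intra, pose, spec)
    pre_ct = blank_applicator_interior(pre_registered, pose, spec)
    pre_water_base = waterize(pre_ct, body_pre)
    return ScenarioSet(
        intraCT=intra_ct,
        preCT_water=_flood_distal_water(pre_water_base, pose, spec),
        preCT=pre_ct,
        preCT_water_air=apply_air_gap(pre_water_base, gap),
        preCT_air=apply_air_gap(pre_ct, gap),
        provenance=dict(provenance or {}),
    )
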