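"""Region-growing segmentation of bone, air gap, applicator wall and body.

The interactive "manually delineated boundaries" step of the clinical workflow
is replaced by explicit constraint masks so every segmentation is reproducible.
HU windows: air gap grows below the −500 HU limit; bone above +200 HU; the PMMA
applicator wall within [60, 200] HU; patient tissue above −300 HU.  Only the
−500 HU air-gap limit is a protocol constant; the others are configurable
defaults.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .applicator import (
    ApplicatorPose,
    ApplicatorSpec,
    axial_gap_distance,
    signed_bevel_distance,
    transverse_frame,
)
from .core import CTVolume, Mask
from .errors import SeedError, SegmentationError

AIR_GAP_HU_MAX = -500.0
BONE_HU_MIN = 200.0
BODY_HU_MIN = -300.0
WALL_HU_WINDOW = (60.0, 200.0)


def _structure(connectivity):
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def region_grow(vol: CTVolume, seeds, hu_min=-np.inf, hu_max=np.inf,
                constraint: Mask | None = None, connectivity=6) -> Mask:
    """Maximal connected region containing the seeds within an HU window.

    Implemented as connected-component labelling of the thresholded volume,
    keeping the components that contain at least one seed; equivalent to (and
    tested against) an explicit flood fill, but deterministic and fast.
    """
    seeds = [tuple(int(i) for i in s) for s in np.atleast_2d(np.asarray(seeds))]
    if not seeds:
        raise SeedError("at least one seed is required")
    shape = vol.shape
    for s in seeds:
        if any(i < 0 or i >= n for i, n in zip(s, shape)):
            raise SeedError(f"seed {s} outside the volume")
        hu = float(vol.values[s])
        if not (hu_min <= hu <= hu_max):
            raise SeedError(f"seed {s} HU={hu:.1f} outside window [{hu_min}, {hu_max}]")
    window = (vol.values >= hu_min) & (vol.values <= hu_max)
    if constraint is not None:
        window &= constraint.values
    labels, _ = ndimage.label(window, structure=_structure(connectivity))
    wanted = {labels[s] for s in seeds} - {0}
    out = np.isin(labels, sorted(wanted)) if wanted else np.zeros(shape, dtype=bool)
    return Mask.like(vol, out)


def _auto_bone_seeds(vol, hu_strong=500.0):
    strong = vol.values >= hu_strong
    if not strong.any():
        raise SegmentationError("no high-HU voxels to seed bone segmentation")
    labels, n = ndimage.label(strong, structure=_structure(6))
    seeds = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        seeds.append(tuple(idx[len(idx) // 2]))
    return seeds


def segment_bone(vol: CTVolume, seeds=None, constraint: Mask | None = None,
                 hu_min=BONE_HU_MIN) -> Mask:
    """Bone = region growing above ``hu_min`` HU plus 1-voxel closing."""
    if seeds is None:
        seeds = _auto_bone_seeds(vol)
    grown = region_grow(vol, seeds, hu_min=hu_min, constraint=constraint)
    closed = ndimage.binary_closing(grown.values, structure=_structure(6))
    closed |= grown.values  # closing must never lose voxels at the border
    if not closed.any():
        raise SegmentationError("bone segmentation is empty")
    return Mask.like(vol, closed)


def _gap_region(vol, pose, spec, max_extension_mm):
    """Distal extension of the applicator's inner cylinder (world predicate)."""
    x, y, z = vol.voxel_centres_world()
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    d = pts - pose.bevel_centre
    s = d @ pose.axis
    r2 = np.einsum("ij,ij->i", d, d) - s * s
    plane = signed_bevel_distance(pts, pose, spec)
    region = (
        (r2 < spec.inner_radius_mm**2)
        & (plane > 0)
        & (s <= max_extension_mm + spec.inner_radius_mm * np.tan(np.deg2rad(spec.bevel_angle_deg)))
    )
    return region.reshape(vol.shape)


def segment_air_gap(vol: CTVolume, pose: ApplicatorPose, spec: ApplicatorSpec,
                    constraint: Mask | None = None, hu_max=AIR_GAP_HU_MAX,
                    max_extension_mm=80.0) -> Mask:
    """Air gap between the applicator's exit face and the irradiation surface.

    Region growing below the −500 HU limit, seeded just distal to the bevel
    plane inside the aperture and constrained to the longitudinal extension of
    the applicator.  An empty result is a valid zero gap.
    """
    region = _gap_region(vol, pose, spec, max_extension_mm)
    if constraint is not None:
        region &= constraint.values
    window = (vol.values <= hu_max) & region

    # seed disc just distal to the bevel plane
    u, v = pose.frame()
    beta = np.tan(np.deg2rad(spec.bevel_angle_deg))
    rollr = np.deg2rad(pose.roll_deg)
    step = max(min(vol.spacing), spec.inner_radius_mm / 6.0)
    offs = np.arange(-spec.inner_radius_mm, spec.inner_radius_mm + step, step)
    uu, vv = np.meshgrid(offs, offs, indexing="ij")
    keep = (uu**2 + vv**2) <= (0.85 * spec.inner_radius_mm) ** 2
    uf, vf = uu[keep], vv[keep]
    delta = 1.5 * min(vol.spacing)
    s_seed = -beta * (uf * np.cos(rollr) + vf * np.sin(rollr)) + delta
    pts = pose.bevel_centre + uf[:, None] * u + vf[:, None] * v + s_seed[:, None] * pose.axis
    idx = np.round(vol.world_to_index(pts)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
    idx = idx[inside]
    seeds = [tuple(i) for i in idx if window[tuple(i)]]
    if not seeds:
        return Mask.like(vol, np.zeros(vol.shape, dtype=bool))
    seeds = list(dict.fromkeys(seeds))
    labels, _ = ndimage.label(window, structure=_structure(6))
    wanted = {labels[s] for s in seeds} - {0}
    out = np.isin(labels, sorted(wanted))
    return Mask.like(vol, out)


def segment_applicator_wall(vol: CTVolume, approx_axis_hint, spec: ApplicatorSpec,
                            hu_window=WALL_HU_WINDOW, tube_margin_mm=15.0,
                            opening_iterations=1) -> Mask:
    """PMMA wall segmentation in a HU window near an approximate axis.

    ``approx_axis_hint`` is ``(point_mm, direction)`` — a rough axis guess (a
    generous tube neighbourhood of ±``tube_margin_mm`` around the nominal radii
    absorbs several mm of hint error).  A one-iteration binary opening removes
    isolated noise voxels that fall into the PMMA HU window.
    """
    point, direction = approx_axis_hint
    point = np.asarray(point, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    x, y, z = vol.voxel_centres_world()
    dx, dy, dz = x - point[0], y - point[1], z - point[2]
    s = dx * direction[0] + dy * direction[1] + dz * direction[2]
    r2 = (dx - s * direction[0]) ** 2 + (dy - s * direction[1]) ** 2 + (dz - s * direction[2]) ** 2
    lo = max(0.0, spec.inner_radius_mm - tube_margin_mm)
    hi = spec.outer_radius_mm + tube_margin_mm
    neighbourhood = (r2 >= lo**2) & (r2 <= hi**2)
    window = (vol.values >= hu_window[0]) & (vol.values <= hu_window[1]) & neighbourhood
    if opening_iterations:
        window = ndimage.binary_opening(
            window, structure=_structure(6), iterations=opening_iterations
        )
    labels, n = ndimage.label(window, structure=_structure(26))
    if n == 0:
        raise SegmentationError("no applicator wall found in the HU window")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    wall = labels == int(np.argmax(counts))

    # fragmentary-wall check against the analytic shell volume
    ss = s[wall]
    axial_extent = float(ss.max() - ss.min()) if ss.size else 0.0
    shell_mm3 = np.pi * (spec.outer_radius_mm**2 - spec.inner_radius_mm**2) * max(axial_extent, 1e-9)
    voxel_mm3 = float(np.prod(vol.spacing))
    if wall.sum() * voxel_mm3 < 0.5 * shell_mm3 or axial_extent < spec.inner_radius_mm:
        raise SegmentationError(
            f"applicator wall fragmentary: {wall.sum()} voxels over {axial_extent:.1f} mm"
        )
    return Mask.like(vol, wall)


def body_mask(vol: CTVolume, exclude: Mask | None = None, threshold=BODY_HU_MIN) -> Mask:
    """Patient tissue: HU >= threshold, largest component, holes filled.

    ``exclude`` (typically the applicator wall, which shares the soft-tissue HU
    range) is subtracted after hole filling.
    """
    thresholded = vol.values >= threshold
    labels, n = ndimage.label(thresholded, structure=_structure(26))
    if n == 0:
        raise SegmentationError("no voxel above the body threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    body = labels == int(np.argmax(counts))
    body = ndimage.binary_fill_holes(body)
    if exclude is not None:
        body &= ~exclude.values
    if not body.any():
        raise SegmentationError("body mask is empty")
    return Mask.like(vol, body)


def max_air_gap_distance(gap: Mask, pose: ApplicatorPose, spec: ApplicatorSpec) -> float:
    """Maximum distance (mm) from the applicator end to the irradiation surface.

    Measured per gap voxel as the signed distance from the bevel plane along the
    applicator axis (distal positive); 0 for an empty gap.
    """
    idx = np.argwhere(gap.values)
    if idx.size == 0:
        return 0.0
    pts = Mask.index_to_world(gap, idx)
    d = axial_gap_distance(pts, pose, spec)
    return float(d.max())
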