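"""Synthetic paired pre/intraoperative CT phantoms with known ground truth.

The generator emulates the imaging conditions of an IOERT case: a torso-like
soft-tissue body (ellipsoid) with bone structures near — but not inside — the
treatment volume, a post-resection tumour-bed cavity with an irregular surface
carved into the intraoperative image, a PMMA applicator at a configurable pose
standing off the tumour bed to create an air gap of known maximum axial extent,
a rigid inter-acquisition motion between the two studies, and additive Gaussian
HU noise.  Every random element is derived from a single seed, so a
``PhantomConfig`` maps to bitwise-reproducible volumes.

The cavity surface is a spherical-cap base plus a sum of seeded 2D Gaussian
bumps; the surface function is kept on the truth object so tests can recompute
the maximum air-gap depth independently of the voxel rasterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .applicator import (
    ApplicatorPose,
    ApplicatorSpec,
    signed_bevel_distance,
    transverse_frame,
)
from .core import AIR_HU, CTVolume, Mask, RigidTransform
from .errors import GeometryError

SOFT_TISSUE_HU = 40.0
BONE_HU = 900.0
PMMA_HU = 120.0
FLUID_HU = 10.0


# ---------------------------------------------------------------------------
# cavity surface model
# ---------------------------------------------------------------------------


@dataclass
class CavityField:
    """Tumour-bed depth function: spherical-cap base + seeded Gaussian bumps.

    ``depth(u, v)`` is the resection depth (mm, >= 0) below the original body
    surface at transverse cavity coordinates (u, v); it is zero outside the
    cavity radius.  The closed form makes the maximum cavity depth — and hence
    the maximum air gap — independently recomputable.
    """

    radius_mm: float
    base_depth_mm: float
    amplitude_mm: float
    bump_centres: np.ndarray  # (n, 2)
    bump_widths: np.ndarray  # (n,)
    bump_amps: np.ndarray  # (n,), in [-amplitude, amplitude]

    @classmethod
    def generate(cls, radius_mm, base_depth_mm, amplitude_mm, rng, n_bumps=6,
                 bump_width_mm=14.0):
        rho = radius_mm * 0.6 * np.sqrt(rng.uniform(0, 1, n_bumps))
        ang = rng.uniform(0, 2 * np.pi, n_bumps)
        centres = np.stack([rho * np.cos(ang), rho * np.sin(ang)], axis=1)
        widths = bump_width_mm * rng.uniform(0.7, 1.3, n_bumps)
        amps = amplitude_mm * rng.uniform(-1.0, 1.0, n_bumps)
        return cls(radius_mm, base_depth_mm, amplitude_mm, centres, widths, amps)

    def depth(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        rho2 = (u * u + v * v) / (self.radius_mm**2)
        taper = np.sqrt(np.clip(1.0 - rho2, 0.0, None))
        bumps = np.zeros_like(taper)
        for (cu, cv), w, a in zip(self.bump_centres, self.bump_widths, self.bump_amps):
            d2 = (u - cu) ** 2 + (v - cv) ** 2
            bumps += a * np.exp(-d2 / (2.0 * w * w))
        return np.clip(taper * (self.base_depth_mm + bumps), 0.0, None)

    def max_depth(self, step_mm=0.25):
        """Maximum depth over a fine transverse grid (the surface oracle)."""
        g = np.arange(-self.radius_mm, self.radius_mm + step_mm, step_mm)
        uu, vv = np.meshgrid(g, g, indexing="ij")
        return float(self.depth(uu, vv).max())


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Conditions for one synthetic IOERT case.

    Defaults mirror an intraoperative chondrosarcoma-like setting: a 7 cm,
    30-degree-bevel applicator at 1.5 mm isotropic CT resolution, soft tissue at
    40 HU with ~900 HU bone structures flanking (but outside) the beam, a
    ~22 mm deep tumour-bed cavity with 8 mm surface irregularity, a 14.5 mm
    maximum air gap (the middle of the observed 8.5-30.5 mm range), a small
    rigid inter-acquisition motion and 15 HU Gaussian noise.
    """

    shape: tuple = (96, 96, 144)
    spacing_mm: tuple = (1.5, 1.5, 1.5)
    body_half_axes_mm: tuple = (62.0, 58.0, 64.0)
    body_centre_mm: tuple | None = None  # default: volume centre xy, deep z
    soft_tissue_hu: float = SOFT_TISSUE_HU
    bone_hu: float = BONE_HU
    bones: tuple | None = None  # default layout built in generate_phantom
    low_density_hu: float | None = None
    low_density_centre_mm: tuple | None = None
    low_density_radius_mm: float = 15.0

    cavity_radius_mm: float | None = None  # default: aperture radius + 3 mm
    cavity_depth_mm: float = 22.0
    cavity_irregularity_mm: float = 8.0
    n_bumps: int = 6
    bump_width_mm: float = 14.0
    fluid_depth_mm: float | None = None

    spec: ApplicatorSpec = field(default_factory=ApplicatorSpec)
    applicator_tilt_deg: tuple = (0.0, 0.0)  # rotations of the axis about x, y
    applicator_roll_deg: float = 40.0
    applicator_offset_mm: tuple = (0.0, 0.0)  # lateral offset of the axis
    target_max_gap_mm: float = 14.5

    motion_rotation_deg: tuple = (2.0, -3.0, 2.0)
    motion_translation_mm: tuple = (4.0, -3.0, 5.0)
    noise_sigma_hu: float = 15.0
    seed: int = 0

    def grid_extent_mm(self):
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def resolved_body_centre(self):
        if self.body_centre_mm is not None:
            return np.asarray(self.body_centre_mm, dtype=float)
        ex, ey, ez = self.grid_extent_mm()
        return np.array([ex / 2.0, ey / 2.0, 0.62 * ez])

    def resolved_cavity_radius(self):
        if self.cavity_radius_mm is not None:
            return float(self.cavity_radius_mm)
        return self.spec.inner_radius_mm + 3.0

    def applicator_axis(self):
        tx, ty = np.deg2rad(np.asarray(self.applicator_tilt_deg, dtype=float))
        a = np.array([0.0, 0.0, 1.0])
        rx = np.array([[1, 0, 0], [0, np.cos(tx), -np.sin(tx)], [0, np.sin(tx), np.cos(tx)]])
        ry = np.array([[np.cos(ty), 0, np.sin(ty)], [0, 1, 0], [-np.sin(ty), 0, np.cos(ty)]])
        return ry @ rx @ a


@dataclass
class PhantomTruth:
    """Ground truth of a generated case (masks on the intraoperative grid)."""

    pose: ApplicatorPose
    motion: RigidTransform
    air_gap: Mask
    applicator_wall: Mask
    cavity: Mask
    bone: Mask
    bone_pre: Mask
    body: Mask
    body_pre: Mask
    max_air_gap_mm: float
    cavity_field: CavityField
    entry_point_mm: np.ndarray


@dataclass
class PhantomCase:
    preop: CTVolume
    intraop: CTVolume
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def add_noise(vol: CTVolume, sigma_hu: float, seed: int) -> CTVolume:
    """Additive Gaussian HU noise; ``sigma = 0`` is the identity."""
    if sigma_hu < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_hu == 0:
        return vol.with_values(vol.values.copy())
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_hu, size=vol.shape).astype(np.float32)
    return vol.with_values(vol.values.astype(np.float32) + noise)


def apply_rigid_motion(vol: CTVolume, t: RigidTransform) -> CTVolume:
    """Resample ``vol`` onto its own grid after moving its content by ``t``.

    The output value at world point x is the input sampled at t^-1(x)
    (trilinear); voxels mapped outside the input are set to air.
    """
    tinv = t.inverse()
    x, y, z = vol.voxel_centres_world()
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    moved = tinv.apply(pts)
    out = vol.sample_world(moved, order=1, cval=AIR_HU).reshape(vol.shape)
    return vol.with_values(out.astype(np.float32))


def _world_grids(vol):
    x, y, z = vol.voxel_centres_world()
    return x.astype(np.float64), y.astype(np.float64), z.astype(np.float64)


def place_applicator(vol: CTVolume, spec: ApplicatorSpec, pose: ApplicatorPose):
    """Rasterise the hollow PMMA tube wall into ``vol`` (returns vol', wall mask).

    Wall voxels (inner radius <= r <= outer radius, proximal to the bevel plane,
    within the tube length) are set to ``spec.wall_hu``; the interior is left as
    ambient content.
    """
    if min(vol.spacing) > spec.wall_thickness_mm:
        import warnings

        warnings.warn("applicator wall thinner than one voxel; mask may be fragmentary")
    x, y, z = _world_grids(vol)
    c = pose.bevel_centre
    a = pose.axis
    dx, dy, dz = x - c[0], y - c[1], z - c[2]
    s = dx * a[0] + dy * a[1] + dz * a[2]
    r2 = (dx - s * a[0]) ** 2 + (dy - s * a[1]) ** 2 + (dz - s * a[2]) ** 2
    m = pose.bevel_normal(spec)
    plane = dx * m[0] + dy * m[1] + dz * m[2]
    r_in, r_out = spec.inner_radius_mm, spec.outer_radius_mm
    wall = (
        (r2 >= r_in**2)
        & (r2 <= r_out**2)
        & (plane <= 0.0)
        & (s >= -spec.tube_length_mm)
    )
    if not wall.any():
        raise GeometryError("applicator pose does not intersect the volume")
    values = vol.values.astype(np.float32).copy()
    values[wall] = spec.wall_hu
    return vol.with_values(values), Mask.like(vol, wall)


def carve_cavity(vol: CTVolume, centre, base_depth_mm, irregularity_amplitude_mm,
                 seed, radius_mm=40.0, axis=(0, 0, 1), n_bumps=6,
                 bump_width_mm=14.0, cavity_field: CavityField | None = None):
    """Carve an irregular tumour-bed cavity into ``vol``.

    ``centre`` should lie on the body surface where the resection starts; the
    removed region extends distally along ``axis`` from the transverse plane
    through ``centre`` down to the cavity depth function (spherical-cap base
    plus seeded Gaussian bumps) within ``radius_mm`` of the axis.  Carved
    voxels are set to air (−1000 HU); the returned mask holds the voxels that
    were tissue before carving.  Idempotent: the removed region is fixed in
    space, so re-carving changes nothing.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    centre = np.asarray(centre, dtype=float)
    rng = np.random.default_rng(seed)
    fieldf = cavity_field or CavityField.generate(
        radius_mm, base_depth_mm, irregularity_amplitude_mm, rng, n_bumps, bump_width_mm
    )
    x, y, z = _world_grids(vol)
    dx, dy, dz = x - centre[0], y - centre[1], z - centre[2]
    s = dx * axis[0] + dy * axis[1] + dz * axis[2]
    uax, vax = transverse_frame(axis)
    u = dx * uax[0] + dy * uax[1] + dz * uax[2]
    v = dx * vax[0] + dy * vax[1] + dz * vax[2]
    inside_r = (u * u + v * v) <= fieldf.radius_mm**2
    if not inside_r.any():
        raise GeometryError("cavity footprint lies outside the volume")

    depth = fieldf.depth(u[inside_r], v[inside_r])
    remove_flat = (s[inside_r] >= -1e-9) & (s[inside_r] <= depth)
    remove = np.zeros(vol.shape, dtype=bool)
    remove[inside_r] = remove_flat
    # only voxels that are currently tissue change
    cavity = remove & (vol.values > -500.0)
    values = vol.values.astype(np.float32).copy()
    values[remove] = AIR_HU
    return vol.with_values(values), Mask.like(vol, cavity)


# ---------------------------------------------------------------------------
# analytic shape rasterisation (ground truth)
# ---------------------------------------------------------------------------


def _ellipsoid_mask(x, y, z, centre, half_axes, rotation=None):
    d = np.stack([x - centre[0], y - centre[1], z - centre[2]], axis=0)
    if rotation is not None:
        r = np.asarray(rotation, dtype=float)
        d = np.einsum("ji,jabc->iabc", r, d)  # R^T d
    ha = np.asarray(half_axes, dtype=float)
    return (d[0] / ha[0]) ** 2 + (d[1] / ha[1]) ** 2 + (d[2] / ha[2]) ** 2 <= 1.0


def _cylinder_mask(x, y, z, centre, axis, radius, half_length):
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    dx, dy, dz = x - centre[0], y - centre[1], z - centre[2]
    s = dx * a[0] + dy * a[1] + dz * a[2]
    r2 = (dx - s * a[0]) ** 2 + (dy - s * a[1]) ** 2 + (dz - s * a[2]) ** 2
    return (np.abs(s) <= half_length) & (r2 <= radius**2)


def _sphere_mask(x, y, z, centre, radius):
    return ((x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2) <= radius**2


def _default_bones(body_centre):
    cb = np.asarray(body_centre, dtype=float)
    return (
        ("cylinder", cb + np.array([-50.0, 0.0, 16.0]), (0, 1, 0), 7.0, 30.0),
        ("cylinder", cb + np.array([50.0, 0.0, 16.0]), (0, 1, 0), 7.0, 30.0),
        ("sphere", cb + np.array([0.0, -47.0, 30.0]), 9.0),
    )


def _rasterise_bones(x, y, z, bones, motion=None):
    mask = np.zeros(x.shape, dtype=bool)
    for bone in bones:
        kind = bone[0]
        if kind == "cylinder":
            _, centre, axis, radius, half_len = bone
            centre = np.asarray(centre, dtype=float)
            axis = np.asarray(axis, dtype=float)
            if motion is not None:
                centre = motion.apply(centre)[0]
                axis = motion.rotation @ axis
            mask |= _cylinder_mask(x, y, z, centre, axis, radius, half_len)
        elif kind == "sphere":
            _, centre, radius = bone
            centre = np.asarray(centre, dtype=float)
            if motion is not None:
                centre = motion.apply(centre)[0]
            mask |= _sphere_mask(x, y, z, centre, radius)
        else:  # pragma: no cover
            raise ValueError(f"unknown bone primitive {kind!r}")
    return mask


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def _ray_ellipsoid_entry(feet, axis, centre, half_axes, rotation=None):
    """First intersection (smallest s) of rays ``feet + s*axis`` with an ellipsoid.

    Returns +inf where the ray misses.  ``feet`` is (n, 3).
    """
    r = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    ha = np.asarray(half_axes, dtype=float)
    q = r @ np.diag(1.0 / ha**2) @ r.T
    a = np.asarray(axis, dtype=float)
    d = feet - np.asarray(centre, dtype=float)
    aa = float(a @ q @ a)
    bb = 2.0 * d @ (q @ a)
    cc = np.einsum("ij,jk,ik->i", d, q, d) - 1.0
    disc = bb * bb - 4.0 * aa * cc
    out = np.full(feet.shape[0], np.inf)
    ok = disc >= 0
    out[ok] = (-bb[ok] - np.sqrt(disc[ok])) / (2.0 * aa)
    return out


def generate_phantom(cfg: PhantomConfig) -> PhantomCase:
    """Generate a paired pre/intraoperative CT case with analytic ground truth.

    The intraoperative anatomy is the preoperative anatomy moved by the
    configured rigid motion (both are rasterised analytically, so the truth
    masks are exact), with the tumour-bed cavity carved and the applicator
    placed so the maximum axial air gap equals ``cfg.target_max_gap_mm``.
    """
    rng_master = np.random.default_rng(cfg.seed)
    seeds = rng_master.integers(0, 2**31 - 1, size=4)

    spacing = tuple(float(s) for s in cfg.spacing_mm)
    grid = CTVolume(np.zeros(cfg.shape, dtype=np.float32), spacing, (0.0, 0.0, 0.0))
    x, y, z = _world_grids(grid)

    body_centre = cfg.resolved_body_centre()
    bones = cfg.bones if cfg.bones is not None else _default_bones(body_centre)
    extent = np.asarray(cfg.grid_extent_mm())
    motion = RigidTransform.from_euler(
        cfg.motion_rotation_deg, cfg.motion_translation_mm, centre=extent / 2.0
    )

    # ---- preoperative anatomy (no cavity, no applicator) -------------------
    def rasterise_anatomy(move):
        bc = body_centre if move is None else move.apply(body_centre)[0]
        rot = None if move is None else move.rotation
        body = _ellipsoid_mask(x, y, z, bc, cfg.body_half_axes_mm, rot)
        bone = _rasterise_bones(x, y, z, bones, move) & body
        values = np.full(cfg.shape, AIR_HU, dtype=np.float32)
        values[body] = cfg.soft_tissue_hu
        if cfg.low_density_hu is not None:
            lc = np.asarray(
                cfg.low_density_centre_mm
                if cfg.low_density_centre_mm is not None
                else body_centre + np.array([0.0, 30.0, 10.0]),
                dtype=float,
            )
            if move is not None:
                lc = move.apply(lc)[0]
            low = _sphere_mask(x, y, z, lc, cfg.low_density_radius_mm) & body
            values[low] = cfg.low_density_hu
        values[bone] = cfg.bone_hu
        return values, body, bone, bc, rot

    pre_values, body_pre, bone_pre, _, _ = rasterise_anatomy(None)
    intra_values, body_moved, bone_intra, bc_intra, rot_intra = rasterise_anatomy(motion)

    # ---- applicator axis and body entry ------------------------------------
    axis = motion.rotation @ cfg.applicator_axis()  # pose given in intraop frame
    uax, vax = transverse_frame(axis)
    off = np.asarray(cfg.applicator_offset_mm, dtype=float)
    axis_point = bc_intra + off[0] * uax + off[1] * vax
    # entry point of the axis line into the (moved) body
    s0 = _ray_ellipsoid_entry(
        axis_point[None] - 200.0 * axis, axis, bc_intra, cfg.body_half_axes_mm, rot_intra
    )
    if not np.isfinite(s0[0]):
        raise GeometryError("applicator axis does not intersect the body")
    q0 = axis_point - 200.0 * axis + s0[0] * axis

    # ---- cavity field and bevel placement ----------------------------------
    cav_radius = cfg.resolved_cavity_radius()
    fieldf = CavityField.generate(
        cav_radius,
        cfg.cavity_depth_mm,
        cfg.cavity_irregularity_mm,
        np.random.default_rng(seeds[0]),
        cfg.n_bumps,
        cfg.bump_width_mm,
    )
    spec = cfg.spec
    r_in = spec.inner_radius_mm
    # fine transverse grid over the aperture footprint
    g = np.arange(-r_in, r_in + 0.25, 0.25)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    disc = (uu**2 + vv**2) <= r_in**2
    uf, vf = uu[disc], vv[disc]
    feet = q0 + uf[:, None] * uax + vf[:, None] * vax
    s_entry_f = _ray_ellipsoid_entry(feet, axis, bc_intra, cfg.body_half_axes_mm, rot_intra)
    if not np.all(np.isfinite(s_entry_f)):
        raise GeometryError("part of the aperture footprint misses the body")
    s_tissue_f = s_entry_f + fieldf.depth(uf, vf)
    beta = np.deg2rad(spec.bevel_angle_deg)
    rollr = np.deg2rad(cfg.applicator_roll_deg)
    lin = -np.tan(beta) * (uf * np.cos(rollr) + vf * np.sin(rollr))
    s_bevel = float(np.max(s_tissue_f - lin)) - cfg.target_max_gap_mm
    bevel_centre = q0 + s_bevel * axis
    idxc = grid.world_to_index(bevel_centre)[0]
    if np.any(idxc < 0) or np.any(idxc > np.asarray(cfg.shape) - 1):
        raise GeometryError("bevel centre falls outside the volume")
    pose = ApplicatorPose(
        bevel_centre, axis, cfg.applicator_roll_deg,
        roll_undefined=(spec.bevel_angle_deg == 0.0),
    )
    max_gap_truth = float(np.max(s_tissue_f - (s_bevel + lin)))

    # ---- carve cavity (analytic entry surface) ------------------------------
    dxq, dyq, dzq = x - q0[0], y - q0[1], z - q0[2]
    s_vox = dxq * axis[0] + dyq * axis[1] + dzq * axis[2]
    u_vox = dxq * uax[0] + dyq * uax[1] + dzq * uax[2]
    v_vox = dxq * vax[0] + dyq * vax[1] + dzq * vax[2]
    in_foot = (u_vox**2 + v_vox**2) <= cav_radius**2
    # per-voxel analytic entry along its own column
    feet_v = (
        q0
        + u_vox[in_foot][:, None] * uax
        + v_vox[in_foot][:, None] * vax
    )
    entry_v = _ray_ellipsoid_entry(feet_v, axis, bc_intra, cfg.body_half_axes_mm, rot_intra)
    depth_v = fieldf.depth(u_vox[in_foot], v_vox[in_foot])
    remove_flat = (s_vox[in_foot] >= entry_v - 1e-9) & (s_vox[in_foot] <= entry_v + depth_v)
    removed = np.zeros(cfg.shape, dtype=bool)
    removed[in_foot] = remove_flat
    cavity = removed & body_moved
    intra_values = intra_values.copy()
    intra_values[removed] = AIR_HU

    # optional biological-fluid pool flat-filling the cavity bottom
    fluid = np.zeros(cfg.shape, dtype=bool)
    s_fluid_level = np.inf
    if cfg.fluid_depth_mm is not None and cfg.fluid_depth_mm > 0:
        s_deepest = float(np.max(s_tissue_f))
        s_fluid_level = s_deepest - cfg.fluid_depth_mm
        fluid = cavity & (s_vox >= s_fluid_level)
        intra_values[fluid] = FLUID_HU

    # ---- place applicator ---------------------------------------------------
    intra_vol = CTVolume(intra_values, spacing, (0.0, 0.0, 0.0))
    intra_vol, wall = place_applicator(intra_vol, spec, pose)

    # ---- truth masks ---------------------------------------------------------
    # air gap: inside the inner cylinder, distal to the bevel plane, proximal to
    # the tissue surface (or fluid level), and not wall
    r2_vox = (u_vox - 0.0) ** 2 + (v_vox - 0.0) ** 2  # cylinder about q0-axis
    pts_flat = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    plane_d = signed_bevel_distance(pts_flat, pose, spec).reshape(cfg.shape)
    in_cyl = r2_vox < r_in**2
    # first-tissue surface per voxel column (analytic): entry + depth
    s_tissue_vox = np.full(cfg.shape, np.inf)
    feet_all = (
        q0
        + u_vox[in_cyl][:, None] * uax
        + v_vox[in_cyl][:, None] * vax
    )
    entry_all = _ray_ellipsoid_entry(feet_all, axis, bc_intra, cfg.body_half_axes_mm, rot_intra)
    s_tissue_vox[in_cyl] = entry_all + fieldf.depth(u_vox[in_cyl], v_vox[in_cyl])
    air_gap = (
        in_cyl
        & (plane_d > 0)
        & (s_vox < s_tissue_vox)
        & (s_vox < s_fluid_level)
        & ~wall.values
    )

    body_intra_mask = (body_moved & ~removed) | fluid
    body_intra_mask &= ~wall.values

    truth = PhantomTruth(
        pose=pose,
        motion=motion,
        air_gap=Mask.like(intra_vol, air_gap),
        applicator_wall=wall,
        cavity=Mask.like(intra_vol, cavity),
        bone=Mask.like(intra_vol, bone_intra & ~removed),
        bone_pre=Mask.like(intra_vol, bone_pre),
        body=Mask.like(intra_vol, body_intra_mask),
        body_pre=Mask.like(intra_vol, body_pre),
        max_air_gap_mm=max_gap_truth,
        cavity_field=fieldf,
        entry_point_mm=q0,
    )

    preop = CTVolume(pre_values, spacing, (0.0, 0.0, 0.0))
    preop = add_noise(preop, cfg.noise_sigma_hu, int(seeds[1]))
    intraop = add_noise(intra_vol, cfg.noise_sigma_hu, int(seeds[2]))
    return PhantomCase(preop=preop, intraop=intraop, truth=truth)
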