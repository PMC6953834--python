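"""Recover the applicator pose from the segmented wall.

The clinical method locates the bevel centre and tube axis from a wall
segmentation and a manual click on the shorter edge; here the axis comes from a
PCA/slab-centre line fit, the distal rim is extracted automatically per angular
bin, the bevel plane is fitted by least squares, and the roll follows from the
angular position of the rim's most proximal point (the shorter edge).  A
user-supplied shorter-edge world point can override the automatic roll,
emulating the manual step.
"""

from __future__ import annotations

import warnings

import numpy as np

from .applicator import ApplicatorPose, ApplicatorSpec, transverse_frame
from .core import CTVolume, Mask
from .errors import GeometryError, IncompleteRimError

N_ANGULAR_BINS = 72  # 5-degree rim bins
MIN_RIM_COVERAGE = 0.75


def fit_axis(wall: Mask, vol: CTVolume | None = None, distal_hint=None,
             slab_mm: float = 4.0, iterations: int = 2):
    """Tube axis (unit vector, distal) and a centreline point from wall voxels.

    The axis starts as the principal direction of the wall voxel coordinates
    and is refined as the line through per-slab wall centres (slabs with
    incomplete angular coverage, e.g. at the beveled end, are dropped).  The
    distal sign is taken from ``distal_hint`` if given, else from the tissue
    fraction (HU > −300) in a 2-diameter neighbourhood of each tube end when a
    CT volume is supplied, else the dominant component is made positive.
    """
    idx = np.argwhere(wall.values)
    if idx.shape[0] < 50:
        raise GeometryError("wall mask too small to fit an axis")
    pts = Mask.index_to_world(wall, idx)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)

    # A cylinder-shell axis minimises the spread of radial distances about the
    # line through the centroid.  The principal directions alone can mix axial
    # and radial components when the tube length is near the eigenvalue
    # crossover (~2.4 radii), so each eigenvector seeds a direct minimisation of
    # std(r)/mean(r) and the best shell-like solution wins.
    sub = pts[:: max(1, pts.shape[0] // 6000)]
    dsub = sub - sub.mean(axis=0)

    def shellness(a):
        s = dsub @ a
        r = np.linalg.norm(dsub - np.outer(s, a), axis=1)
        return r.std() / max(r.mean(), 1e-9)

    def polish(a0):
        from scipy.optimize import minimize

        u0, v0 = transverse_frame(a0)

        def obj(p):
            a = a0 + p[0] * u0 + p[1] * v0
            return shellness(a / np.linalg.norm(a))

        res = minimize(obj, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200})
        a = a0 + res.x[0] * u0 + res.x[1] * v0
        return a / np.linalg.norm(a)

    starts = [polish(evecs[:, i]) for i in range(3)]
    axis0 = min(starts, key=shellness)

    def refine(axis, n_ang=16):
        """Line fit through the centres of complete rings only.

        A slab whose angular coverage about the axis is incomplete (the beveled
        rim, a clipped tube end) has an off-axis centre and is dropped; full
        rings are centred on the true axis regardless of voxelisation.
        """
        point = centroid
        for _ in range(iterations + 1):
            d = pts - point
            s = d @ axis
            u, v = transverse_frame(axis)
            theta = np.arctan2(d @ v, d @ u)
            nbins = max(int((s.max() - s.min()) / slab_mm), 3)
            edges = np.linspace(s.min(), s.max() + 1e-9, nbins + 1)
            which = np.digitize(s, edges) - 1
            centres = []
            for b in range(nbins):
                sel = which == b
                if not sel.any():
                    continue
                ang_occupied = np.unique(
                    ((theta[sel] + np.pi) / (2 * np.pi) * n_ang).astype(int) % n_ang
                )
                if len(ang_occupied) == n_ang:  # complete ring
                    centres.append(pts[sel].mean(axis=0))
            if len(centres) < 3:
                break
            centres = np.asarray(centres)
            # robust line fit: rings straddling the bevel transition can be
            # angularly complete yet off-axis; trim large lateral residuals
            for _ in range(3):
                point = centres.mean(axis=0)
                dd = centres - point
                _, _, vt = np.linalg.svd(dd, full_matrices=False)
                new_axis = vt[0]
                resid = np.linalg.norm(
                    dd - np.outer(dd @ new_axis, new_axis), axis=1
                )
                cut = max(1.5, 3.0 * np.median(resid))
                keep = resid <= cut
                if keep.all() or keep.sum() < 3:
                    break
                centres = centres[keep]
            if new_axis @ axis < 0:
                new_axis = -new_axis
            axis = new_axis
        s = (pts - point) @ axis
        r = np.linalg.norm((pts - point) - np.outer(s, axis), axis=1)
        score = r.std() / max(r.mean(), 1e-9)  # low = shell-like
        return axis, point, score, float(s.max() - s.min()), float(r.mean())

    axis, point, score, extent, mean_r = refine(axis0)
    if score > 0.2 or extent < 0.3 * mean_r:
        raise GeometryError("degenerate wall mask: no cylindrical axis found")

    # sign disambiguation
    if distal_hint is not None:
        hint = np.asarray(distal_hint, dtype=float)
        if axis @ hint < 0:
            axis = -axis
    elif vol is not None:
        s = (pts - point) @ axis
        radius = (s.max() - s.min()) / 2.0
        diam = 2.0 * np.median(np.linalg.norm(
            (pts - point) - np.outer((pts - point) @ axis, axis), axis=1))
        probe = min(2.0 * diam, radius)
        fracs = []
        for end in (point + s.max() * axis, point + s.min() * axis):
            x, y, z = vol.voxel_centres_world()
            d2 = (x - end[0]) ** 2 + (y - end[1]) ** 2 + (z - end[2]) ** 2
            ball = d2 <= probe**2
            fracs.append(float(np.mean(vol.values[ball] > -300.0)) if ball.any() else 0.0)
        if fracs[1] > fracs[0]:  # min-s end is the tissue side
            axis = -axis
    else:
        dominant = int(np.argmax(np.abs(axis)))
        if axis[dominant] < 0:
            axis = -axis
    return axis / np.linalg.norm(axis), point


def locate_bevel(wall: Mask, axis, centreline_point, spec: ApplicatorSpec,
                 shorter_edge_point=None):
    """Bevel centre, roll and flags from the distal rim of the wall mask.

    The rim is the most-distal wall voxel in each of 72 angular bins about the
    axis; the bevel plane is fitted to the rim by least squares.  Roll is the
    angular position of the rim's most proximal point; a supplied shorter-edge
    world point overrides it.  ``roll_undefined`` is set for flat (0-degree
    bevel) applicators, whose rim is rotationally symmetric.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    point = np.asarray(centreline_point, dtype=float)
    u, v = transverse_frame(axis)

    idx = np.argwhere(wall.values)
    if idx.size == 0:
        raise GeometryError("empty wall mask")
    pts = Mask.index_to_world(wall, idx)
    d = pts - point
    s = d @ axis
    du = d @ u
    dv = d @ v
    theta = np.arctan2(dv, du) % (2 * np.pi)

    bins = (theta / (2 * np.pi) * N_ANGULAR_BINS).astype(int) % N_ANGULAR_BINS
    eps = 0.75 * min(wall.spacing)
    rim = []
    for b in range(N_ANGULAR_BINS):
        sel = bins == b
        if not sel.any():
            continue
        smax = s[sel].max()
        near = sel.copy()
        near[sel] = s[sel] >= smax - eps  # average ties: no index-order bias
        rim.append((du[near].mean(), dv[near].mean(), s[near].mean()))
    if len(rim) < MIN_RIM_COVERAGE * N_ANGULAR_BINS:
        raise IncompleteRimError(
            f"rim covers only {len(rim)}/{N_ANGULAR_BINS} angular bins"
        )
    rim = np.asarray(rim)
    x, y, sz = rim[:, 0], rim[:, 1], rim[:, 2]

    # least-squares plane s = c0 + c1*x + c2*y
    a_mat = np.stack([np.ones_like(x), x, y], axis=1)
    c0, c1, c2 = np.linalg.lstsq(a_mat, sz, rcond=None)[0]
    fitted_bevel_deg = float(np.rad2deg(np.arctan(np.hypot(c1, c2))))

    # The bevel centre lies on the tube axis where it crosses the fitted plane
    # (the axis line from the ring fit is more reliable than the rim centroid).
    # Rim voxel centres sit up to one voxel proximal to the physical cut, so the
    # plane is pushed distally by half a voxel along its normal.
    slope = np.sqrt(1.0 + c1 * c1 + c2 * c2)
    m_world = (axis - c1 * u - c2 * v) / slope
    h_m = float(np.abs(m_world) @ np.asarray(wall.spacing))
    bevel_centre = point + (c0 + 0.5 * h_m * slope) * axis

    roll_undefined = spec.bevel_angle_deg == 0.0 or fitted_bevel_deg < 2.0
    if shorter_edge_point is not None:
        e = np.asarray(shorter_edge_point, dtype=float) - bevel_centre
        roll = float(np.rad2deg(np.arctan2(e @ v, e @ u))) % 360.0
        roll_undefined = spec.bevel_angle_deg == 0.0
    elif roll_undefined:
        roll = 0.0
    else:
        roll = float(np.rad2deg(np.arctan2(-c2, -c1))) % 360.0

    r_rim = np.hypot(x, y)
    fitted_diameter = float(2.0 * r_rim.mean() - spec.wall_thickness_mm)
    return bevel_centre, roll, {
        "roll_undefined": bool(roll_undefined),
        "fitted_bevel_angle_deg": fitted_bevel_deg,
        "fitted_diameter_mm": fitted_diameter,
    }


def estimate_pose(wall: Mask, spec: ApplicatorSpec, vol: CTVolume | None = None,
                  distal_hint=None, shorter_edge_point=None) -> ApplicatorPose:
    """Full pose: axis fit + bevel location, with a diameter QC check."""
    axis, point = fit_axis(wall, vol=vol, distal_hint=distal_hint)
    centre, roll, flags = locate_bevel(wall, axis, point, spec,
                                       shorter_edge_point=shorter_edge_point)
    nominal = spec.diameter_cm * 10.0
    if abs(flags["fitted_diameter_mm"] - nominal) > 0.10 * nominal:
        warnings.warn(
            f"fitted applicator diameter {flags['fitted_diameter_mm']:.1f} mm deviates "
            f">10% from spec {nominal:.1f} mm"
        )
    return ApplicatorPose(
        bevel_centre=centre,
        axis=axis,
        roll_deg=roll,
        roll_undefined=flags["roll_undefined"],
        fitted_diameter_mm=flags["fitted_diameter_mm"],
    )
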