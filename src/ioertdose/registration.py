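"""Rigid CT-to-CT alignment by normalised mutual information over bone.

The preoperative (moving) image is aligned to the intraoperative (fixed) image
by maximising Studholme-normalised mutual information, evaluated only on the
fixed image's segmented bone mask (dilated by 2 voxels), with a 4→2→1 mm
multi-resolution Gaussian schedule and a Powell optimiser.  Everything is
deterministic given the initial transform.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize

from .core import AIR_HU, CTVolume, Mask, RigidTransform
from .errors import ConvergenceError, EmptyMaskError, InitializationError

HU_CLAMP = (-1000.0, 2000.0)


def _entropy(p):
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _joint_histogram(a, b, bins, hu_range=HU_CLAMP):
    lo, hi = hu_range
    a = np.clip(a, lo, hi)
    b = np.clip(b, lo, hi)
    ia = np.minimum(((a - lo) / (hi - lo) * bins).astype(np.int64), bins - 1)
    ib = np.minimum(((b - lo) / (hi - lo) * bins).astype(np.int64), bins - 1)
    h = np.bincount(ia * bins + ib, minlength=bins * bins).reshape(bins, bins)
    return h.astype(np.float64)


def nmi(fixed: CTVolume, moving_warped: CTVolume, mask: Mask, bins: int = 32,
        hu_range=HU_CLAMP) -> float:
    """Studholme NMI, (H(A)+H(B))/H(A,B) over the masked joint histogram.

    Range (1, 2]; degenerate (constant) images return 2.0 by convention (the
    images are then perfectly dependent) with a warning.
    """
    if not (fixed.same_grid(moving_warped) and fixed.shape == mask.shape):
        from .errors import GridMismatchError

        raise GridMismatchError("fixed, moving and mask must share one grid")
    m = mask.values
    if not m.any():
        raise EmptyMaskError("NMI over an empty mask")
    return _nmi_samples(fixed.values[m], moving_warped.values[m], bins, hu_range)


def _nmi_samples(a, b, bins, hu_range=HU_CLAMP, warn_degenerate=True):
    h = _joint_histogram(a, b, bins, hu_range)
    p = h / h.sum()
    h_joint = _entropy(p)
    if h_joint == 0.0:
        if warn_degenerate:
            warnings.warn("degenerate joint histogram (constant images); NMI := 2")
        return 2.0
    h_a = _entropy(p.sum(axis=1))
    h_b = _entropy(p.sum(axis=0))
    return (h_a + h_b) / h_joint


def apply_transform(vol: CTVolume, t: RigidTransform, reference: CTVolume) -> CTVolume:
    """Resample ``vol`` onto the reference grid through ``t`` (moving→fixed)."""
    x, y, z = reference.voxel_centres_world()
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    moved = t.inverse().apply(pts)
    out = vol.sample_world(moved, order=1, cval=AIR_HU).reshape(reference.shape)
    return CTVolume(out.astype(np.float32), reference.spacing, reference.origin,
                    reference.orientation)


def _subsample_points(pts, values, max_n):
    if pts.shape[0] <= max_n:
        return pts, values
    stride = int(np.ceil(pts.shape[0] / max_n))
    return pts[::stride], values[::stride]


def rigid_register(fixed: CTVolume, moving: CTVolume, fixed_bone: Mask,
                   init: RigidTransform | None = None, bins: int = 32,
                   smooth_mm=(4.0, 2.0, 1.0), max_samples=(8000, 15000, 30000),
                   dilate_voxels: int = 2, bone_hu_min: float = 200.0,
                   min_overlap: float = 0.10, xtol: float = 1e-3,
                   maxiter: int = 60) -> RigidTransform:
    """Recover the rigid transform mapping moving-image to fixed-image world.

    NMI is evaluated over the fixed bone mask dilated by ``dilate_voxels``,
    sampling the moving image through the current transform.  Raises
    ``InitializationError`` when fewer than ``min_overlap`` of the fixed bone
    voxels map onto bone-like HU in the moving image under ``init``, and
    ``ConvergenceError`` (with diagnostics) when the optimiser fails.
    """
    if not fixed_bone.values.any():
        raise EmptyMaskError("fixed bone mask is empty")
    if init is None:
        # moments initialisation: align the bone-intensity centroids
        fixed_idx = np.argwhere(fixed_bone.values)
        c_fixed = Mask.index_to_world(fixed_bone, fixed_idx).mean(axis=0)
        mov_sel = moving.values >= bone_hu_min
        if mov_sel.any():
            c_mov = CTVolume.index_to_world(moving, np.argwhere(mov_sel)).mean(axis=0)
            init = RigidTransform(translation=c_fixed - c_mov)
        else:
            init = RigidTransform.identity()

    # initialisation sanity: does the init map fixed bone onto moving bone?
    bone_idx = np.argwhere(fixed_bone.values)
    bone_pts = Mask.index_to_world(fixed_bone, bone_idx)
    init_moving_pts = init.inverse().apply(bone_pts)
    hu = moving.sample_world(init_moving_pts, order=1, cval=AIR_HU)
    overlap = float(np.mean(hu >= bone_hu_min))
    if overlap < min_overlap:
        raise InitializationError(
            f"bone overlap after initialisation is {overlap:.1%} (< {min_overlap:.0%})"
        )

    mask = ndimage.binary_dilation(
        fixed_bone.values, structure=ndimage.generate_binary_structure(3, 1),
        iterations=dilate_voxels,
    )
    all_idx = np.argwhere(mask)
    all_pts = Mask.index_to_world(fixed_bone, all_idx)
    centre = bone_pts.mean(axis=0)

    # decompose init into parameters about `centre`
    def params_from_transform(t):
        r = t.rotation
        sy = -r[2, 0]
        ay = np.arcsin(np.clip(sy, -1, 1))
        ax = np.arctan2(r[2, 1], r[2, 2])
        az = np.arctan2(r[1, 0], r[0, 0])
        trans = t.translation - (centre - r @ centre)
        return np.array([np.rad2deg(ax), np.rad2deg(ay), np.rad2deg(az), *trans])

    def transform_from_params(p):
        return RigidTransform.from_euler(p[:3], p[3:], centre=centre)

    p = params_from_transform(init)
    history = []
    first_level = True
    for sigma_mm, max_n in zip(smooth_mm, max_samples):
        sig_f = np.asarray(sigma_mm) / np.asarray(fixed.spacing)
        sig_m = np.asarray(sigma_mm) / np.asarray(moving.spacing)
        fixed_s = ndimage.gaussian_filter(fixed.values.astype(np.float32), sig_f)
        moving_s = ndimage.gaussian_filter(moving.values.astype(np.float32), sig_m)
        fvals_all = fixed_s[tuple(all_idx.T)]
        pts, fvals = _subsample_points(all_pts, fvals_all, max_n)

        mov_vol = moving.with_values(moving_s)

        def cost(params):
            t = transform_from_params(params)
            mvals = mov_vol.sample_world(t.inverse().apply(pts), order=1, cval=AIR_HU)
            return -_nmi_samples(fvals, mvals, bins, warn_degenerate=False)

        if first_level:
            # deterministic rotation grid search around the initialisation to
            # select the NMI basin before local optimisation
            grid = np.array([-8.0, -4.0, 0.0, 4.0, 8.0])
            best_p, best_c = p, cost(p)
            for ax in grid:
                for ay in grid:
                    for az in grid:
                        if ax == ay == az == 0.0:
                            continue
                        cand = p + np.array([ax, ay, az, 0.0, 0.0, 0.0])
                        c = cost(cand)
                        if c < best_c:
                            best_p, best_c = cand, c
            p = best_p
            first_level = False

        res = optimize.minimize(
            cost, p, method="Powell",
            options={"xtol": xtol, "ftol": 1e-9, "maxiter": maxiter,
                     "maxfev": 20000},
        )
        history.append({"sigma_mm": float(sigma_mm), "nmi": -float(res.fun),
                        "nfev": int(res.nfev), "success": bool(res.success)})
        if not res.success and res.nfev >= 20000:
            raise ConvergenceError("registration optimiser did not converge",
                                   diagnostics={"levels": history})
        p = res.x
    return transform_from_params(p)


def registration_tre(recovered: RigidTransform, truth: RigidTransform,
                     bone: Mask) -> float:
    """Mean target-registration error (mm) over bone voxels."""
    idx = np.argwhere(bone.values)
    if idx.size == 0:
        raise EmptyMaskError("TRE over an empty mask")
    pts_fixed = Mask.index_to_world(bone, idx)
    # both transforms map moving->fixed; compare where each sends the same
    # moving-frame points
    pts_moving = truth.inverse().apply(pts_fixed)
    err = recovered.apply(pts_moving) - pts_fixed
    return float(np.linalg.norm(err, axis=1).mean())
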