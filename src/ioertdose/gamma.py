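"""3D gamma analysis (dose difference / distance-to-agreement).

A reference voxel passes when some evaluated-dose sample point u within the
search radius satisfies

    gamma(v) = min_u sqrt( (|u - v| / DTA)^2 + ((D_eval(u) - D_ref(v)) / dD)^2 ) <= 1

with dD the dose tolerance times the normalisation dose (global normalisation:
one distribution-wide reference dose, by default the reference maximum).  The
evaluated distribution is sampled on a sub-voxel lattice (default voxel/3) with
trilinear interpolation, out to 3x the DTA.

Two implementations share this contract: :func:`gamma_map` (distance-sorted
search with exact pruning) and :func:`gamma_bruteforce` (exhaustive scan over
every sample point, no pruning) — the oracle the fast path is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Mask
from .errors import EmptyAnalysisError, GridMismatchError


@dataclass
class GammaCriteria:
    """3%/3 mm-style settings: tolerances, threshold, normalisation, search."""

    dose_tolerance_pct: float = 3.0
    dta_mm: float = 3.0
    threshold_pct: float = 10.0
    normalisation: str = "global"  # or "local"
    normalisation_dose: float | None = None  # None -> reference maximum
    search_radius_mm: float | None = None  # None -> 3 * dta
    interp_fraction: float = 1.0 / 3.0  # sub-voxel lattice step, in voxels

    def __post_init__(self):
        if min(self.dose_tolerance_pct, self.dta_mm, self.threshold_pct) <= 0:
            raise ValueError("tolerances and threshold must be positive")
        if not (0 < self.threshold_pct < 100):
            raise ValueError("threshold must be in (0, 100)")
        if self.normalisation not in ("global", "local"):
            raise ValueError("normalisation must be 'global' or 'local'")

    @property
    def radius_mm(self):
        return self.search_radius_mm if self.search_radius_mm is not None else 3.0 * self.dta_mm


@dataclass
class GammaResult:
    """Per-voxel gamma (NaN outside the analysis set) and the pass rate."""

    gamma: np.ndarray
    analysis_mask: Mask
    pass_rate: float
    analysed: int
    passed: int
    criteria: GammaCriteria = field(repr=False, default=None)


def _norm_dose(ref_values, criteria):
    if criteria.normalisation_dose is not None:
        return float(criteria.normalisation_dose)
    return float(ref_values.max())


def analysis_mask(ref, tissue: Mask, criteria: GammaCriteria) -> Mask:
    """Voxels with reference dose above the threshold, inside patient tissue."""
    if ref.shape != tissue.shape:
        raise GridMismatchError("reference dose and tissue mask must share a grid")
    norm = _norm_dose(ref.values, criteria)
    sel = (ref.values > criteria.threshold_pct / 100.0 * norm) & tissue.values
    if not sel.any():
        raise EmptyAnalysisError(
            f"no voxel above {criteria.threshold_pct}% of the normalisation dose"
        )
    return Mask(sel, ref.spacing, ref.origin, ref.orientation)


def _refine_factor(criteria):
    return max(1, int(round(1.0 / criteria.interp_fraction)))


def _supersample(values, k):
    """Trilinear refinement of a 3D array by integer factor k per axis.

    Output index f corresponds to input index f / k (length (n-1)*k + 1).
    """
    out = np.asarray(values, dtype=np.float64)
    if k == 1:
        return out.copy()
    for axis in range(3):
        n = out.shape[axis]
        if n == 1:
            continue
        idx = np.arange((n - 1) * k + 1)
        base = np.minimum(idx // k, n - 2)
        frac = (idx - base * k) / k
        lo = np.take(out, base, axis=axis)
        hi = np.take(out, base + 1, axis=axis)
        shape = [1, 1, 1]
        shape[axis] = len(idx)
        w = frac.reshape(shape)
        out = lo * (1.0 - w) + hi * w
    return out


def _offsets(shape_fine, spacing, k, radius_mm):
    """Integer fine-lattice offsets within the physical search radius."""
    sf = np.asarray(spacing, dtype=float) / k
    nmax = np.floor(radius_mm / sf).astype(int)
    oi = np.arange(-nmax[0], nmax[0] + 1)
    oj = np.arange(-nmax[1], nmax[1] + 1)
    ol = np.arange(-nmax[2], nmax[2] + 1)
    gi, gj, gl = np.meshgrid(oi, oj, ol, indexing="ij")
    d2 = (gi * sf[0]) ** 2 + (gj * sf[1]) ** 2 + (gl * sf[2]) ** 2
    keep = d2 <= radius_mm**2 + 1e-12
    offs = np.stack([gi[keep], gj[keep], gl[keep]], axis=1)
    return offs, d2[keep]


def _prepare(ref, eval_, criteria, mask):
    if ref.shape != eval_.shape or ref.shape != mask.shape:
        raise GridMismatchError("reference, evaluated and mask must share a grid")
    if not np.allclose(ref.spacing, eval_.spacing):
        raise GridMismatchError("reference and evaluated spacings differ")
    k = _refine_factor(criteria)
    fine = _supersample(eval_.values, k)
    coarse_idx = np.argwhere(mask.values)
    norm = _norm_dose(ref.values, criteria)
    dref = ref.values[mask.values].astype(np.float64)
    if criteria.normalisation == "global":
        dd = np.full(dref.shape, criteria.dose_tolerance_pct / 100.0 * norm)
    else:
        dd = criteria.dose_tolerance_pct / 100.0 * np.maximum(dref, 1e-12)
    offs, d2 = _offsets(fine.shape, ref.spacing, k, criteria.radius_mm)
    return k, fine, coarse_idx, dref, dd, offs, d2


def _result(gamma_flat, mask, ref, criteria):
    gamma_arr = np.full(mask.shape, np.nan)
    gamma_arr[mask.values] = gamma_flat
    analysed = int(mask.values.sum())
    passed = int((gamma_flat <= 1.0).sum())
    return GammaResult(
        gamma=gamma_arr,
        analysis_mask=mask,
        pass_rate=100.0 * passed / analysed,
        analysed=analysed,
        passed=passed,
        criteria=criteria,
    )


def gamma_map(ref, eval_, criteria: GammaCriteria, mask: Mask,
              chunk_offsets: int = 256, gamma_max: float | None = None) -> GammaResult:
    """Gamma over the analysis mask: distance-sorted search with exact pruning.

    Offsets are visited in order of increasing distance; a voxel whose current
    best gamma is already below the distance term of the remaining offsets
    cannot improve, so it is dropped — the minimum is unchanged (pruning is
    exact, see the brute-force equivalence tests).

    ``gamma_max`` (must be >= 1 when given) stops the search once the distance
    term alone exceeds it: gamma values above ``gamma_max`` become upper bounds,
    while values <= ``gamma_max`` — and hence the pass rate — remain exact,
    because any voxel with true gamma <= gamma_max attains its minimum at an
    offset whose distance term is <= gamma_max, which is always searched.
    """
    if gamma_max is not None and gamma_max < 1.0:
        raise ValueError("gamma_max must be >= 1 to keep the pass rate exact")
    k, fine, coarse_idx, dref, dd, offs, d2 = _prepare(ref, eval_, criteria, mask)
    order = np.argsort(d2, kind="stable")
    offs, d2 = offs[order], d2[order]
    dist_term = d2 / criteria.dta_mm**2

    fshape = np.asarray(fine.shape)
    fine_flat = fine.ravel()
    strides = np.array([fshape[1] * fshape[2], fshape[2], 1], dtype=np.int64)
    pos = coarse_idx.astype(np.int64) * k

    nvox = pos.shape[0]
    best2 = np.full(nvox, np.inf)
    active = np.arange(nvox)
    pos_a = pos
    dref_a, dd_a = dref, dd

    for lo in range(0, len(offs), chunk_offsets):
        if active.size == 0:
            break
        sl = slice(lo, lo + chunk_offsets)
        chunk = offs[sl]
        dterm = dist_term[sl]
        if gamma_max is not None and dterm[0] > gamma_max**2:
            break
        # prune: offsets at >= dmin cannot improve voxels with best2 <= dmin
        keep = best2[active] > dterm[0]
        active = active[keep]
        if active.size == 0:
            break
        pos_a = pos[active]
        dref_a = dref[active]
        dd_a = dd[active]
        tgt = pos_a[:, None, :] + chunk[None, :, :]  # (n, m, 3)
        valid = np.all((tgt >= 0) & (tgt < fshape), axis=2)
        flat_idx = (tgt * strides).sum(axis=2)
        np.clip(flat_idx, 0, fine_flat.size - 1, out=flat_idx)
        de = fine_flat[flat_idx]
        cand = dterm[None, :] + ((de - dref_a[:, None]) / dd_a[:, None]) ** 2
        cand[~valid] = np.inf
        best2[active] = np.minimum(best2[active], cand.min(axis=1))

    return _result(np.sqrt(best2), mask, ref, criteria)


def gamma_bruteforce(ref, eval_, criteria: GammaCriteria, mask: Mask,
                     chunk_voxels: int = 256) -> GammaResult:
    """Exhaustive gamma: every sample point in the search radius, no pruning.

    Intended for small grids (<= 64^3 advisable); the verification oracle for
    :func:`gamma_map`.
    """
    k, fine, coarse_idx, dref, dd, offs, d2 = _prepare(ref, eval_, criteria, mask)
    dist_term = d2 / criteria.dta_mm**2
    fshape = np.asarray(fine.shape)
    fine_flat = fine.ravel()
    strides = np.array([fshape[1] * fshape[2], fshape[2], 1], dtype=np.int64)
    pos = coarse_idx.astype(np.int64) * k

    best2 = np.empty(pos.shape[0])
    for lo in range(0, pos.shape[0], chunk_voxels):
        sl = slice(lo, lo + chunk_voxels)
        tgt = pos[sl][:, None, :] + offs[None, :, :]
        valid = np.all((tgt >= 0) & (tgt < fshape), axis=2)
        flat_idx = (tgt * strides).sum(axis=2)
        np.clip(flat_idx, 0, fine_flat.size - 1, out=flat_idx)
        de = fine_flat[flat_idx]
        cand = dist_term[None, :] + ((de - dref[sl][:, None]) / dd[sl][:, None]) ** 2
        cand[~valid] = np.inf
        best2[sl] = cand.min(axis=1)

    return _result(np.sqrt(best2), mask, ref, criteria)


def average_pass_rate(results) -> float:
    """Arithmetic mean of pass rates (accepts GammaResults or numbers)."""
    rates = [r.pass_rate if isinstance(r, GammaResult) else float(r) for r in results]
    if not rates:
        raise ValueError("average of an empty list of results")
    return float(np.mean(rates))
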