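"""Electron pencil-beam engine: depth dose, lateral profile, radiological depth."""

import numpy as np
import pytest

from ioertdose.applicator import ApplicatorPose, ApplicatorSpec
from ioertdose.core import AIR_HU, CTVolume, DensityVolume, hu_to_density
from ioertdose.dose import (
    BeamSpec,
    PDDModel,
    absolute_scale,
    compute_dose,
    lateral_factor,
    pdd,
    radiological_depth,
)
from ioertdose.errors import ConfigError, GeometryError


@pytest.fixture(scope="module")
def model():
    return PDDModel.default()


def _water_beam(shape=(64, 64, 96), bevel=0.0, diameter=7.0, z_bevel=20.0,
                body_hu=0.0):
    vals = np.full(shape, body_hu, dtype=np.float32)
    ct = CTVolume(vals, (1.5, 1.5, 1.5))
    spec = ApplicatorSpec(diameter, bevel)
    centre = [shape[0] * 1.5 / 2, shape[1] * 1.5 / 2, z_bevel]
    pose = ApplicatorPose(centre, [0, 0, 1], 0, roll_undefined=(bevel == 0))
    return ct, BeamSpec(9.0, spec, pose)


class TestRadiologicalDepth:
    def test_homogeneous_water_equals_geometric(self, model):
        ct, beam = _water_beam()
        density = hu_to_density(ct)
        pt = np.array([48.0, 48.0, 50.0])  # 30 mm deep on-axis
        z = radiological_depth(density, pt, beam)[0]
        assert z == pytest.approx(30.0, rel=0.01)

    def test_air_then_water(self, model):
        # 10 mm air gap then water: point 20 mm below the bevel plane
        # (fine 0.5 mm grid keeps the interpolated air/water boundary sharp)
        vals = np.full((64, 64, 100), 0.0, dtype=np.float32)
        vals[:, :, :40] = AIR_HU  # air until z = 20 mm
        ct = CTVolume(vals, (0.5, 0.5, 0.5))
        spec = ApplicatorSpec(4.0, 0.0)
        pose = ApplicatorPose([16, 16, 10.0], [0, 0, 1], 0, roll_undefined=True)
        beam = BeamSpec(9.0, spec, pose)
        z = radiological_depth(hu_to_density(ct), [16.0, 16.0, 30.0], beam)[0]
        # ~10 mm air (rho 0.00121) + 10 mm water
        assert z == pytest.approx(10.0 + 10.0 * 0.00121, abs=0.4)

    def test_dense_slab_piecewise_arithmetic(self, model):
        # density-1.5 slab from 5-15 mm depth, point at 20 mm: 5 + 15 + 5 mm w.e.
        vals = np.zeros((64, 64, 96), dtype=np.float32)
        dens = hu_to_density(CTVolume(vals, (1.5, 1.5, 1.5))).values.copy()
        zmm = np.arange(96) * 1.5
        slab = (zmm >= 25.0) & (zmm < 35.0)  # bevel at z=20 -> depth 5..15
        dens[:, :, slab] = 1.5
        density = DensityVolume(dens, (1.5, 1.5, 1.5))
        spec = ApplicatorSpec(7.0, 0.0)
        pose = ApplicatorPose([48, 48, 20.0], [0, 0, 1], 0, roll_undefined=True)
        beam = BeamSpec(9.0, spec, pose)
        z = radiological_depth(density, [48.0, 48.0, 40.0], beam, step_mm=0.25)[0]
        assert z == pytest.approx(25.0, abs=0.8)

    def test_proximal_point_rejected(self, model):
        ct, beam = _water_beam()
        with pytest.raises(GeometryError):
            radiological_depth(hu_to_density(ct), [48.0, 48.0, 10.0], beam)


class TestPDD:
    @pytest.mark.parametrize("energy", [6.0, 9.0, 12.0])
    def test_anchor_values(self, model, energy):
        p = model.params(energy)
        assert pdd(model, energy, p["r100_mm"]) == pytest.approx(1.0, abs=1e-9)
        assert pdd(model, energy, p["r90_mm"]) == pytest.approx(0.90, abs=1e-9)
        assert pdd(model, energy, p["r50_mm"]) == pytest.approx(0.50, abs=1e-9)
        assert pdd(model, energy, 0.0) == pytest.approx(p["surface"], abs=1e-9)

    def test_midpoint_matches_independent_spline(self, model):
        # independently rebuild the shipped monotone cubic from the anchors
        from scipy.interpolate import PchipInterpolator

        p = model.params(9.0)
        knots_z = [0.0, p["r100_mm"], p["r90_mm"], p["r50_mm"], p["rp_mm"],
                   p["rp_mm"] + 15.0]
        knots_d = [p["surface"], 1.0, 0.9, 0.5, p["tail"] + 0.015, p["tail"]]
        oracle = PchipInterpolator(knots_z, knots_d)
        z = (p["r90_mm"] + p["r50_mm"]) / 2.0
        assert pdd(model, 9.0, z) == pytest.approx(float(oracle(z)), rel=1e-12)

    def test_monotone_beyond_peak(self, model):
        p = model.params(9.0)
        z = np.linspace(p["r100_mm"], p["rp_mm"] + 30, 300)
        vals = pdd(model, 9.0, z)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_unknown_energy_raises(self, model):
        with pytest.raises(ConfigError):
            pdd(model, 21.0, 10.0)

    def test_negative_depth_rejected(self, model):
        with pytest.raises(ValueError):
            pdd(model, 9.0, -1.0)


class TestLateralFactor:
    def test_on_axis_unity(self):
        assert lateral_factor(0.0, 20.0, 35.0) == pytest.approx(1.0, abs=1e-6)

    def test_half_at_projected_edge(self):
        assert lateral_factor(35.0, 20.0, 35.0) == pytest.approx(0.5, abs=1e-12)

    def test_edge_profile_integral_matches_erf(self):
        # integral of the erfc edge over a symmetric window equals the
        # closed-form antiderivative of 0.5*erfc
        from scipy.integrate import quad
        from scipy.special import erfc

        sigma = 2.5
        R = 35.0
        f = lambda r: lateral_factor(r, 0.0, R, sigma=sigma)
        got, _ = quad(f, R - 10, R + 10, limit=200)
        s = np.sqrt(2.0) * sigma
        anti = lambda x: 0.5 * (x * erfc(x / s) - s / np.sqrt(np.pi) * np.exp(-(x / s) ** 2))
        expected = anti(10.0) - anti(-10.0)
        assert got == pytest.approx(expected, abs=1e-6)


class TestComputeDose:
    def test_central_axis_reproduces_pdd(self, model):
        ct, beam = _water_beam()
        d = compute_dose(ct, beam, model)
        z = np.arange(96) * 1.5 - 20.0
        sel = (z > 1) & (z < 60)
        prof = d.values[32, 32, sel]
        corr = prof * ((1000.0 + z[sel]) / 1000.0) ** 2  # divide out inverse-square
        expected = pdd(model, 9.0, z[sel])
        np.testing.assert_allclose(corr / corr.max(), expected / expected.max(),
                                   atol=1e-4)

    def test_air_gap_shifts_depth_not_pdd_and_broadens_penumbra(self, model):
        # 10 mm uniform air gap vs zero gap over a flat water body, on a fine
        # 0.75 mm grid so the interpolated air/water boundary stays sharp
        shape = (80, 80, 110)
        sp = 0.75
        water = np.zeros(shape, dtype=np.float32)
        gap = water.copy()
        k = int(30 / sp)
        gap[:, :, :k] = AIR_HU  # water starts at z = 30 mm
        cx = shape[0] * sp / 2
        spec = ApplicatorSpec(4.0, 0.0)
        pose0 = ApplicatorPose([cx, cx, 30.0], [0, 0, 1], 0, roll_undefined=True)
        poseg = ApplicatorPose([cx, cx, 20.0], [0, 0, 1], 0, roll_undefined=True)
        d0 = compute_dose(CTVolume(water, (sp,) * 3), BeamSpec(9.0, spec, pose0), model)
        dg = compute_dose(CTVolume(gap, (sp,) * 3), BeamSpec(9.0, spec, poseg), model)
        z = np.arange(shape[2]) * sp
        mid = shape[0] // 2

        def depth90(d):
            prof = d.values[mid, mid, :]
            pk = prof.argmax()
            below = np.where(prof[pk:] <= 90.0)[0][0] + pk
            f = (90.0 - prof[below - 1]) / (prof[below] - prof[below - 1])
            return (z[below - 1] + f * sp) - 30.0  # depth below water surface

        assert abs(depth90(d0) - depth90(dg)) < 0.5
        # penumbra: lateral 80-20 distance just below the water surface grows
        krow = k + 2

        def penumbra(d):
            prof = d.values[:, mid, krow]
            x = np.arange(shape[0]) * sp
            hi = np.interp(-0.8 * prof.max(), -prof[mid:], x[mid:])
            lo = np.interp(-0.2 * prof.max(), -prof[mid:], x[mid:])
            return lo - hi

        assert penumbra(dg) > penumbra(d0)

    def test_curved_bed_curves_the_90_isodose(self, model, still_phantom):
        cfg, case = still_phantom
        beam = BeamSpec(9.0, cfg.spec, case.truth.pose)
        d = compute_dose(case.intraop, beam, PDDModel.default(energies=(9.0,)))
        # depth of the 90% isodose below the bevel plane varies across the
        # field because the irradiation surface is irregular
        i0 = int(case.truth.pose.bevel_centre[0] / 1.5)
        j0 = int(case.truth.pose.bevel_centre[1] / 1.5)
        depths = []
        for di in (-12, -6, 0, 6, 12):
            prof = d.values[i0 + di, j0, :]
            if prof.max() < 90:
                continue
            pk = prof.argmax()
            below = np.where(prof[pk:] <= 90.0)[0]
            if len(below):
                depths.append((pk + below[0]) * 1.5)
        assert len(depths) >= 3
        assert max(depths) - min(depths) > 3.0

    def test_deterministic(self, model, still_phantom):
        cfg, case = still_phantom
        beam = BeamSpec(9.0, cfg.spec, case.truth.pose)
        m = PDDModel.default(energies=(9.0,))
        a = compute_dose(case.intraop, beam, m)
        b = compute_dose(case.intraop, beam, m)
        np.testing.assert_array_equal(a.values, b.values)

    def test_non_increasing_beyond_r100_in_water(self, model):
        ct, beam = _water_beam()
        d = compute_dose(ct, beam, model)
        p = model.params(9.0)
        z = np.arange(96) * 1.5 - 20.0
        sel = z > p["r100_mm"] + 1.5
        prof = d.values[32, 32, sel]
        assert np.all(np.diff(prof) <= 1e-6)

    def test_beam_missing_grid_raises(self, model):
        ct = CTVolume(np.zeros((16, 16, 16), dtype=np.float32), (1.5, 1.5, 1.5))
        spec = ApplicatorSpec(7.0, 0.0)
        pose = ApplicatorPose([500.0, 500.0, 500.0], [0, 0, 1], 0, roll_undefined=True)
        with pytest.raises(GeometryError):
            compute_dose(ct, BeamSpec(9.0, spec, pose), model)


class TestAbsoluteScale:
    def test_prescription_at_90_percent(self):
        from ioertdose.dose import DoseGrid

        d = DoseGrid(np.array([[[90.0]]]), (1.5, 1.5, 1.5), (0, 0, 0))
        assert absolute_scale(d, 10.0)[0, 0, 0] == pytest.approx(10.0)

    def test_maximum_voxel(self):
        from ioertdose.dose import DoseGrid

        d = DoseGrid(np.array([[[100.0, 0.0]]]), (1.5, 1.5, 1.5), (0, 0, 0))
        gy = absolute_scale(d, 12.5)
        assert gy[0, 0, 0] == pytest.approx(13.888888, rel=1e-6)
        assert gy[0, 0, 1] == 0.0
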