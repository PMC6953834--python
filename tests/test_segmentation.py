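"""Region growing and the derived bone / air-gap / wall / body segmentations."""

import numpy as np
import pytest

from ioertdose.applicator import ApplicatorPose, ApplicatorSpec
from ioertdose.core import AIR_HU, CTVolume, Mask, dice
from ioertdose.errors import SeedError, SegmentationError
from ioertdose.phantom import PhantomConfig, generate_phantom
from ioertdose.segmentation import (
    body_mask,
    max_air_gap_distance,
    region_grow,
    segment_air_gap,
    segment_applicator_wall,
    segment_bone,
)


def flood_fill_oracle(window, seeds, connectivity):
    """Brute-force BFS flood fill, independent of scipy labelling."""
    from collections import deque

    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                 if (i, j, k) != (0, 0, 0)]
    out = np.zeros_like(window)
    q = deque(tuple(s) for s in seeds if window[tuple(s)])
    for s in q:
        out[s] = True
    while q:
        c = q.popleft()
        for d in neigh:
            n = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
            if all(0 <= n[a] < window.shape[a] for a in range(3)):
                if window[n] and not out[n]:
                    out[n] = True
                    q.append(n)
    return out


class TestRegionGrow:
    def test_uniform_volume_fills_everything(self):
        vol = CTVolume(np.full((10, 10, 10), 50.0, dtype=np.float32))
        m = region_grow(vol, [(5, 5, 5)], hu_min=0, hu_max=100)
        assert m.values.all()

    def test_shell_confines_growth(self):
        vals = np.full((20, 20, 20), 50.0, dtype=np.float32)
        vals[5, 5:15, 5:15] = vals[14, 5:15, 5:15] = 500.0
        vals[5:15, 5, 5:15] = vals[5:15, 14, 5:15] = 500.0
        vals[5:15, 5:15, 5] = vals[5:15, 5:15, 14] = 500.0
        vol = CTVolume(vals)
        m = region_grow(vol, [(10, 10, 10)], hu_min=0, hu_max=100)
        assert m.values[10, 10, 10]
        assert not m.values[2, 2, 2]  # outside the closed shell

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        from scipy import ndimage

        blob = ndimage.gaussian_filter(rng.normal(0, 1, (18, 18, 18)), 1.5)
        vals = (blob * 400).astype(np.float32)
        vol = CTVolume(vals)
        window = (vals >= 50).astype(bool)
        seeds = np.argwhere(window)[::50]
        if len(seeds) == 0:
            pytest.skip("no seed in window")
        got = region_grow(vol, seeds, hu_min=50, connectivity=connectivity)
        expected = flood_fill_oracle(window, seeds, connectivity)
        np.testing.assert_array_equal(got.values, expected)

    def test_seed_invariant_within_component(self, rng):
        from scipy import ndimage

        blob = ndimage.gaussian_filter(rng.normal(0, 1, (16, 16, 16)), 2.0)
        vol = CTVolume((blob * 300).astype(np.float32))
        window = vol.values >= 30
        comp = np.argwhere(window)
        if len(comp) < 2:
            pytest.skip("degenerate field")
        labels, _ = __import__("scipy.ndimage", fromlist=["label"]).label(window)
        lab = labels[tuple(comp[0])]
        same = [tuple(c) for c in comp if labels[tuple(c)] == lab]
        a = region_grow(vol, [same[0]], hu_min=30)
        b = region_grow(vol, [same[-1]], hu_min=30)
        np.testing.assert_array_equal(a.values, b.values)

    def test_constraint_monotone(self, rng):
        vol = CTVolume((rng.uniform(0, 100, (12, 12, 12))).astype(np.float32))
        small = np.zeros(vol.shape, bool)
        small[3:8, 3:8, 3:8] = True
        big = small.copy()
        big[2:10, 2:10, 2:10] = True
        seed = (5, 5, 5)
        a = region_grow(vol, [seed], hu_min=0, constraint=Mask.like(vol, small))
        b = region_grow(vol, [seed], hu_min=0, constraint=Mask.like(vol, big))
        assert not np.any(a.values & ~b.values)

    def test_seed_outside_window_raises(self):
        vol = CTVolume(np.zeros((8, 8, 8), dtype=np.float32))
        with pytest.raises(SeedError):
            region_grow(vol, [(4, 4, 4)], hu_min=100)

    def test_seed_outside_volume_raises(self):
        vol = CTVolume(np.zeros((8, 8, 8), dtype=np.float32))
        with pytest.raises(SeedError):
            region_grow(vol, [(9, 0, 0)], hu_min=-10, hu_max=10)


class TestSegmentBone:
    def test_phantom_bone_recovered(self, moved_phantom):
        _, case = moved_phantom
        bone = segment_bone(case.intraop)
        assert dice(bone, case.truth.bone) >= 0.95

    def test_soft_tissue_seed_rejected(self, still_phantom):
        _, case = still_phantom
        # a voxel in soft tissue (40 HU) violates the bone window
        soft = np.argwhere((case.intraop.values > 30) & (case.intraop.values < 50))
        with pytest.raises(SeedError):
            segment_bone(case.intraop, seeds=[tuple(soft[0])])

    def test_constraint_excludes_a_bone(self, still_phantom):
        _, case = still_phantom
        intra = case.intraop
        bones_idx = np.argwhere(case.truth.bone.values)
        x_mid = np.median(bones_idx[:, 0])
        left = Mask.like(intra, np.arange(intra.shape[0])[:, None, None]
                         < x_mid * np.ones(intra.shape, dtype=float))
        seed_left = tuple(bones_idx[bones_idx[:, 0] < x_mid][0])
        m = segment_bone(intra, seeds=[seed_left], constraint=left)
        assert m.count() > 0
        assert not np.any(m.values & ~left.values)

    def test_all_air_fails(self):
        vol = CTVolume(np.full((10, 10, 10), AIR_HU, dtype=np.float32))
        with pytest.raises(SegmentationError):
            segment_bone(vol)


class TestSegmentAirGap:
    def test_known_gap_dice(self, moved_phantom):
        cfg, case = moved_phantom
        gap = segment_air_gap(case.intraop, case.truth.pose, cfg.spec)
        assert dice(gap, case.truth.air_gap) >= 0.95

    def test_zero_standoff_flat_bed_empty(self):
        # flat water slab exactly at the bevel plane of a flat applicator
        vals = np.full((64, 64, 64), AIR_HU, dtype=np.float32)
        vals[:, :, 40:] = 40.0
        vol = CTVolume(vals, (1.5, 1.5, 1.5))
        spec = ApplicatorSpec(5.0, 0.0, tube_length_mm=50.0)
        pose = ApplicatorPose([48, 48, 40 * 1.5], [0, 0, 1], 0, roll_undefined=True)
        gap = segment_air_gap(vol, pose, spec)
        assert gap.count() == 0
        assert max_air_gap_distance(gap, pose, spec) == 0.0

    def test_fluid_pool_excluded(self):
        cfg = PhantomConfig(seed=13, noise_sigma_hu=0.0, fluid_depth_mm=6.0,
                            motion_rotation_deg=(0, 0, 0),
                            motion_translation_mm=(0, 0, 0))
        case = generate_phantom(cfg)
        gap = segment_air_gap(case.intraop, case.truth.pose, cfg.spec)
        # fluid voxels are ~10 HU, above the -500 HU limit: never in the gap
        fluid = np.isclose(case.intraop.values, 10.0)
        assert not np.any(gap.values & fluid)
        assert dice(gap, case.truth.air_gap) >= 0.95

    def test_gap_disjoint_from_body(self, moved_phantom):
        cfg, case = moved_phantom
        gap = segment_air_gap(case.intraop, case.truth.pose, cfg.spec)
        wall = segment_applicator_wall(
            case.intraop, (cfg.resolved_body_centre(), cfg.applicator_axis()), cfg.spec)
        body = body_mask(case.intraop, exclude=wall)
        assert not np.any(gap.values & body.values)


class TestSegmentWall:
    def test_noiseless_wall_covers_truth(self, still_phantom):
        cfg, case = still_phantom
        wall = segment_applicator_wall(
            case.intraop, (cfg.resolved_body_centre(), cfg.applicator_axis()),
            cfg.spec, opening_iterations=0)
        inter = np.logical_and(wall.values, case.truth.applicator_wall.values).sum()
        assert inter / case.truth.applicator_wall.count() >= 0.90

    def test_hint_off_by_5mm_same_result(self, still_phantom):
        cfg, case = still_phantom
        point = cfg.resolved_body_centre()
        a = segment_applicator_wall(case.intraop, (point, cfg.applicator_axis()),
                                    cfg.spec, opening_iterations=0)
        b = segment_applicator_wall(case.intraop, (point + np.array([5.0, 0, 0]),
                                                   cfg.applicator_axis()),
                                    cfg.spec, opening_iterations=0)
        assert dice(a, b) >= 0.999

    def test_no_applicator_fails(self, still_phantom):
        cfg, case = still_phantom
        wall_free = case.preop  # preoperative image has no applicator
        with pytest.raises(SegmentationError):
            segment_applicator_wall(
                wall_free, (cfg.resolved_body_centre(), cfg.applicator_axis()), cfg.spec)


class TestBodyMask:
    def test_phantom_body_dice(self, moved_phantom):
        cfg, case = moved_phantom
        wall = segment_applicator_wall(
            case.intraop, (cfg.resolved_body_centre(), cfg.applicator_axis()), cfg.spec)
        body = body_mask(case.intraop, exclude=wall)
        assert dice(body, case.truth.body) >= 0.99

    def test_all_air_raises(self):
        vol = CTVolume(np.full((8, 8, 8), AIR_HU, dtype=np.float32))
        with pytest.raises(SegmentationError):
            body_mask(vol)

    def test_internal_low_density_region_retained(self):
        vals = np.full((24, 24, 24), AIR_HU, dtype=np.float32)
        vals[4:20, 4:20, 4:20] = 40.0
        vals[10:14, 10:14, 10:14] = -800.0  # enclosed low-density region
        vol = CTVolume(vals)
        body = body_mask(vol)
        assert body.values[11, 11, 11]


class TestMaxAirGap:
    def test_flat_standoff_10mm(self):
        vals = np.full((64, 64, 64), AIR_HU, dtype=np.float32)
        vals[:, :, 40:] = 40.0  # tissue from z = 60 mm
        vol = CTVolume(vals, (1.5, 1.5, 1.5))
        spec = ApplicatorSpec(5.0, 0.0, tube_length_mm=45.0)
        pose = ApplicatorPose([48, 48, 50.0], [0, 0, 1], 0, roll_undefined=True)
        gap = segment_air_gap(vol, pose, spec)
        assert max_air_gap_distance(gap, pose, spec) == pytest.approx(10.0, abs=1.6)

    def test_irregular_bed_matches_surface_oracle(self, still_phantom):
        cfg, case = still_phantom
        gap = segment_air_gap(case.intraop, case.truth.pose, cfg.spec)
        measured = max_air_gap_distance(gap, case.truth.pose, cfg.spec)
        assert measured == pytest.approx(case.truth.max_air_gap_mm, abs=1.5)
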