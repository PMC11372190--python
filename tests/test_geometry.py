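import numpy as np
import pytest

from conftest import cylinder_mask
from helpers import brute_force_nearest_arc, grid_points_mm
from pvat.geometry import (
    Centerline,
    LandmarkSet,
    SECTION_CODES,
    end_deviation,
    extract_centerline,
    project_landmark,
    section_aorta,
)
from pvat.phantom import CurvedCenterline, PhantomConfig, generate_phantom


def axis_centerline(z_lo=0.0, z_hi=99.0, x=20.0, y=20.0, step=1.0):
    z = np.arange(z_lo, z_hi + step / 2, step)
    return Centerline(points=np.column_stack([np.full_like(z, x), np.full_like(z, y), z]))


class TestExtractCenterline:
    def test_straight_cylinder_recovers_axis(self):
        mask = cylinder_mask(shape=(40, 40, 60), radius=5.0, center=(20, 20))
        cl = extract_centerline(mask, (1.0, 1.0, 1.0))
        assert np.abs(cl.points[:, :2] - 20.0).max() <= 0.5
        assert cl.length == pytest.approx(59.0, abs=3.0)
        # every point lies inside the mask
        idx = np.round(cl.points).astype(int)
        assert mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_anisotropic_spacing_gives_physical_length(self):
        spacing = (0.7, 0.7, 2.0)
        mask = cylinder_mask(shape=(30, 30, 25), radius=7.0, center=(15, 15))
        cl = extract_centerline(mask, spacing)
        assert cl.length == pytest.approx(24 * 2.0, abs=2 * 2.0)
        assert np.abs(cl.points[:, :2] - 15 * 0.7).max() <= 0.5 * 0.7 + 1e-9

    def test_curved_phantom_length_within_5pct(self):
        cfg = PhantomConfig(
            grid_shape=(64, 57, 80),
            centerline=CurvedCenterline(x_mm=32, y_mm=28, amplitude_mm=6, period_mm=70),
        )
        vol, truth = generate_phantom(cfg)
        cl = extract_centerline(truth.segmentation, vol.spacing)
        assert cl.length == pytest.approx(truth.path_length_mm, rel=0.05)

    def test_empty_and_fragmented_masks_raise(self):
        with pytest.raises(ValueError, match="empty"):
            extract_centerline(np.zeros((10, 10, 10), bool), (1, 1, 1))
        two = np.zeros((40, 40, 30), bool)
        two[5:10, 5:10, 5:25] = True  # 2000 voxels
        two[25:30, 25:30, 5:25] = True
        with pytest.raises(ValueError, match="sizes"):
            extract_centerline(two, (1, 1, 1))


class TestProjectLandmark:
    def test_first_point_projects_to_zero(self):
        cl = axis_centerline()
        assert project_landmark(cl, cl.points[0]) == 0.0

    def test_tie_resolves_to_smaller_arc_length(self):
        cl = axis_centerline(step=1.0)
        # equidistant from the points at z = 10 and z = 11
        assert project_landmark(cl, [20.0, 20.0, 10.5]) == 10.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        cfg = PhantomConfig(
            grid_shape=(48, 48, 60),
            centerline=CurvedCenterline(x_mm=24, y_mm=24, amplitude_mm=5, period_mm=60),
        )
        _, truth = generate_phantom(cfg)
        cl = Centerline(points=truth.centerline_points)
        for _ in range(50):
            p = rng.uniform(0, 48, size=3)
            expected = brute_force_nearest_arc(p[None, :], cl.points, cl.arc_length)[0]
            assert project_landmark(cl, p) == expected


class TestSectionAorta:
    def landmarks_aaa(self, x=20.0, y=20.0):
        return LandmarkSet(
            {
                "aortic_bifurcation": [x, y, 0.0],
                "coeliac_trunk": [x, y, 99.0],
                "aaa_inferior_end": [x, y, 20.0],
                "aaa_superior_end": [x, y, 60.0],
            }
        )

    def test_straight_tube_sections_equal_axial_intervals(self):
        mask = cylinder_mask(shape=(40, 40, 100), radius=5.0)
        cl = axis_centerline()
        sec = section_aorta(mask, (1, 1, 1), cl, self.landmarks_aaa())
        zz = np.arange(100)[None, None, :] * np.ones_like(mask, dtype=int)
        in_mask_an = sec.labels[mask] == SECTION_CODES["aneurysmal"]
        axial_an = (zz[mask] >= 20) & (zz[mask] <= 60)
        assert np.array_equal(in_mask_an, axial_an)

    def test_control_infrarenal_interval(self):
        mask = cylinder_mask(shape=(40, 40, 100), radius=5.0)
        cl = axis_centerline()
        lms = LandmarkSet(
            {"aortic_bifurcation": [20, 20, 0.0], "right_renal_junction": [20, 20, 80.0]}
        )
        sec = section_aorta(mask, (1, 1, 1), cl, lms)
        zz = np.arange(100)[None, None, :] * np.ones_like(mask, dtype=int)
        in_mask_ir = sec.labels[mask] == SECTION_CODES["infrarenal"]
        assert np.array_equal(in_mask_ir, zz[mask] <= 80)

    def test_mask_voxels_partition_into_single_labels(self, aaa_phantom):
        cfg, vol, truth = aaa_phantom
        cl = extract_centerline(truth.segmentation, vol.spacing)
        sec = section_aorta(truth.segmentation, vol.spacing, cl, LandmarkSet(truth.landmarks))
        labels = sec.labels[truth.segmentation]
        assert set(np.unique(labels)) <= set(SECTION_CODES.values())
        n_sections = sum(
            np.count_nonzero(labels == SECTION_CODES[name]) for name in sec.intervals
        )
        n_other = np.count_nonzero(labels == SECTION_CODES["other"])
        assert n_sections + n_other == labels.size  # one label per voxel

    def test_labels_match_exhaustive_nearest_point_assignment(self):
        cfg = PhantomConfig(
            grid_shape=(36, 36, 40),
            lumen_radius_mm=5.0,
            centerline=CurvedCenterline(x_mm=18, y_mm=18, amplitude_mm=4, period_mm=50),
            aneurysm=None,
        )
        vol, truth = generate_phantom(cfg)
        cl = extract_centerline(truth.segmentation, vol.spacing)
        lms = LandmarkSet(truth.landmarks)
        sec = section_aorta(truth.segmentation, vol.spacing, cl, lms)
        pts = grid_points_mm(truth.segmentation.shape, vol.spacing)
        arc = brute_force_nearest_arc(pts, sec.centerline.points, sec.centerline.arc_length)
        lo, hi = sec.intervals["infrarenal"]
        expected = np.where(
            (arc >= lo) & (arc <= hi), SECTION_CODES["infrarenal"], SECTION_CODES["other"]
        ).reshape(sec.labels.shape)
        assert np.array_equal(sec.labels, expected)

    def test_rigid_translation_invariance(self):
        mask = cylinder_mask(shape=(40, 40, 80), radius=5.0, center=(15, 15))
        lms = self.landmarks_aaa(x=15.0, y=15.0)
        cl = axis_centerline(z_hi=79.0, x=15.0, y=15.0)
        sec = section_aorta(mask, (1, 1, 1), cl, lms)

        shift = np.array([4, 6, 0])
        mask_t = np.roll(mask, shift, axis=(0, 1, 2))
        pts_t = {k: np.asarray(v, float) + shift for k, v in lms.points.items()}
        cl_t = Centerline(points=cl.points + shift)
        sec_t = section_aorta(mask_t, (1, 1, 1), cl_t, LandmarkSet(pts_t))
        assert np.array_equal(
            np.roll(sec.labels, shift, axis=(0, 1, 2))[mask_t], sec_t.labels[mask_t]
        )

    def test_out_of_order_landmarks_raise(self):
        mask = cylinder_mask(shape=(40, 40, 100), radius=5.0)
        cl = axis_centerline()
        lms = LandmarkSet(
            {
                "aortic_bifurcation": [20, 20, 0.0],
                "coeliac_trunk": [20, 20, 99.0],
                "aaa_inferior_end": [20, 20, 60.0],
                "aaa_superior_end": [20, 20, 20.0],
            }
        )
        with pytest.raises(ValueError, match="superior end"):
            section_aorta(mask, (1, 1, 1), cl, lms)

    def test_incomplete_landmark_set_rejected(self):
        with pytest.raises(ValueError, match="neither"):
            LandmarkSet({"aortic_bifurcation": [0, 0, 0]}).kind


class TestEndDeviation:
    def test_identical_sets_give_zero(self):
        cl = axis_centerline()
        lms = LandmarkSet(
            {
                "aortic_bifurcation": [20, 20, 0.0],
                "coeliac_trunk": [20, 20, 99.0],
                "aaa_inferior_end": [20, 20, 20.0],
                "aaa_superior_end": [20, 20, 60.0],
            }
        )
        dev = end_deviation(cl, lms, lms)
        assert dev == {"inferior": 0.0, "superior": 0.0, "mean": 0.0}

    def test_straight_tube_axial_shift_is_recovered(self):
        cl = axis_centerline()
        truth = LandmarkSet(
            {"aaa_inferior_end": [20, 20, 20.0], "aaa_superior_end": [20, 20, 60.0]}
        )
        pred = LandmarkSet(
            {"aaa_inferior_end": [20, 20, 23.0], "aaa_superior_end": [20, 20, 57.0]}
        )
        dev = end_deviation(cl, pred, truth)
        assert dev["inferior"] == pytest.approx(3.0)
        assert dev["superior"] == pytest.approx(3.0)
        assert dev["mean"] == pytest.approx(3.0)

    def test_curved_tube_matches_projection_oracle(self):
        cfg = PhantomConfig(
            grid_shape=(48, 48, 60),
            centerline=CurvedCenterline(x_mm=24, y_mm=24, amplitude_mm=5, period_mm=60),
        )
        _, truth = generate_phantom(cfg)
        cl = Centerline(points=truth.centerline_points)
        rng = np.random.default_rng(9)
        t = LandmarkSet(
            {"aaa_inferior_end": rng.uniform(10, 40, 3), "aaa_superior_end": rng.uniform(10, 40, 3)}
        )
        p = LandmarkSet(
            {"aaa_inferior_end": rng.uniform(10, 40, 3), "aaa_superior_end": rng.uniform(10, 40, 3)}
        )
        dev = end_deviation(cl, p, t)
        for role, key in (("aaa_inferior_end", "inferior"), ("aaa_superior_end", "superior")):
            s_p = brute_force_nearest_arc(
                np.asarray(p[role])[None, :], cl.points, cl.arc_length
            )[0]
            s_t = brute_force_nearest_arc(
                np.asarray(t[role])[None, :], cl.points, cl.arc_length
            )[0]
            assert dev[key] == pytest.approx(abs(s_p - s_t))

    def test_missing_ends_raise(self):
        cl = axis_centerline()
        lms = LandmarkSet({"aaa_inferior_end": [20, 20, 20.0]})
        with pytest.raises(ValueError, match="aaa_superior_end"):
            end_deviation(cl, lms, lms)
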