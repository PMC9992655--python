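"""µCT pipeline: each stage against generator ground truth."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ommatidia.errors import EmptySelectionError, IllConditionedError
from ommatidia.oda3d import (
    EyePointCloud,
    assign_clusters,
    cloud_from_stack,
    correct_problem_clusters,
    export_spreadsheets,
    fit_sphere,
    make_cross_section,
    measure_io_pairs,
    partition_objective,
    rasterize_and_detect,
    run_pipeline,
    summarize,
)
from ommatidia.synth import (
    SyntheticEyeSpec,
    make_synthetic_eye3d,
    voxelize,
)


def _sphere_samples(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    v[:, 0] = np.abs(v[:, 0])  # hemisphere, as for a real eye scan
    return radius * v


class TestLoadStack:
    def test_density_selection_matches_generator_membership(self):
        spec = SyntheticEyeSpec(extent_deg=(15, 15), noise_sigma=0.0)
        eye = make_synthetic_eye3d(spec)
        stack, origin = voxelize(eye.points, voxel_size=5.0)
        cloud = cloud_from_stack(stack, 5.0, density_range=(100, 255))
        # every selected voxel contains at least one generated point
        sel = np.floor((eye.points - origin) / 5.0).astype(int)
        expected = {tuple(i) for i in sel}
        got = {tuple(i) for i in np.round(cloud.coords / 5.0 - 0.0).astype(int)}
        assert got == expected
        assert np.all(cloud.density == 200)

    def test_out_of_range_selection_errors_with_bounds(self):
        stack = np.full((4, 8, 8), 10, dtype=np.uint8)
        with pytest.raises(EmptySelectionError, match="300"):
            cloud_from_stack(stack, 1.0, density_range=(300, 400))

    def test_voxel_size_scales_coordinates(self):
        stack = np.zeros((3, 4, 5), dtype=np.uint8)
        stack[2, 3, 4] = 200
        cloud = cloud_from_stack(stack, 5.0, density_range=(100, 255))
        np.testing.assert_array_equal(cloud.coords, [[20.0, 15.0, 10.0]])


class TestFitSphere:
    def test_exact_recovery_on_noiseless_shell(self):
        pts = _sphere_samples(500, 100.0)
        fit = fit_sphere(pts)
        assert fit.radius == pytest.approx(100.0, abs=1e-6)
        np.testing.assert_allclose(fit.center, 0.0, atol=1e-6)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-6)

    def test_recovery_under_isotropic_noise(self):
        rng = np.random.default_rng(101)  # independent of the shell draws
        pts = _sphere_samples(2000, 100.0, seed=1) + rng.normal(0, 1.0, (2000, 3))
        fit = fit_sphere(pts)
        assert fit.radius == pytest.approx(100.0, abs=0.5)

    def test_translated_shell_recovers_center(self):
        pts = _sphere_samples(500, 50.0) + np.array([10.0, -20.0, 5.0])
        fit = fit_sphere(pts)
        np.testing.assert_allclose(fit.center, [10.0, -20.0, 5.0], atol=1e-6)

    def test_coplanar_points_are_degenerate(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.random((10, 2)) * 100, np.zeros(10)])
        with pytest.raises(IllConditionedError):
            fit_sphere(pts)


class TestCrossSection:
    def test_zero_thickness_shell_has_zero_residuals(self):
        pts = _sphere_samples(800, 200.0, seed=3)
        cloud = EyePointCloud(coords=pts)
        section = make_cross_section(cloud, fit_sphere(cloud))
        assert np.abs(section.surface_residuals).max() < 1e-3 * 200.0
        assert len(section.members) == 400

    def test_member_fraction_is_half_on_random_clouds(self):
        rng = np.random.default_rng(4)
        for n in (101, 500, 1234):
            pts = _sphere_samples(n, 100.0, seed=n) * rng.uniform(
                0.9, 1.1, size=(n, 1)
            )
            cloud = EyePointCloud(coords=pts)
            section = make_cross_section(cloud, fit_sphere(cloud))
            assert abs(len(section.members) / n - 0.5) <= 1.0 / n

    def test_uniform_thickness_members_span_central_band(self):
        rng = np.random.default_rng(5)
        n = 20000
        base = _sphere_samples(n, 100.0, seed=6)
        radii = rng.uniform(90.0, 110.0, n)
        pts = base / 100.0 * radii[:, None]
        cloud = EyePointCloud(coords=pts)
        section = make_cross_section(cloud, fit_sphere(cloud))
        member_r = np.linalg.norm(pts[section.members], axis=1)
        # central 50% of a uniform 20 µm band is the middle 10 µm
        assert np.percentile(member_r, 1) > 94.0
        assert np.percentile(member_r, 99) < 106.0

    def test_members_are_exactly_central_residual_half(self, spherical_run):
        section = spherical_run["section"]
        n = len(section.surface_residuals)
        lo = np.sort(section.surface_residuals)[n // 4]
        hi = np.sort(section.surface_residuals)[n // 4 + n // 2 - 1]
        member_res = section.surface_residuals[section.members]
        assert member_res.min() >= lo - 1e-9
        assert member_res.max() <= hi + 1e-9
        assert len(section.members) == n // 2


class TestRasterizeAndDetect:
    def test_center_count_matches_generator(self, spherical_run):
        eye = spherical_run["eye"]
        centers = rasterize_and_detect(spherical_run["section"])
        assert abs(len(centers) - eye.n_cones) <= 0.02 * eye.n_cones

    def test_single_vs_four_segments_agree(self, spherical_run):
        section = spherical_run["section"]
        one = rasterize_and_detect(section, window_deg=90.0)
        four = rasterize_and_detect(section, window_deg=23.0)
        assert abs(len(one) - len(four)) <= 0.01 * len(one)

    def test_empty_section_yields_no_centers(self, spherical_run):
        import dataclasses

        section = dataclasses.replace(
            spherical_run["section"], members=np.array([], dtype=int)
        )
        assert rasterize_and_detect(section).shape == (0, 3)


class TestAssignClusters:
    def test_zero_skew_assignment_matches_generator(self, spherical_run):
        eye = spherical_run["eye"]
        clusters = spherical_run["clusters"]
        d, idx = cKDTree(eye.centroids).query(clusters.centroids)
        mapped = idx[clusters.labels]
        assert (mapped == eye.labels).mean() >= 0.99

    def test_two_separated_cones_partition_perfectly(self):
        rng = np.random.default_rng(7)
        a = np.array([500.0, 0.0, 0.0]) + rng.normal(0, 1, (50, 3))
        b = np.array([500.0, 40.0, 0.0]) + rng.normal(0, 1, (50, 3))
        cloud = EyePointCloud(coords=np.vstack([a, b]))
        # use a plain sphere about the origin so angles are well defined
        from ommatidia.oda3d import SphereFit

        sphere = SphereFit(
            center=np.zeros(3), radius=500.0,
            residuals=np.zeros(100),
        )
        section = make_cross_section(cloud, sphere)
        clusters = assign_clusters(
            section, np.array([[500.0, 0.0, 0.0], [500.0, 40.0, 0.0]])
        )
        assert (clusters.labels[:50] == clusters.labels[0]).all()
        assert (clusters.labels[50:] == clusters.labels[50]).all()
        assert clusters.labels[0] != clusters.labels[50]

    def test_single_center_takes_all_points(self, spherical_run):
        section = spherical_run["section"]
        clusters = assign_clusters(section, section.cloud.coords[:1])
        assert (clusters.labels == 0).all()


class TestCorrectProblemClusters:
    def test_clean_eye_is_left_unchanged(self):
        spec = SyntheticEyeSpec(
            lens_diameter=25, radius_h=800, radius_v=800, extent_deg=(25, 25),
            seed=8,
        )
        eye = make_synthetic_eye3d(spec)
        cloud = EyePointCloud(coords=eye.points)
        sphere = fit_sphere(cloud)
        section = make_cross_section(cloud, sphere)
        clusters = assign_clusters(section, rasterize_and_detect(section))
        fixed = correct_problem_clusters(clusters, section, seed=0)
        assert fixed.problematic.sum() == 0
        np.testing.assert_array_equal(fixed.labels, clusters.labels)

    def test_skewed_oval_eye_flag_count_strictly_decreases(self):
        # 20 degrees of uniform skew on an oval eye: projected clusters
        # overlap enough that the nearest-centre pass splits several cones
        spec = SyntheticEyeSpec(
            lens_diameter=20, radius_h=500, radius_v=1500,
            extent_deg=(50, 16), skew=20.0, seed=5,
        )
        eye = make_synthetic_eye3d(spec)
        cloud = EyePointCloud(coords=eye.points)
        sphere = fit_sphere(cloud)
        section = make_cross_section(cloud, sphere)
        clusters = assign_clusters(section, rasterize_and_detect(section))
        from ommatidia.oda3d import _misneighbor_fractions

        before = (
            _misneighbor_fractions(
                cloud.coords, clusters.labels, clusters.n_clusters
            )
            >= 0.10
        ).sum()
        fixed = correct_problem_clusters(clusters, section, seed=1)
        assert before > 0
        assert fixed.problematic.sum() < before

    def test_objective_of_isotropic_equidistant_cluster(self):
        # octahedron vertices: all points equidistant from the centre and
        # the spread is isotropic, so the aspect-ratio term is exactly 1
        pts = np.array(
            [[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0],
             [0, -1.0, 0], [0, 0, 1.0], [0, 0, -1.0]]
        )
        labels = np.zeros(len(pts), dtype=int)
        obj = partition_objective(pts, labels, np.array([1.0, 0.0, 0.0]))
        mean_proj_dist = np.linalg.norm(
            pts[:, 1:] - pts[:, 1:].mean(axis=0), axis=1
        ).mean()
        assert obj == pytest.approx(mean_proj_dist + 1.0, rel=1e-6)


class TestMeasureOmmatidia:
    def test_zero_skew_eye_recovers_diameter_and_low_skew(self, spherical_run):
        records = spherical_run["records"]
        D = np.array([r.diameter_um for r in records])
        skews = np.array([r.skewness_deg for r in records])
        assert D.mean() == pytest.approx(20.0, rel=0.05)
        assert np.nanmedian(skews) < 2.0

    def test_tilted_cones_recover_tilt_angle(self):
        spec = SyntheticEyeSpec(
            lens_diameter=20, radius_h=1000, radius_v=1000,
            extent_deg=(40, 40), skew=10.0, seed=9,
        )
        eye = make_synthetic_eye3d(spec)
        records, _, _, _ = run_pipeline(EyePointCloud(coords=eye.points))
        skews = np.array([r.skewness_deg for r in records])
        assert np.nanmedian(skews) == pytest.approx(10.0, abs=2.0)

    def test_adjusted_diameter_never_exceeds_diameter(self, spherical_run):
        for r in spherical_run["records"]:
            assert r.adjusted_diameter_um <= r.diameter_um + 1e-9

    def test_axes_are_unit_norm_and_outward(self, spherical_run):
        section = spherical_run["section"]
        for r in spherical_run["records"]:
            assert np.linalg.norm(r.anatomical_axis) == pytest.approx(1.0)
            assert np.linalg.norm(r.ideal_axis) == pytest.approx(1.0)
            outward = r.centroid - section.sphere.center
            assert r.ideal_axis @ outward > 0


class TestMeasureIoPairs:
    def test_median_io_matches_spherical_formula(self, spherical_run):
        from ommatidia.optics import spherical_io_angle

        pairs = spherical_run["pairs"]
        total = np.median(
            [p.io_total_deg for p in pairs if not p.outlier]
        )
        expected = spherical_io_angle(20.0, 1000.0)
        assert total == pytest.approx(expected, rel=0.10)

    def test_total_is_hypotenuse_of_components(self, spherical_run):
        for p in spherical_run["pairs"][:200]:
            assert p.io_total_deg == pytest.approx(
                np.hypot(p.io_h_deg, p.io_v_deg)
            )

    def test_parallel_axes_give_zero_angle(self, spherical_run):
        import copy

        records = [copy.copy(r) for r in spherical_run["records"][:8]]
        axis = records[0].averaged_axis
        for r in records:
            r.averaged_axis = axis
            r.neighbors = tuple(j for j in range(8) if j != r.id and j in
                                [q.id for q in records])
        pairs = measure_io_pairs(records, spherical_run["section"])
        assert all(p.io_total_deg == pytest.approx(0.0, abs=1e-9) for p in pairs)

    def test_orientation_folds_into_half_circle(self, spherical_run):
        for p in spherical_run["pairs"]:
            assert -90.0 < p.orientation_deg <= 90.0


class TestExportAndSummary:
    def test_spreadsheets_roundtrip_and_reference_valid_ids(
        self, tmp_path, spherical_run
    ):
        import pandas as pd

        cone_path, pair_path = export_spreadsheets(
            spherical_run["records"], spherical_run["pairs"],
            str(tmp_path / "eye"),
        )
        cones = pd.read_csv(cone_path)
        pairs = pd.read_csv(pair_path)
        assert len(cones) == len(spherical_run["records"])
        assert len(pairs) == len(spherical_run["pairs"])
        assert set(pairs.cone_i).issubset(set(cones.cone))
        assert set(pairs.cone_j).issubset(set(cones.cone))
        r0 = spherical_run["records"][0]
        assert cones.diameter_um[0] == pytest.approx(r0.diameter_um, rel=1e-6)
        assert cones.x[0] == pytest.approx(r0.centroid[0], rel=1e-6)

    def test_summary_validates_against_schema(self, spherical_run):
        from ommatidia.io import validate_summary
        from ommatidia.optics import world_project

        vf = world_project(
            spherical_run["records"], spherical_run["section"].sphere.center
        )
        summary = summarize(
            spherical_run["records"], spherical_run["pairs"], visual_field=vf
        )
        validate_summary(summary)  # should not raise
        assert summary["count"] == len(spherical_run["records"])


class TestRigidMotionEquivariance:
    def test_scalar_outputs_invariant_under_rotation_translation(self):
        spec = SyntheticEyeSpec(
            lens_diameter=20, radius_h=1000, radius_v=1000,
            extent_deg=(30, 30), seed=10,
        )
        eye = make_synthetic_eye3d(spec)
        rng = np.random.default_rng(42)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = eye.points @ q.T + np.array([123.4, -567.8, 910.1])

        def scalars(points):
            records, pairs, _, _ = run_pipeline(EyePointCloud(coords=points))
            return np.array([
                len(records),
                np.mean([r.diameter_um for r in records]),
                np.nanmedian([r.skewness_deg for r in records]),
                np.median([p.io_total_deg for p in pairs if not p.outlier]),
            ])

        base, shifted = scalars(eye.points), scalars(moved)
        np.testing.assert_allclose(shifted, base, rtol=1e-6)
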