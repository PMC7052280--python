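"""Orthomosaic blending, view geometry, GSD, GCP detection, georeferencing."""

import math

import numpy as np
import pytest

from thermofield import scene_sim as sc
from thermofield import thermal_mosaic as tm
from thermofield import trial_design as td
from thermofield.errors import FitError, GeometryError, InputError, ParameterError

from conftest import make_flat_truth


def constant_frame(value, pose, camera, frame_id=0):
    return sc.ThermalFrame(
        frame_id=frame_id,
        pixels=np.full((camera.n_y, camera.n_x), value, dtype=np.float32),
        pose=pose, timestamp=0.0,
    )


class TestComputeGsd:
    def test_reference_camera_gives_5_5_cm(self):
        assert tm.compute_gsd(80.0, 25.0, 640) * 100 == pytest.approx(5.5, abs=0.05)

    def test_other_axis(self):
        assert tm.compute_gsd(80.0, 20.0, 512) == pytest.approx(0.0551, abs=0.0001)

    def test_zero_altitude(self):
        assert tm.compute_gsd(0.0, 25.0, 640) == 0.0

    def test_wide_fov_rejected(self):
        with pytest.raises(ParameterError):
            tm.compute_gsd(80.0, 180.0, 640)


class TestViewGeometry:
    def test_camera_directly_above(self):
        vg = tm.view_geometry((3.0, 4.0), (3.0, 4.0, 80.0))
        assert vg.zenith_deg == 0.0

    def test_offset_equal_to_altitude_gives_45_degrees(self):
        vg = tm.view_geometry((0.0, 0.0), (80.0, 0.0, 80.0))
        assert vg.zenith_deg == pytest.approx(45.0)

    def test_camera_north_of_point(self):
        vg = tm.view_geometry((0.0, 0.0), (0.0, 10.0, 80.0))
        assert vg.azimuth_deg == pytest.approx(0.0)
        assert vg.zenith_deg == pytest.approx(math.degrees(math.atan(10 / 80)), abs=0.01)

    def test_zero_altitude_rejected(self):
        with pytest.raises(GeometryError):
            tm.view_geometry((0.0, 0.0), (1.0, 1.0, 0.0))


class TestBuildOrthomosaic:
    camera = sc.CameraModel(n_x=64, n_y=52, netd_c=0.0)

    def test_single_frame_identical_across_modes(self, small_scene):
        frame = small_scene["frames"][40]
        cam = small_scene["camera"]
        a = tm.build_orthomosaic([frame], cam, mode="average")
        d = tm.build_orthomosaic([frame], cam, mode="disabled")
        assert np.array_equal(a.temperature, d.temperature, equal_nan=True)

    def test_two_constant_frames_average_and_nearest(self):
        f1 = constant_frame(30.0, (0.0, 0.0, 80.0, 0.0), self.camera, 0)
        f2 = constant_frame(34.0, (5.0, 0.0, 80.0, 0.0), self.camera, 1)
        grid = (-2.0, -2.0, 7.0, 2.0, 0.5)
        avg = tm.build_orthomosaic([f1, f2], self.camera, grid=grid, mode="average")
        overlap = avg.provenance == 2
        assert overlap.any()
        assert np.allclose(avg.temperature[overlap], 32.0)
        dis = tm.build_orthomosaic([f1, f2], self.camera, grid=grid, mode="disabled")
        xs, _ = dis.pixel_centers()
        covered = dis.provenance >= 0
        for i, j in zip(*np.nonzero(covered)):
            want = 0 if abs(xs[j] - 0.0) <= abs(xs[j] - 5.0) else 1
            assert dis.provenance[i, j] == want

    def test_average_equals_bruteforce_mean(self, small_scene):
        """Oracle: exhaustive per-pixel mean over a frame loop."""
        frames = small_scene["frames"][30:38]
        cam = small_scene["camera"]
        mos = tm.build_orthomosaic(frames, cam, mode="average")
        xs, ys = mos.pixel_centers()
        gx, gy = np.meshgrid(xs, ys)
        total = np.zeros(mos.shape)
        count = np.zeros(mos.shape)
        for f in frames:  # independent brute-force accumulation
            vals, valid, _ = tm._frame_sample(f, cam, gx, gy)
            total[valid] += vals[valid]
            count[valid] += 1
        expect = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        assert np.allclose(mos.temperature, expect, equal_nan=True)
        assert np.array_equal(mos.provenance, count.astype(int))

    def test_disabled_winner_has_minimal_zenith(self, small_scene):
        frames = small_scene["frames"][30:38]
        cam = small_scene["camera"]
        mos = tm.build_orthomosaic(frames, cam, mode="disabled")
        xs, ys = mos.pixel_centers()
        rng = np.random.default_rng(0)
        ii, jj = np.nonzero(mos.provenance >= 0)
        pick = rng.choice(len(ii), size=200, replace=False)
        by_id = {f.frame_id: f for f in frames}
        for k in pick:
            i, j = ii[k], jj[k]
            pt = (xs[j], ys[i])
            zeniths = {}
            for f in frames:
                vals, valid, _ = tm._frame_sample(
                    f, cam, np.array([pt[0]]), np.array([pt[1]]))
                if valid[0]:
                    zeniths[f.frame_id] = tm.view_geometry(pt, f.pose).zenith_deg
            winner = mos.provenance[i, j]
            assert winner in zeniths
            assert zeniths[winner] <= min(zeniths.values()) + 1e-9

    def test_constant_scene_constant_mosaic_any_mode(self):
        frames = [constant_frame(30.0, (x, 0.0, 80.0, 0.0), self.camera, k)
                  for k, x in enumerate(np.arange(0, 30, 5.0))]
        for mode in ("average", "disabled"):
            mos = tm.build_orthomosaic(frames, self.camera, mode=mode)
            vals = mos.temperature[np.isfinite(mos.temperature)]
            assert np.allclose(vals, 30.0)

    def test_more_overlap_cannot_decrease_provenance(self):
        grid = (-5.0, -5.0, 20.0, 5.0, 0.5)
        sparse = [constant_frame(30.0, (x, 0.0, 80.0, 0.0), self.camera, k)
                  for k, x in enumerate(np.arange(0, 16, 8.0))]
        dense = [constant_frame(30.0, (x, 0.0, 80.0, 0.0), self.camera, k)
                 for k, x in enumerate(np.arange(0, 16, 2.0))]
        m_sparse = tm.build_orthomosaic(sparse, self.camera, grid=grid, mode="average")
        m_dense = tm.build_orthomosaic(dense, self.camera, grid=grid, mode="average")
        assert (m_dense.provenance >= m_sparse.provenance).all()

    def test_empty_frame_list_rejected(self):
        with pytest.raises(InputError):
            tm.build_orthomosaic([], self.camera)

    def test_grid_outside_footprints_warns_all_nan(self):
        f = constant_frame(30.0, (0.0, 0.0, 80.0, 0.0), self.camera)
        with pytest.warns(UserWarning, match="outside all frame footprints"):
            mos = tm.build_orthomosaic([f], self.camera,
                                       grid=(500.0, 500.0, 510.0, 510.0, 1.0))
        assert np.isnan(mos.temperature).all()

    def test_seamlines_only_in_disabled_overlap(self):
        f1 = constant_frame(30.0, (0.0, 0.0, 80.0, 0.0), self.camera, 0)
        f2 = constant_frame(34.0, (5.0, 0.0, 80.0, 0.0), self.camera, 1)
        dis = tm.build_orthomosaic([f1, f2], self.camera,
                                   grid=(-2.0, -2.0, 7.0, 2.0, 0.5), mode="disabled")
        assert tm.seamline_mask(dis).any()

    def test_tiff_round_trip(self, small_mosaics, tmp_path):
        mos = small_mosaics["average"]
        path = str(tmp_path / "m.tif")
        mos.write_tiff(path)
        back = tm.Orthomosaic.read_tiff(path)
        assert np.allclose(back.temperature, mos.temperature.astype(np.float32),
                           equal_nan=True)
        assert back.gsd == mos.gsd and back.blending_mode == "average"


class TestGeoreference:
    def test_perfect_detections_zero_rmse(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, size=(10, 2))
        res = tm.georeference(pts, pts)
        assert res.rmse_m == pytest.approx(0.0, abs=1e-9)

    def test_uniform_shift_absorbed(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 50, size=(8, 2))
        res = tm.georeference(pts + np.array([1.0, 1.0]), pts)
        assert res.rmse_m == pytest.approx(0.0, abs=1e-9)
        assert res.shift == pytest.approx((-1.0, -1.0), abs=1e-9)

    def test_monte_carlo_rmse_matches_bruteforce_oracle(self):
        """Residual RMSE under isotropic detection noise, compared against an
        independent least-squares simulation of the same similarity fit."""
        rng = np.random.default_rng(3)
        true = np.column_stack([rng.uniform(0, 60, 16), rng.uniform(0, 40, 16)])
        sigma = 0.03
        impl = []
        for _ in range(200):
            det = true + rng.normal(0, sigma, true.shape)
            impl.append(tm.georeference(det, true).rmse_m)

        # brute-force oracle: similarity fit via complex linear regression
        rng2 = np.random.default_rng(4)
        oracle = []
        zt = true[:, 0] + 1j * true[:, 1]
        for _ in range(200):
            det = true + rng2.normal(0, sigma, true.shape)
            zd = det[:, 0] + 1j * det[:, 1]
            A = np.column_stack([zd, np.ones_like(zd)])
            coef, *_ = np.linalg.lstsq(A, zt, rcond=None)
            resid = A @ coef - zt
            oracle.append(np.sqrt(np.mean(np.abs(resid) ** 2)))
        assert np.mean(impl) == pytest.approx(np.mean(oracle), rel=0.15)

    def test_too_few_or_collinear_rejected(self):
        with pytest.raises(FitError):
            tm.georeference(np.zeros((2, 2)), np.zeros((2, 2)))
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(FitError):
            tm.georeference(line, line)


@pytest.fixture(scope="module")
def gcp_mosaic():
    """Small full-resolution scene with 16 rendered thermal GCP targets."""
    d = td.generate_design(n_test=39, rep_shape=(7, 6), check_block_shape=(7, 6),
                           n_replicates=1, seed=0)
    td.build_virtual_grid(d, (1, 7), (8, 14))
    td.plot_polygons(d)
    gcps = sc.default_gcp_layout(d)
    truth = make_flat_truth(d, baseline=30.0, cover=0.8, contrast=10.0, gcps=gcps)
    cam = sc.CameraModel(netd_c=0.0)
    b = np.array([p.polygon.bounds for p in d.plots])
    area = (b[:, 0].min() - 4, b[:, 1].min() - 4, b[:, 2].max() + 4, b[:, 3].max() + 4)
    plan = sc.plan_flight(area, camera=cam)
    frames = sc.render_flight(truth, plan, cam, seed=None)
    mos = tm.build_orthomosaic(frames, cam, mode="average")
    return {"mosaic": mos, "gcps": gcps, "frames": frames, "camera": cam,
            "truth": truth}


class TestDetectGcps:
    def test_noiseless_detection_within_half_gsd(self, gcp_mosaic):
        mos = gcp_mosaic["mosaic"]
        pts = tm.detect_gcps(mos, max_targets=16)
        truth = np.array([(g.x, g.y) for g in gcp_mosaic["gcps"]])
        assert len(pts) == 16
        # match each detection to the nearest true target
        d = np.linalg.norm(pts[:, None, :] - truth[None, :, :], axis=2)
        nearest = d.min(axis=1)
        assert (nearest <= 0.5 * mos.gsd).all()
        assert len(set(d.argmin(axis=1))) == 16

    def test_mosaic_without_gcps_gives_empty(self):
        rng = np.random.default_rng(5)
        plain = tm.Orthomosaic(
            temperature=30.0 + rng.normal(0, 0.05, (200, 200)),
            gsd=0.055, origin=(0.0, 0.0),
            provenance=np.ones((200, 200), dtype=int), blending_mode="average")
        with pytest.warns(UserWarning):
            pts = tm.detect_gcps(plain, threshold=0.8)
        assert len(pts) == 0

    def test_detection_with_sensor_noise(self, gcp_mosaic):
        rng = np.random.default_rng(8)
        noisy = tm.Orthomosaic(
            temperature=gcp_mosaic["mosaic"].temperature
            + rng.normal(0, 0.05, gcp_mosaic["mosaic"].shape),
            gsd=gcp_mosaic["mosaic"].gsd, origin=gcp_mosaic["mosaic"].origin,
            provenance=gcp_mosaic["mosaic"].provenance, blending_mode="average")
        pts = tm.detect_gcps(noisy, max_targets=16)
        truth = np.array([(g.x, g.y) for g in gcp_mosaic["gcps"]])
        d = np.linalg.norm(pts[:, None, :] - truth[None, :, :], axis=2)
        hits = (d.min(axis=1) <= 2 * noisy.gsd).sum()
        assert hits >= 15

    def test_end_to_end_georeferencing_rmse_small(self, gcp_mosaic):
        pts = tm.detect_gcps(gcp_mosaic["mosaic"], max_targets=16)
        truth = np.array([(g.x, g.y) for g in gcp_mosaic["gcps"]])
        # order detections by nearest truth
        d = np.linalg.norm(pts[:, None, :] - truth[None, :, :], axis=2)
        order = d.argmin(axis=1)
        res = tm.georeference(pts[np.argsort(order)], truth[np.sort(order)])
        assert res.rmse_cm < 0.5 * gcp_mosaic["mosaic"].gsd * 100
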