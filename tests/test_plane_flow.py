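"""Plane fitting, mask smoothing, velocity sampling, flow integration and
the comparison statistics."""

import numpy as np
import pytest
from scipy import ndimage

from flow4d.io import AcquisitionMeta, Flow4D, Plane, Segmentation4D
from flow4d.plane_flow import (
    PlaneSample,
    dice_coefficient,
    fit_plane_pca,
    flow_rate,
    linear_regression,
    net_flow_volume,
    sample_plane,
    smooth_plane_mask,
)


class TestFitPlanePca:
    def test_exactly_planar_points(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-10, 10, 40),
                               rng.uniform(-10, 10, 40),
                               np.full(40, 5.0)])
        plane = fit_plane_pca(pts, reference_normal=[0, 0, 1])
        assert abs(np.dot(plane.normal, [0, 0, 1])) >= 0.999
        assert plane.origin[2] == pytest.approx(5.0)

    def test_noisy_planar_points(self):
        rng = np.random.default_rng(1)
        n_true = np.array([1.0, 2.0, 2.0]) / 3.0
        e1 = np.array([2.0, -1.0, 0.0]) / np.sqrt(5)
        e2 = np.cross(n_true, e1)
        uv = rng.uniform(-15, 15, (60, 2))
        pts = uv[:, :1] * e1 + uv[:, 1:] * e2 + rng.normal(0, 0.1, (60, 3))
        plane = fit_plane_pca(pts, reference_normal=n_true)
        # oracle: SVD of the centred points
        _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
        assert abs(np.dot(plane.normal, vt[2])) >= 0.9999
        assert abs(np.dot(plane.normal, n_true)) >= 0.995

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1.0, 1, 1], [2.0, 2, 2]])
        with pytest.raises(ValueError):
            fit_plane_pca(pts)

    def test_normal_sign_follows_reference(self):
        pts = np.column_stack([np.tile([0.0, 1, 2], 3),
                               np.repeat([0.0, 1, 2], 3),
                               np.zeros(9)])
        plane = fit_plane_pca(pts, reference_normal=[0, 0, -1])
        assert plane.normal[2] < 0


class TestSmoothPlaneMask:
    def test_all_false_stays_false(self):
        out = smooth_plane_mask(np.zeros((30, 30), dtype=bool))
        assert not out.any()

    def test_disk_grows_within_bounds(self):
        yy, xx = np.mgrid[:50, :50]
        disk10 = (xx - 25) ** 2 + (yy - 25) ** 2 <= 100
        out = smooth_plane_mask(disk10, radius_px=9, keep_frac=0.1)
        # oracle: brute-force convolution with the normalized disk kernel
        r = 9
        ky, kx = np.mgrid[-r:r + 1, -r:r + 1]
        kernel = ((kx ** 2 + ky ** 2) <= r * r).astype(float)
        kernel /= kernel.sum()
        brute = ndimage.convolve(disk10.astype(float), kernel,
                                 mode="constant") >= 0.1
        np.testing.assert_array_equal(out, brute | disk10)
        # output stays disk-like with radius in [10, 19]
        radius = np.sqrt(out.sum() / np.pi)
        assert 10 <= radius <= 19

    def test_never_shrinks_on_random_blobs(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            blob = ndimage.gaussian_filter(
                rng.normal(size=(40, 40)), rng.uniform(1, 4)) > rng.uniform(0, 0.2)
            out = smooth_plane_mask(blob, radius_px=9, keep_frac=0.1)
            assert out.sum() >= blob.sum()
            assert (out | blob).sum() == out.sum()  # superset of the input


def _tube_flow(radius_mm=10.0, v_max=100.0, shape=(40, 40, 8), nt=2,
               spacing=1.0):
    """Axial tube along z with a Poiseuille profile, on a unit-spacing grid."""
    meta = AcquisitionMeta(voxel_size=[spacing] * 3, frame_duration=500.0,
                           n_frames=nt, venc=200.0)
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                    axis=-1) * spacing
    cx = (shape[0] - 1) * spacing / 2
    r = np.sqrt((grid[..., 0] - cx) ** 2 + (grid[..., 1] - cx) ** 2)
    prof = np.where(r <= radius_mm, v_max * (1 - (r / radius_mm) ** 2), 0.0)
    mag = np.ones(shape + (nt,))
    vel = np.zeros(shape + (nt, 3))
    vel[..., 2] = prof[..., None]
    labels = (r <= radius_mm).astype(np.int16)
    seg = Segmentation4D(np.repeat(labels[..., None], nt, axis=3), 0)
    return Flow4D(mag, vel, meta), seg


class TestSamplePlane:
    def test_constant_velocity_region(self):
        meta = AcquisitionMeta(voxel_size=[1, 1, 1], frame_duration=50.0,
                               n_frames=2, venc=120.0)
        mag = np.ones((16, 16, 16, 2))
        vel = np.zeros((16, 16, 16, 2, 3))
        vel[...] = [10.0, -5.0, 30.0]
        flow = Flow4D(mag, vel, meta)
        seg = Segmentation4D(np.ones((16, 16, 16, 2), dtype=np.int16), 0)
        plane = Plane(name="p", origin=[7.5, 7.5, 8.0], normal=[0, 0, 1.0],
                      in_plane_axes=[[1.0, 0, 0], [0, 1.0, 0]], extent=[4, 4])
        sample = sample_plane(flow, seg, plane, 1, spacing=0.5)
        vals = sample.velocity[:, :, 0, :].reshape(-1, 3)
        np.testing.assert_allclose(
            vals, np.tile([10.0, -5.0, 30.0], (len(vals), 1)), atol=1e-9)

    def test_tube_cross_section_is_disk(self):
        flow, seg = _tube_flow()
        plane = Plane(name="p", origin=[19.5, 19.5, 4.0], normal=[0, 0, 1.0],
                      in_plane_axes=[[1.0, 0, 0], [0, 1.0, 0]],
                      extent=[16, 16])
        sample = sample_plane(flow, seg, plane, 1, spacing=0.5)
        mask = sample.mask[..., 0]
        # one connected, disk-like component containing the axis point
        lab, n = ndimage.label(mask)
        assert n == 1
        assert mask[mask.shape[0] // 2, mask.shape[1] // 2]

    def test_plane_outside_volume_raises(self):
        flow, seg = _tube_flow()
        plane = Plane(name="far", origin=[500.0, 500.0, 500.0],
                      normal=[0, 0, 1.0],
                      in_plane_axes=[[1.0, 0, 0], [0, 1.0, 0]], extent=[4, 4])
        with pytest.raises(ValueError):
            sample_plane(flow, seg, plane, 1)


class TestFlowRate:
    def _uniform_sample(self, vn=50.0, n=10, spacing=1.0):
        velocity = np.zeros((n, n, 1, 3))
        velocity[..., 0, 2] = vn
        mask = np.ones((n, n, 1), dtype=bool)
        return PlaneSample(grid=np.zeros((n, n, 3)), velocity=velocity,
                           mask=mask, normal=np.array([0.0, 0, 1]),
                           spacing=spacing)

    def test_uniform_closed_form(self):
        # 50 cm/s over 100 px of 1 mm^2 -> 50 ml/s
        assert flow_rate(self._uniform_sample(), 0) == pytest.approx(50.0)

    def test_zero_velocity(self):
        assert flow_rate(self._uniform_sample(vn=0.0), 0) == 0.0

    def test_retrograde_is_negative(self):
        assert flow_rate(self._uniform_sample(vn=-20.0), 0) < 0

    def test_empty_mask_warns_and_zero(self):
        s = self._uniform_sample()
        s.mask[:] = False
        with pytest.warns(RuntimeWarning):
            assert flow_rate(s, 0) == 0.0

    def test_poiseuille_against_quadrature(self):
        flow, seg = _tube_flow(radius_mm=10.0, v_max=100.0)
        plane = Plane(name="p", origin=[19.5, 19.5, 4.0], normal=[0, 0, 1.0],
                      in_plane_axes=[[1.0, 0, 0], [0, 1.0, 0]],
                      extent=[16, 16])
        sample = sample_plane(flow, seg, plane, 1, spacing=0.5)
        q = flow_rate(sample, 0)
        # oracle: dense midpoint quadrature of the analytic profile
        h = 0.05
        xs = np.arange(-10 + h / 2, 10, h)
        xx, yy = np.meshgrid(xs, xs)
        rr = np.sqrt(xx ** 2 + yy ** 2)
        q_true = (100.0 * (1 - (rr[rr <= 10] / 10.0) ** 2)).sum() * h * h * 1e-2
        assert q_true == pytest.approx(100.0 * np.pi * 100 / 2 * 1e-2, rel=1e-3)
        assert abs(q - q_true) / q_true <= 0.03

    def test_linear_in_velocity(self):
        s = self._uniform_sample(vn=37.0)
        s3 = self._uniform_sample(vn=3 * 37.0)
        assert flow_rate(s3, 0) == pytest.approx(3 * flow_rate(s, 0))


class TestNetFlowVolume:
    def test_constant_rate_closed_form(self):
        assert net_flow_volume([60.0] * 20, 50.0) == pytest.approx(60.0)

    def test_zero_rates(self):
        assert net_flow_volume(np.zeros(10), 52.8) == 0.0

    def test_half_sine_against_analytic_integral(self):
        # Q(t) = 157.08 sin(pi t / 0.3) during 0.3 s systole, 0 in diastole,
        # sampled at the clinical 52.8 ms resolution
        dt = 0.0528
        t_mid = (np.arange(20) + 0.5) * dt
        q = np.where(t_mid < 0.3, 157.08 * np.sin(np.pi * t_mid / 0.3), 0.0)
        v = net_flow_volume(q, 52.8)
        analytic = 2 * 157.08 * 0.3 / np.pi
        assert analytic == pytest.approx(30.0, abs=0.01)
        assert abs(v - analytic) / analytic <= 0.05


class TestLinearRegression:
    def test_perfect_identity(self):
        x = np.arange(10.0)
        res = linear_regression(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_affine_closed_form(self):
        x = np.linspace(0, 5, 12)
        res = linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, 30)
        y = 1.7 * x - 3.2 + rng.normal(0, 1, 30)
        res = linear_regression(x, y)
        a = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(a.T @ a, a.T @ y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert 0 <= res.r_squared <= 1
        assert 0 < res.p_value <= 1

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression(np.ones(5), np.arange(5.0))

    def test_significance_flag(self):
        x = np.arange(20.0)
        assert linear_regression(x, 3 * x).significant


class TestDiceCoefficient:
    def test_identical_nonempty(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert dice_coefficient(a, b) == 0.0

    def test_half_overlap_closed_form(self):
        # b covers exactly half of a: dice = 2*(n/2) / (n + n/2) = 2/3
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[:2], b[:1] = True, True
        assert dice_coefficient(a, b) == pytest.approx(2 / 3)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice_coefficient(z, z) == 1.0

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((3, 3, 3), bool),
                             np.zeros((4, 4, 4), bool))
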