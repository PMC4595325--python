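"""Velocity preprocessing: static-tissue detection, temporal unwrapping,
background polynomial fit and correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flow4d.io import AcquisitionMeta, Flow4D
from flow4d.preprocess import (
    EmptyMaskError,
    StaticTissueMask,
    _poly_design,
    correct_background,
    detect_static_tissue,
    fit_background,
    unwrap_temporal,
)


def _meta(n_frames, venc=120.0):
    return AcquisitionMeta(voxel_size=[1, 1, 1], frame_duration=50.0,
                           n_frames=n_frames, venc=venc)


def _flow_from_series(series, venc=120.0):
    """One-voxel-thick flow whose x velocity follows the given time series."""
    series = np.asarray(series, dtype=float)
    nt = len(series)
    mag = np.ones((2, 2, 2, nt))
    vel = np.zeros((2, 2, 2, nt, 3))
    vel[..., 0] = series
    return Flow4D(mag, vel, _meta(nt, venc))


class TestDetectStaticTissue:
    def _shell_phantom(self, vessel_std=30.0):
        """Static shell (std 0) plus a pulsatile 'vessel' core."""
        rng = np.random.default_rng(0)
        nt = 8
        mag = np.full((10, 10, 10, nt), 1.0)
        vel = np.zeros((10, 10, 10, nt, 3))
        # vessel core: alternating velocity -> temporal std ~ vessel_std
        core = np.s_[4:6, 4:6, :]
        vel[core + (slice(None), 0)] = vessel_std * np.sqrt(2.0) * (
            np.arange(nt) % 2)
        return Flow4D(mag, vel, _meta(nt)), core

    def test_mask_covers_shell_only(self):
        flow, core = self._shell_phantom()
        static = detect_static_tissue(flow, mag_frac=0.1, vel_std_max=2.0)
        core_mask = np.zeros(flow.shape, dtype=bool)
        core_mask[core] = True
        # oracle: direct per-voxel std of speed
        std = flow.speed().std(axis=3)
        assert not static.mask[core_mask].any()
        assert static.mask[~core_mask].all()
        assert (std[static.mask] <= 2.0).all()

    def test_all_zero_magnitude_raises(self):
        flow = Flow4D(np.zeros((4, 4, 4, 3)), np.zeros((4, 4, 4, 3, 3)),
                      _meta(3))
        with pytest.raises(EmptyMaskError):
            detect_static_tissue(flow)

    def test_limit_case_covers_everything(self):
        flow, _ = self._shell_phantom()
        static = detect_static_tissue(flow, mag_frac=0.0,
                                      vel_std_max=np.inf)
        assert static.mask.all()

    def test_weights_zero_outside_mask(self):
        flow, _ = self._shell_phantom()
        static = detect_static_tissue(flow)
        assert (static.weights[~static.mask] == 0).all()
        assert static.weights.max() <= 1.0


class TestUnwrapTemporal:
    @staticmethod
    def _oracle_unwrap(series, venc):
        """Exhaustive search over k*2*venc corrections minimizing jumps."""
        series = list(series)
        out = [series[0]]
        for v in series[1:]:
            candidates = [v + 2 * venc * k for k in range(-3, 4)]
            out.append(min(candidates, key=lambda c: abs(c - out[-1])))
        return np.array(out)

    def test_documented_wrap_case(self):
        flow = _flow_from_series([100.0, 110.0, -115.0], venc=120.0)
        out = unwrap_temporal(flow)
        np.testing.assert_allclose(out.velocity[0, 0, 0, :, 0],
                                   [100.0, 110.0, 125.0])

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        venc = 120.0
        for _ in range(20):
            true = rng.uniform(-200, 200, 10)
            true[0] = rng.uniform(-100, 100)  # wrap-free anchor
            # limit frame-to-frame jumps so the series is unwrappable
            true = np.cumsum(np.clip(np.diff(np.r_[true[0], true]), -100, 100))
            wrapped = np.mod(true + venc, 2 * venc) - venc
            out = unwrap_temporal(_flow_from_series(wrapped, venc))
            oracle = self._oracle_unwrap(wrapped, venc)
            np.testing.assert_allclose(out.velocity[0, 0, 0, :, 0], oracle,
                                       atol=1e-9)

    def test_wrap_free_series_unchanged(self):
        flow = _flow_from_series([10.0, -50.0, 60.0, 0.0])
        out = unwrap_temporal(flow)
        np.testing.assert_array_equal(out.velocity, flow.velocity)

    def test_idempotent(self):
        flow = _flow_from_series([100.0, 110.0, -115.0, -100.0, 119.0])
        once = unwrap_temporal(flow)
        twice = unwrap_temporal(once)
        np.testing.assert_array_equal(once.velocity, twice.velocity)

    def test_anchor_frame_backward_scan(self):
        # anchor mid-series: earlier frames unwrapped scanning backwards
        flow = _flow_from_series([-115.0, 110.0, 100.0])
        out = unwrap_temporal(flow, anchor_frame=2)
        np.testing.assert_allclose(out.velocity[0, 0, 0, :, 0],
                                   [125.0, 110.0, 100.0])

    @given(st.lists(st.floats(min_value=-119, max_value=119), min_size=2,
                    max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_changes_are_multiples_of_two_venc(self, series):
        venc = 120.0
        flow = _flow_from_series(series, venc)
        out = unwrap_temporal(flow)
        delta = out.velocity - flow.velocity
        k = delta / (2 * venc)
        np.testing.assert_allclose(k, np.round(k), atol=1e-12)
        # post-condition: successive differences within (-venc, venc]
        diffs = np.diff(out.velocity[0, 0, 0, :, 0])
        assert (diffs > -venc - 1e-9).all() and (diffs <= venc + 1e-9).all()


def _static_flow_with_offset(coeffs, shape=(10, 10, 10), nt=3):
    """Motion-free flow whose velocity equals the polynomial offset field."""
    offset = (_poly_design(shape) @ coeffs.T).reshape(shape + (3,))
    mag = np.ones(shape + (nt,))
    vel = np.repeat(offset[:, :, :, None, :], nt, axis=3)
    return Flow4D(mag, vel, _meta(nt))


class TestBackgroundFit:
    def test_injected_offset_recovered_exactly(self):
        coeffs = np.zeros((3, 10))
        coeffs[0, 0] = 0.5      # constant 0.5 cm/s on x
        coeffs[0, 1] = 0.01     # linear in x
        coeffs[2, 6] = -0.002   # quadratic in z on the z component
        flow = _static_flow_with_offset(coeffs)
        static = StaticTissueMask(np.ones(flow.shape, bool),
                                  np.ones(flow.shape))
        model = fit_background(flow, static)
        # oracle: exact normal-equations solve on the full design
        design = _poly_design(flow.shape)
        for c in range(3):
            expected = np.linalg.solve(design.T @ design,
                                       design.T @ flow.velocity[..., 0, c].ravel())
            np.testing.assert_allclose(model.coeffs[c], expected, atol=1e-9)
        np.testing.assert_allclose(model.coeffs, coeffs, atol=1e-6)

    def test_zero_offset_gives_zero_coeffs(self):
        flow = _static_flow_with_offset(np.zeros((3, 10)))
        static = StaticTissueMask(np.ones(flow.shape, bool),
                                  np.ones(flow.shape))
        model = fit_background(flow, static)
        np.testing.assert_allclose(model.coeffs, 0.0, atol=1e-9)

    def test_too_few_voxels_raises(self):
        flow = _static_flow_with_offset(np.zeros((3, 10)))
        mask = np.zeros(flow.shape, bool)
        mask.ravel()[:9] = True
        static = StaticTissueMask(mask, mask.astype(float))
        with pytest.raises(ValueError):
            fit_background(flow, static)

    def test_coplanar_voxels_rank_deficient(self):
        flow = _static_flow_with_offset(np.zeros((3, 10)))
        mask = np.zeros(flow.shape, bool)
        mask[:, :, 4] = True  # a single z slice cannot constrain z^2
        static = StaticTissueMask(mask, mask.astype(float))
        with pytest.raises(ValueError):
            fit_background(flow, static)


class TestBackgroundCorrect:
    def test_correct_after_fit_zeroes_static_mean(self):
        coeffs = np.zeros((3, 10))
        coeffs[1, 3] = 0.4
        coeffs[0, 7] = -0.1
        flow = _static_flow_with_offset(coeffs)
        static = StaticTissueMask(np.ones(flow.shape, bool),
                                  np.ones(flow.shape))
        out = correct_background(flow, fit_background(flow, static))
        mean_vel = out.velocity.mean(axis=3)
        assert np.abs(mean_vel[static.mask]).max() < 0.01

    def test_zero_model_is_identity(self):
        flow = _static_flow_with_offset(np.zeros((3, 10)))
        static = StaticTissueMask(np.ones(flow.shape, bool),
                                  np.ones(flow.shape))
        model = fit_background(flow, static)
        out = correct_background(flow, model)
        np.testing.assert_allclose(out.velocity, flow.velocity, atol=1e-9)

    def test_constant_model_subtracts_exactly(self):
        rng = np.random.default_rng(4)
        mag = np.ones((6, 6, 6, 3))
        vel = rng.normal(0, 10, (6, 6, 6, 3, 3))
        flow = Flow4D(mag, vel, _meta(3))
        coeffs = np.zeros((3, 10))
        coeffs[:, 0] = [1.5, -2.0, 0.25]
        from flow4d.preprocess import BackgroundModel
        out = correct_background(flow, BackgroundModel(coeffs, flow.shape))
        np.testing.assert_allclose(flow.velocity - out.velocity,
                                   np.broadcast_to([1.5, -2.0, 0.25],
                                                   flow.velocity.shape),
                                   atol=1e-12)

    def test_magnitude_untouched(self):
        coeffs = np.zeros((3, 10))
        coeffs[0, 0] = 1.0
        flow = _static_flow_with_offset(coeffs)
        static = StaticTissueMask(np.ones(flow.shape, bool),
                                  np.ones(flow.shape))
        out = correct_background(flow, fit_background(flow, static))
        np.testing.assert_array_equal(out.magnitude, flow.magnitude)

    def test_correction_never_increases_static_rms(self):
        # noisy case: weighted RMS in static tissue must not increase
        rng = np.random.default_rng(5)
        coeffs = rng.normal(0, 0.3, (3, 10))
        flow = _static_flow_with_offset(coeffs)
        noisy = Flow4D(flow.magnitude,
                       flow.velocity + rng.normal(0, 0.5, flow.velocity.shape),
                       flow.meta)
        static = StaticTissueMask(np.ones(flow.shape, bool),
                                  np.ones(flow.shape))
        out = correct_background(noisy, fit_background(noisy, static))
        rms_before = np.sqrt((noisy.velocity.mean(axis=3) ** 2).mean())
        rms_after = np.sqrt((out.velocity.mean(axis=3) ** 2).mean())
        assert rms_after <= rms_before + 1e-12
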