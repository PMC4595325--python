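"""Offline velocity corrections: temporal phase unwrapping and eddy-current
background correction.

Phase-contrast velocities wrap by multiples of 2*VENC when the true speed
exceeds the velocity-encoding limit.  :func:`unwrap_temporal` removes wraps by
scanning each voxel's time series and folding successive differences back
into ``(-venc, venc]``, anchored at a configurable wrap-free frame.

Residual eddy-current/background phase offsets are modelled as a full
second-order 3D polynomial per velocity component, fitted by weighted least
squares to voxels classified as static tissue, and subtracted from every
frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Flow4D

__all__ = [
    "StaticTissueMask",
    "BackgroundModel",
    "detect_static_tissue",
    "unwrap_temporal",
    "fit_background",
    "correct_background",
]


class EmptyMaskError(ValueError):
    """No static tissue could be identified; background correction must be skipped."""


@dataclass
class StaticTissueMask:
    """Boolean mask of static-tissue voxels with per-voxel confidence weights.

    ``weights`` are zero outside the mask and in (0, 1] inside, decreasing
    with the temporal standard deviation of the speed.
    """

    mask: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.mask.shape:
            raise ValueError("weights and mask must share one grid")
        if np.any(self.weights[~self.mask] != 0):
            raise ValueError("weights must be zero outside the mask")
        if np.any(self.weights > 1) or np.any(self.weights < 0):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# 2nd-order 3D polynomial basis: 1, x, y, z, x^2, y^2, z^2, xy, xz, yz
N_POLY_TERMS = 10


@dataclass
class BackgroundModel:
    """Per-component coefficients of a 2nd-order 3D background polynomial.

    Coefficients are expressed in normalized voxel coordinates (each axis
    mapped to [-1, 1]) for conditioning; evaluating the model yields a cm/s
    offset field on the acquisition grid.
    """

    coeffs: np.ndarray  # (3, 10)
    shape: tuple
    residual_rms: np.ndarray = None  # (3,) weighted RMS of the fit residual

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (3, N_POLY_TERMS):
            raise ValueError(f"coeffs must be (3, {N_POLY_TERMS})")
        self.shape = tuple(self.shape)

    def evaluate(self) -> np.ndarray:
        """Offset field in cm/s, shape ``self.shape + (3,)``."""
        design = _poly_design(self.shape)
        out = design @ self.coeffs.T  # (nvox, 3)
        return out.reshape(self.shape + (3,))


def _normalized_coords(shape) -> np.ndarray:
    """Voxel-centre coordinates normalized to [-1, 1] per axis, (nvox, 3)."""
    axes = []
    for n in shape:
        if n > 1:
            axes.append(np.linspace(-1.0, 1.0, n))
        else:
            axes.append(np.zeros(1))
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def _poly_design(shape) -> np.ndarray:
    c = _normalized_coords(shape)
    x, y, z = c[:, 0], c[:, 1], c[:, 2]
    return np.stack(
        [np.ones_like(x), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z],
        axis=1,
    )


def detect_static_tissue(flow: Flow4D, mag_frac: float = 0.1,
                         vel_std_max: float = 2.0) -> StaticTissueMask:
    """Classify voxels as static tissue by signal strength and velocity stability.

    A voxel is static when its time-mean magnitude reaches ``mag_frac`` times
    the volume-wide 95th percentile of time-mean magnitude AND the temporal
    standard deviation of its speed is at most ``vel_std_max`` cm/s.  Weights
    inside the mask are ``clamp(1 - std / vel_std_max, 0, 1)``.

    Raises
    ------
    EmptyMaskError
        If no voxel qualifies (correction should then be skipped).
    """
    mean_mag = flow.magnitude.mean(axis=3)
    speed_std = flow.speed().std(axis=3)
    ref = np.percentile(mean_mag, 95)
    mask = (mean_mag >= mag_frac * ref) & (speed_std <= vel_std_max)
    if ref <= 0 or not mask.any():
        raise EmptyMaskError("no static tissue found; skip background correction")
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.clip(1.0 - speed_std / vel_std_max, 0.0, 1.0) if np.isfinite(
            vel_std_max) else np.ones_like(speed_std)
    weights = np.where(mask, w, 0.0)
    # guard: an in-mask voxel with std exactly vel_std_max still counts a little
    weights[mask & (weights == 0)] = np.finfo(float).tiny
    weights[mask] = np.clip(weights[mask], 0.0, 1.0)
    return StaticTissueMask(mask=mask, weights=weights)


def unwrap_temporal(flow: Flow4D, anchor_frame: int = 0) -> Flow4D:
    """Remove +/-2*VENC phase wraps along the time axis.

    Scanning frames in time order from ``anchor_frame`` (assumed wrap-free),
    whenever a successive difference exceeds +venc the value (and all later
    frames) is shifted by -2*venc, and vice versa, so that after the pass all
    successive differences lie in ``(-venc, venc]``.  The operation is
    idempotent and only ever changes values by integer multiples of 2*venc.
    """
    venc = flow.meta.venc
    v = flow.velocity
    nt = v.shape[3]
    if not 0 <= anchor_frame < nt:
        raise ValueError("anchor_frame out of range")
    # scan forward from the anchor and, separately, backward for earlier frames
    out = v.copy()
    _unwrap_scan(out, venc, range(anchor_frame + 1, nt))
    _unwrap_scan(out, venc, range(anchor_frame - 1, -1, -1))
    return Flow4D(flow.magnitude.copy(), out, flow.meta)


def _unwrap_scan(v: np.ndarray, venc: float, frames) -> None:
    """In-place sequential wrap correction along the listed frames."""
    frames = list(frames)
    if not frames:
        return
    step = 1 if len(frames) == 1 or frames[1] > frames[0] else -1
    for t in frames:
        prev = v[..., t - step, :]
        diff = v[..., t, :] - prev
        # number of 2*venc periods to remove; diff == +/-venc stays uncorrected
        k = np.round(diff / (2.0 * venc))
        k[np.abs(diff) == venc] = 0
        if np.any(k):
            v[..., t, :] -= 2.0 * venc * k


def fit_background(flow: Flow4D, static: StaticTissueMask) -> BackgroundModel:
    """Weighted least-squares fit of a 2nd-order background polynomial.

    The temporal-mean velocity of each component over static-tissue voxels is
    fitted with the 10-term quadratic basis in normalized voxel coordinates,
    using the static-tissue confidence weights.

    Raises
    ------
    ValueError
        If fewer than 10 voxels carry positive weight or the weighted design
        is rank-deficient (e.g., all static voxels coplanar).
    """
    sel = static.weights.ravel() > 0
    if sel.sum() < N_POLY_TERMS:
        raise ValueError(
            f"need >= {N_POLY_TERMS} static voxels with positive weight, "
            f"got {int(sel.sum())}")
    design = _poly_design(flow.shape)[sel]
    w = static.weights.ravel()[sel]
    sw = np.sqrt(w)
    a = design * sw[:, None]
    if np.linalg.matrix_rank(a) < N_POLY_TERMS:
        raise ValueError("rank-deficient design: static voxels degenerate")
    mean_vel = flow.velocity.mean(axis=3).reshape(-1, 3)[sel]
    coeffs = np.empty((3, N_POLY_TERMS))
    rms = np.empty(3)
    for c in range(3):
        b = mean_vel[:, c] * sw
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        coeffs[c] = sol
        resid = design @ sol - mean_vel[:, c]
        rms[c] = np.sqrt(np.sum(w * resid ** 2) / np.sum(w))
    return BackgroundModel(coeffs=coeffs, shape=flow.shape, residual_rms=rms)


def correct_background(flow: Flow4D, model: BackgroundModel) -> Flow4D:
    """Subtract the evaluated background polynomial from every frame.

    Magnitude is untouched; each velocity component loses the same static
    offset field in all frames.
    """
    if model.shape != flow.shape:
        raise ValueError("background model grid-incompatible with flow data")
    offset = model.evaluate()  # (nx, ny, nz, 3)
    vel = flow.velocity - offset[:, :, :, None, :]
    return Flow4D(flow.magnitude.copy(), vel, flow.meta)
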