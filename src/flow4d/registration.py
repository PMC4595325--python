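"""Affine and multi-scale non-rigid diffeomorphic registration.

The non-rigid engine follows the Morphon family of algorithms: local
incremental displacements are estimated iteratively from image structure
with a per-voxel certainty, fluid-regularized (Gaussian smoothing of the
increment, modelling a viscous fluid), accumulated *diffeomorphically* by
composing the increment with the running field — never by voxel-wise
addition — and elastic-regularized (certainty-weighted Gaussian smoothing of
the accumulated field, modelling an elastic material).  Composition of
small, smooth increments keeps the Jacobian determinant of the total
deformation positive everywhere: the field can compress and stretch the
anatomy but cannot tear or fold it.

The local displacement is estimated from local structure: with ``g`` the
mean of the warped-source and target gradients and ``diff`` their intensity
difference, the per-voxel optical-flow constraints ``g . delta = -diff`` are
aggregated over the fluid kernel into a structure tensor ``G * (g g^T)``
and force ``G * (-diff g)`` and solved as a Tikhonov-regularized 3x3 system
per voxel.  The spatial aggregation is what resolves the aperture problem
on locally one-dimensional structures such as vessel walls; the per-voxel
certainty is the aggregated gradient energy (the tensor trace).  Increments
are capped at one voxel per iteration so the composed field stays
invertible.

Conventions
-----------
All geometry in this module is in 0-based voxel coordinates of the target
grid.  Displacement fields use the pull-back convention: the warped image at
target voxel ``x`` samples the source at ``x + d(x)``.  Forward point
mapping therefore goes through :func:`invert_field`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "RegistrationParams",
    "ncc",
    "register_affine",
    "register_morphon",
    "warp_image",
    "warp_labels",
    "invert_field",
    "map_points",
    "jacobian_determinant",
]


@dataclass
class AffineTransform:
    """12-parameter affine map in voxel coordinates: ``y = M x + t``."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-9:
            raise ValueError("affine matrix must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.matrix, np.eye(3), atol=1e-12)
                and np.allclose(self.translation, 0, atol=1e-12))


@dataclass
class DisplacementField:
    """Dense per-voxel displacement on the target grid, pull-back convention.

    ``d`` has shape ``(nx, ny, nz, 3)`` in voxel units of the target grid
    (multiply by the voxel size for mm); a target voxel ``x`` samples the
    source at ``x + d(x)``.  ``certainty`` is the accumulated nonnegative
    per-voxel confidence of the local displacement estimates.
    """

    d: np.ndarray
    certainty: np.ndarray = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.ndim != 4 or self.d.shape[-1] != 3:
            raise ValueError("displacement must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("displacement field must be finite everywhere")
        if self.certainty is None:
            self.certainty = np.ones(self.d.shape[:3])
        self.certainty = np.asarray(self.certainty, dtype=np.float64)
        if self.certainty.shape != self.d.shape[:3]:
            raise ValueError("certainty grid must match the field grid")

    @property
    def shape(self) -> tuple:
        return self.d.shape[:3]

    @classmethod
    def zero(cls, shape) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (3,)))

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.d ** 2).sum(axis=-1)).max())


@dataclass
class RegistrationParams:
    """Multi-scale registration schedule and regularization strengths.

    ``sigma_fluid`` smooths each incremental displacement (viscous-fluid
    behaviour); ``sigma_elastic`` smooths the accumulated field (elastic
    behaviour); both are Gaussian standard deviations in voxels of the
    current pyramid level.
    """

    n_scales: int = 3
    iters_per_scale: int = 5
    sigma_fluid: float = 2.0
    sigma_elastic: float = 1.5
    use_edge_representation: bool = False
    interpolation: str = "linear"

    def __post_init__(self):
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.iters_per_scale < 1:
            raise ValueError("iters_per_scale must be >= 1")
        if self.sigma_fluid < 0 or self.sigma_elastic < 0:
            raise ValueError("regularization sigmas must be >= 0")
        if self.interpolation != "linear":
            raise ValueError("only linear interpolation is supported")


# ---------------------------------------------------------------------------
# similarity and helpers

def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized (Pearson) intensity correlation between two volumes."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("correlation undefined for a constant image")
    return float((a @ b) / denom)


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _identity_grid(shape) -> np.ndarray:
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _sample(image: np.ndarray, coords: np.ndarray, order: int = 1,
            cval: float = 0.0) -> np.ndarray:
    """Linear sampling of ``image`` at voxel coordinates (..., 3); OOB -> cval."""
    pts = np.moveaxis(coords, -1, 0)
    return ndimage.map_coordinates(image, pts, order=order, mode="constant",
                                   cval=cval, prefilter=False)


def _sample_field(field_d: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Interpolate a (nx, ny, nz, 3) field at voxel coordinates (..., 3)."""
    out = np.empty(coords.shape, dtype=np.float64)
    pts = np.moveaxis(coords, -1, 0)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(field_d[..., c], pts, order=1,
                                              mode="nearest", prefilter=False)
    return out


def _pyramid(image: np.ndarray, n_scales: int, min_size: int = 8) -> list:
    """Gaussian pyramid, finest first; levels below ``min_size`` are dropped."""
    levels = [np.asarray(image, dtype=np.float64)]
    for _ in range(n_scales - 1):
        prev = levels[-1]
        if min(prev.shape) < 2 * min_size:
            break
        smoothed = ndimage.gaussian_filter(prev, 1.0, mode="nearest")
        levels.append(smoothed[::2, ::2, ::2])
    return levels


# ---------------------------------------------------------------------------
# affine registration

def _affine_from_params(p: np.ndarray) -> AffineTransform:
    """translation(3) + rotation(3, rad) + log-scale(3) + shear(3) -> transform."""
    t = p[0:3]
    rx, ry, rz = p[3:6]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rot = (np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
           @ np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
           @ np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]]))
    scale = np.diag(np.exp(p[6:9]))
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = p[9:12]
    return AffineTransform(rot @ shear @ scale, t)


def _warp_affine_level(source: np.ndarray, transform: AffineTransform,
                       level_scale: float, center: np.ndarray) -> np.ndarray:
    """Resample ``source`` through ``y = M (x - c) + c + t/f`` at one level."""
    m = transform.matrix
    offset = center - m @ center + transform.translation / level_scale
    return ndimage.affine_transform(source, m, offset=offset, order=1,
                                    mode="constant", cval=0.0, prefilter=False)


def register_affine(source: np.ndarray, target: np.ndarray,
                    params: RegistrationParams = None) -> AffineTransform:
    """Estimate a 12-parameter affine aligning ``source`` onto ``target``.

    Optimizes a normalized intensity-correlation objective over a coarse-to-
    fine pyramid (``n_scales`` levels, ``iters_per_scale`` refinement cycles
    per level).  The transform is centred on the volume midpoint, with the
    translation expressed in full-resolution voxels.  If the optimized
    objective ends up worse than at identity the identity transform is
    returned with a warning.
    """
    params = params or RegistrationParams()
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if source.ndim != 3 or target.ndim != 3:
        raise ValueError("expected 3D volumes")
    if source.max() == source.min() or target.max() == target.min():
        raise ValueError("correlation undefined for a constant image")
    src = _normalize(source)
    tgt = _normalize(target)

    src_pyr = _pyramid(src, params.n_scales)
    tgt_pyr = _pyramid(tgt, params.n_scales)
    n_levels = min(len(src_pyr), len(tgt_pyr))

    p = np.zeros(12)
    for level in range(n_levels - 1, -1, -1):
        s_l, t_l = src_pyr[level], tgt_pyr[level]
        f = 2.0 ** level
        center = (np.array(t_l.shape) - 1) / 2.0

        def objective(q, _s=s_l, _t=t_l, _f=f, _c=center):
            try:
                tr = _affine_from_params(q)
            except ValueError:
                return 2.0
            warped = _warp_affine_level(_s, tr, _f, _c)
            if warped.max() == warped.min():
                return 2.0
            # tiny pull toward identity: breaks ties along directions in
            # which the image is invariant (e.g. translation along a
            # uniform tube) without biasing well-constrained parameters
            penalty = 1e-3 * (np.sum((q[:3] / 10.0) ** 2) + np.sum(q[3:] ** 2))
            return 1.0 - ncc(warped, _t) + penalty

        if level == n_levels - 1:
            # translation-only pre-alignment for large offsets
            res = optimize.minimize(
                lambda q: objective(np.r_[q, p[3:]]), p[:3], method="Powell",
                options={"maxiter": 10, "xtol": 1e-3, "ftol": 1e-6})
            p[:3] = res.x
        res = optimize.minimize(
            objective, p, method="Powell",
            options={"maxiter": params.iters_per_scale, "xtol": 1e-4,
                     "ftol": 1e-8})
        if res.fun <= objective(p):
            p = res.x

    final = _affine_from_params(p)
    center_full = (np.array(target.shape) - 1) / 2.0
    warped_full = _warp_affine_level(src, final, 1.0, center_full)
    try:
        obj_final = 1.0 - ncc(warped_full, tgt)
    except ValueError:
        obj_final = 2.0
    obj_identity = 1.0 - ncc(src, tgt)
    if obj_final > obj_identity:
        warnings.warn("affine registration diverged; returning identity",
                      RuntimeWarning)
        return AffineTransform.identity()
    # fold the centring into matrix/translation: y = M x + (c - M c + t)
    m = final.matrix
    t = center_full - m @ center_full + final.translation
    return AffineTransform(m, t)


# ---------------------------------------------------------------------------
# Morphon-style non-rigid registration

def _smooth_weighted(arr: np.ndarray, cert: np.ndarray, sigma: float) -> np.ndarray:
    """Certainty-weighted (normalized-convolution) Gaussian smoothing."""
    if sigma <= 0:
        return arr
    eps = 1e-8
    wc = ndimage.gaussian_filter(cert, sigma, mode="nearest") + eps
    out = np.empty_like(arr)
    for c in range(arr.shape[-1]):
        out[..., c] = ndimage.gaussian_filter(arr[..., c] * cert, sigma,
                                              mode="nearest") / wc
    return out


_MAX_STEP_VOX = 1.0     # per-iteration increment cap, keeps composition invertible
_TIKHONOV_FRAC = 0.05   # regularization relative to the tensor trace
_SIGMA_EXTEND = 4.0     # field extension reach into low-certainty regions


def _extend_field(d: np.ndarray, cert: np.ndarray,
                  sigma: float = _SIGMA_EXTEND) -> np.ndarray:
    """Propagate the field into low-certainty regions by normalized convolution.

    Structureless regions (vessel interiors, background) provide no
    displacement evidence; they inherit a certainty-weighted long-range
    average of the surrounding well-determined field.
    """
    c0 = 0.1 * cert.mean() + 1e-12
    d_ext = _smooth_weighted(d, cert + 1e-12, sigma)
    w = (cert / (cert + c0))[..., None]
    return w * d + (1.0 - w) * d_ext


def _morphon_level(source: np.ndarray, target: np.ndarray, d: np.ndarray,
                   cert_acc: np.ndarray, params: RegistrationParams):
    """Run ``iters_per_scale`` displacement updates at one pyramid level."""
    grid = _identity_grid(target.shape)
    grad_t = np.stack(np.gradient(target), axis=-1)
    eye = np.eye(3)
    for _ in range(params.iters_per_scale):
        warped = _sample(source, grid + d)
        diff = warped - target
        grad_w = np.stack(np.gradient(warped), axis=-1)
        g = 0.5 * (grad_w + grad_t)
        # optical-flow constraints g . delta = -diff, aggregated over the
        # fluid kernel (the aggregation doubles as fluid regularization and
        # resolves the aperture problem at locally 1D structures)
        sf = max(params.sigma_fluid, 0.5)
        tensor = np.empty(target.shape + (3, 3))
        force = np.empty(target.shape + (3,))
        for i in range(3):
            force[..., i] = ndimage.gaussian_filter(-diff * g[..., i], sf,
                                                    mode="nearest")
            for j in range(i, 3):
                t_ij = ndimage.gaussian_filter(g[..., i] * g[..., j], sf,
                                               mode="nearest")
                tensor[..., i, j] = tensor[..., j, i] = t_ij
        trace = np.trace(tensor, axis1=-2, axis2=-1)
        reg = _TIKHONOV_FRAC * trace / 3.0 + 1e-12
        delta = np.linalg.solve(tensor + reg[..., None, None] * eye,
                                force[..., None])[..., 0]
        mag = np.sqrt(np.sum(delta ** 2, axis=-1))
        delta *= np.minimum(1.0, _MAX_STEP_VOX / np.maximum(mag, 1e-12))[..., None]
        # diffeomorphic accumulation: compose increment with the running field
        d = delta + _sample_field(d, grid + delta)
        cert_acc = np.maximum(cert_acc, trace)
        # elastic regularization of the accumulated field
        d = _smooth_weighted(d, cert_acc + 1e-8, params.sigma_elastic)
    return _extend_field(d, cert_acc), cert_acc


def register_morphon(source: np.ndarray, target: np.ndarray,
                     params: RegistrationParams = None) -> DisplacementField:
    """Multi-scale non-rigid registration of ``source`` onto ``target``.

    Both volumes must share one grid (run :func:`register_affine` and
    resample first when needed).  Returns a pull-back displacement field
    whose interior Jacobian determinant is strictly positive.
    """
    params = params or RegistrationParams()
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if source.shape != target.shape:
        raise ValueError("source and target must share one grid")
    if source.ndim != 3:
        raise ValueError("expected 3D volumes")
    if not (np.all(np.isfinite(source)) and np.all(np.isfinite(target))):
        raise ValueError("NaN/Inf in registration inputs")

    if params.use_edge_representation:
        from .atlas_seg import edge_map
        source = edge_map(source)
        target = edge_map(target)
    src = _normalize(source)
    tgt = _normalize(target)

    src_pyr = _pyramid(src, params.n_scales)
    tgt_pyr = _pyramid(tgt, params.n_scales)
    n_levels = min(len(src_pyr), len(tgt_pyr))

    d = np.zeros(src_pyr[n_levels - 1].shape + (3,))
    cert = np.zeros(src_pyr[n_levels - 1].shape)
    for level in range(n_levels - 1, -1, -1):
        s_l, t_l = src_pyr[level], tgt_pyr[level]
        if d.shape[:3] != s_l.shape:
            zoom = np.array(s_l.shape) / np.array(d.shape[:3])
            d = np.stack([ndimage.zoom(d[..., c], zoom, order=1,
                                       mode="nearest", prefilter=False)
                          for c in range(3)], axis=-1) * 2.0
            cert = ndimage.zoom(cert, zoom, order=1, mode="nearest",
                                prefilter=False)
        d, cert = _morphon_level(s_l, t_l, d, cert, params)

    out = DisplacementField(d=d, certainty=cert)
    # enforce the diffeomorphism contract: smooth further if any folding
    for _ in range(5):
        if _min_interior_jacobian(out) > 0:
            break
        out = DisplacementField(
            _smooth_weighted(out.d, out.certainty + 1e-8,
                             max(params.sigma_elastic, 1.0)),
            out.certainty)
    return out


# ---------------------------------------------------------------------------
# warping, inversion, point mapping, diagnostics

def warp_image(image: np.ndarray, affine: AffineTransform = None,
               displacement: DisplacementField = None,
               mode: str = "linear") -> np.ndarray:
    """Warp ``image`` through ``output(x) = image(A(x + d(x)))``.

    ``mode='linear'`` interpolates intensities; ``mode='mask'`` interpolates
    a 0/1 image linearly and thresholds at 0.5.  Out-of-bounds samples map
    to 0.
    """
    if mode not in ("linear", "mask"):
        raise ValueError(f"unknown warp mode {mode!r}")
    image = np.asarray(image, dtype=np.float64)
    affine = affine or AffineTransform.identity()
    if displacement is None:
        coords = _identity_grid(image.shape)
    else:
        coords = _identity_grid(displacement.shape) + displacement.d
    if not affine.is_identity:
        coords = affine.apply(coords)
    out = _sample(image, coords)
    if mode == "mask":
        return out >= 0.5
    return out


def warp_labels(labels: np.ndarray, affine: AffineTransform = None,
                displacement: DisplacementField = None) -> np.ndarray:
    """Warp an integer label volume, one mask-mode warp per label code.

    Each code's binary mask is interpolated linearly; voxels take the code
    with the largest interpolated occupancy when it exceeds 0.5.
    """
    labels = np.asarray(labels)
    codes = [int(c) for c in np.unique(labels) if c != 0]
    if displacement is not None:
        shape = displacement.shape
    else:
        shape = labels.shape
    best = np.full(shape, 0.5)
    out = np.zeros(shape, dtype=labels.dtype)
    for code in codes:
        soft = warp_image((labels == code).astype(np.float64), affine,
                          displacement, mode="linear")
        take = soft > best
        out[take] = code
        best = np.maximum(best, soft)
    return out


def invert_field(displacement: DisplacementField, n_iter: int = 30,
                 tol: float = 0.05) -> DisplacementField:
    """Invert a diffeomorphic pull-back field by fixed-point iteration.

    Iterates ``d_inv(x) <- -d(x + d_inv(x))`` until the largest update is
    below ``tol`` voxels or ``n_iter`` is reached; raises if the composition
    residual ``max |d_inv(x) + d(x + d_inv(x))|`` still exceeds ``tol``.
    """
    d = displacement.d
    grid = _identity_grid(displacement.shape)
    d_inv = -d.copy()
    for _ in range(n_iter):
        new = -_sample_field(d, grid + d_inv)
        update = np.abs(new - d_inv).max()
        d_inv = new
        if update < tol:
            break
    residual = np.abs(d_inv + _sample_field(d, grid + d_inv)).max()
    if residual > tol:
        raise RuntimeError(
            f"field inversion did not converge: residual {residual:.4f} voxels "
            f"after {n_iter} iterations (tol {tol})")
    return DisplacementField(d_inv, displacement.certainty.copy())


def map_points(points: np.ndarray, affine: AffineTransform = None,
               displacement: DisplacementField = None,
               inverse_displacement: DisplacementField = None):
    """Map source-image (atlas) points forward onto the target grid.

    The registration chain is pull-back — a target voxel ``x`` samples the
    source at ``A(x + d(x))`` — so pushing a source point ``p`` forward uses
    the inverse: ``x = A^{-1}(p) + d_inv(A^{-1}(p))``.  Points are in voxel
    coordinates.  Returns ``(mapped_points, in_bounds)`` where points mapping
    outside the target grid are retained but flagged.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    affine = affine or AffineTransform.identity()
    y = affine.inverse().apply(pts)
    if displacement is not None:
        d_inv = inverse_displacement or invert_field(displacement)
        y = y + _sample_field(d_inv.d, y)
        shape = displacement.shape
    else:
        shape = None
    if shape is not None:
        upper = np.array(shape) - 1
        in_bounds = np.all((y >= 0) & (y <= upper), axis=1)
    else:
        in_bounds = np.ones(len(y), dtype=bool)
    return y, in_bounds


def jacobian_determinant(displacement: DisplacementField) -> np.ndarray:
    """Central-difference determinant of ``I + grad(d)`` per voxel.

    Border voxels use one-sided differences; diffeomorphism checks should
    look at the interior (see :func:`min_interior_jacobian`).
    """
    d = displacement.d
    jac = np.empty(d.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(d[..., comp])
        for axis in range(3):
            jac[..., comp, axis] = grads[axis]
    jac += np.eye(3)
    return np.linalg.det(jac)


def min_interior_jacobian(displacement: DisplacementField) -> float:
    return _min_interior_jacobian(displacement)


def _min_interior_jacobian(displacement: DisplacementField) -> float:
    det = jacobian_determinant(displacement)
    interior = det[1:-1, 1:-1, 1:-1]
    if interior.size == 0:
        interior = det
    return float(interior.min())
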