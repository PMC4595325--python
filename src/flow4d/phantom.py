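"""Synthetic pulsatile-flow phantoms with analytic ground truth.

The generator emulates a clinical 4D flow acquisition — by default a
64x64x64 grid of 2.7 x 2.7 x 2.8 mm voxels, 20 cardiac frames of 52.8 ms and
a VENC of 120 cm/s — filled with tubular vessels carrying laminar Poiseuille
flow modulated by a cardiac waveform:

    v(r, t) = v_max * (1 - (r/R)^2) * w(t)        (axial direction)

so the peak volumetric flow rate through any perpendicular cross-section is
``Q_peak = v_max * pi R^2 / 2`` and the analytic net volume over one cycle
is ``Q_peak * integral(w)``.  Available geometries are a straight tube, a
gently curved tube, two independent parallel tubes, and a Y-bifurcation
whose branch radii are chosen as ``R * sqrt(f_i)`` so the branch flows sum
exactly to the trunk flow.

Optional corruptions exercise the preprocessing stages: bulk sinusoidal
motion of the geometry (ground-truth per-frame offsets recorded), Gaussian
velocity/magnitude noise, a second-order polynomial background velocity
offset, and +/-2*VENC phase wrapping wherever the corrupted velocity exceeds
the encoding limit.  All randomness derives from one seed; velocity values
are assigned from the analytic profile at voxel centres (no subvoxel
averaging), so the remaining discretization error is what the pipeline's
few-percent tolerances absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import AcquisitionMeta, Flow4D, Plane
from .preprocess import N_POLY_TERMS, _poly_design

__all__ = [
    "Waveform",
    "PhantomSpec",
    "PhantomTruth",
    "make_waveform",
    "make_phantom",
    "apply_motion",
    "default_meta",
]

LUMEN_MAG = 1.0
SHELL_MAG = 0.5
BACKGROUND_MAG = 0.05
ML_PER_CM_S_MM2 = 1e-2  # cm/s * mm^2 -> ml/s


def default_meta(n_frames: int = 20,
                 frame_duration: float = 52.8) -> AcquisitionMeta:
    """Acquisition metadata matching the emulated clinical protocol."""
    return AcquisitionMeta(voxel_size=np.array([2.7, 2.7, 2.8]),
                           frame_duration=frame_duration, n_frames=n_frames,
                           venc=120.0)


@dataclass
class Waveform:
    """Cardiac flow waveform w(t) with values in [0, 1].

    ``half_sine`` is a systolic half sine of length ``systole_duration``
    followed by diastolic zero flow; ``constant`` is steady flow; ``table``
    uses the per-frame multipliers given in ``values`` (peak must be 1).
    """

    shape: str = "half_sine"
    systole_duration: float = 0.3
    cycle_duration: float = None
    values: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.shape not in ("half_sine", "constant", "table"):
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        if self.shape == "table":
            if self.values is None:
                raise ValueError("table waveform requires values")
            self.values = np.asarray(self.values, dtype=float)
            if self.values.min() < 0 or not np.isclose(self.values.max(), 1.0):
                raise ValueError("table multipliers must lie in [0, 1] and peak at 1")


def make_waveform(spec: Waveform, n_frames: int, frame_duration_ms: float = None):
    """Sample a waveform at frame midpoints and return its analytic integral.

    Returns ``(multipliers, integral_s)`` where ``multipliers`` has one value
    per frame and ``integral_s`` is the exact integral of the continuous
    waveform over the cycle in seconds (for ``table``: the rectangle sum).
    """
    if spec.cycle_duration is None:
        if frame_duration_ms is None:
            raise ValueError("cycle duration unknown: give frame_duration_ms")
        cycle = n_frames * frame_duration_ms / 1000.0
    else:
        cycle = spec.cycle_duration
    if spec.shape != "table" and not 0 < spec.systole_duration <= cycle:
        raise ValueError("systole_duration must lie in (0, cycle_duration]")
    dt = cycle / n_frames
    t_mid = (np.arange(n_frames) + 0.5) * dt
    if spec.shape == "constant":
        return np.ones(n_frames), cycle
    if spec.shape == "half_sine":
        ts = spec.systole_duration
        mult = np.where(t_mid < ts, np.sin(np.pi * t_mid / ts), 0.0)
        return np.clip(mult, 0.0, None), 2.0 * ts / np.pi
    # table
    if len(spec.values) != n_frames:
        raise ValueError("table length must equal n_frames")
    return spec.values.copy(), float(spec.values.sum() * dt)


@dataclass
class PhantomSpec:
    """Full description of a synthetic 4D flow dataset."""

    geometry: str = "straight_tube"
    grid_shape: tuple = (64, 64, 64)
    radius: float = 10.0                 # mm (trunk radius)
    v_max: float = 100.0                 # cm/s peak centreline velocity
    waveform: Waveform = field(default_factory=Waveform)
    split_fractions: tuple = (0.5, 0.5)  # Y-bifurcation flow split
    bend_amplitude: float = 8.0          # mm, curved_tube centreline bow
    branch_slope: float = 0.35           # Y-branch lateral slope (mm per mm)
    motion_amplitude: float = 0.0        # mm bulk/radial motion
    motion_mode: str = "bulk_sinusoidal"
    noise_sigma_vel: float = 0.0         # cm/s
    noise_sigma_mag: float = 0.0         # fraction of lumen magnitude
    background_poly: Optional[np.ndarray] = None  # (3, 10) cm/s coefficients
    wrap_inject: bool = False
    seed: int = 0
    grid: AcquisitionMeta = field(default_factory=default_meta)

    def __post_init__(self):
        if self.geometry not in ("straight_tube", "curved_tube",
                                 "y_bifurcation", "two_vessel"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.radius <= 0 or self.v_max <= 0:
            raise ValueError("radius and v_max must be positive")
        if self.noise_sigma_vel < 0 or self.noise_sigma_mag < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be nonnegative")
        if self.motion_mode not in ("bulk_sinusoidal", "radial_pulsation"):
            raise ValueError(f"unknown motion mode {self.motion_mode!r}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.background_poly is not None:
            self.background_poly = np.asarray(self.background_poly, dtype=float)
            if self.background_poly.shape != (3, N_POLY_TERMS):
                raise ValueError(f"background_poly must be (3, {N_POLY_TERMS})")


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom."""

    labels_t: np.ndarray                 # (nx, ny, nz, nt) int16
    plane_truth: dict                    # plane name -> net volume (ml)
    planes: list                         # list of Plane (world mm)
    vessel_names: dict                   # code -> name
    plane_vessel_codes: dict             # plane name -> label code
    motion_offsets_mm: np.ndarray        # (nt, 3) bulk offset per frame
    peak_frame_true: int
    waveform_multipliers: np.ndarray
    waveform_integral_s: float
    spec: PhantomSpec
    velocity_prewrap: Optional[np.ndarray] = None

    def labels(self, t: int) -> np.ndarray:
        return self.labels_t[..., t]

    def motion_field(self, t: int) -> np.ndarray:
        """Bulk displacement (mm) of frame ``t`` relative to the peak frame."""
        return self.motion_offsets_mm[t] - self.motion_offsets_mm[self.peak_frame_true]


# ---------------------------------------------------------------------------
# geometry

class _Branch:
    """A straight (possibly slanted) tube segment with Poiseuille flow."""

    def __init__(self, point, direction, radius, v_max, z_range, name):
        self.point = np.asarray(point, dtype=float)
        self.direction = np.asarray(direction, dtype=float)
        self.direction /= np.linalg.norm(self.direction)
        self.radius = float(radius)
        self.v_max = float(v_max)
        self.z_range = z_range
        self.name = name

    def evaluate(self, pts: np.ndarray):
        """(mask, unit-waveform velocity vectors) at world points (N, 3)."""
        rel = pts - self.point
        axial = rel @ self.direction
        radial = rel - axial[:, None] * self.direction[None, :]
        r = np.linalg.norm(radial, axis=1)
        mask = r <= self.radius
        if self.z_range is not None:
            z0, z1 = self.z_range
            mask &= (pts[:, 2] >= z0) & (pts[:, 2] < z1)
        prof = np.where(mask, self.v_max * (1.0 - (r / self.radius) ** 2), 0.0)
        vel = prof[:, None] * self.direction[None, :]
        return mask, vel

    @property
    def q_peak(self) -> float:
        """Peak flow rate through a perpendicular section, ml/s."""
        return self.v_max * np.pi * self.radius ** 2 / 2.0 * ML_PER_CM_S_MM2


class _CurvedTube:
    """Tube whose centreline bows sinusoidally in x along z (small slope)."""

    def __init__(self, center_xy, bend, radius, v_max, length_z, name):
        self.center_xy = np.asarray(center_xy, dtype=float)
        self.bend = float(bend)
        self.radius = float(radius)
        self.v_max = float(v_max)
        self.length_z = float(length_z)
        self.name = name

    def evaluate(self, pts: np.ndarray):
        z = pts[:, 2]
        cx = self.center_xy[0] + self.bend * np.sin(np.pi * z / self.length_z)
        dx = pts[:, 0] - cx
        dy = pts[:, 1] - self.center_xy[1]
        r = np.sqrt(dx ** 2 + dy ** 2)  # same-z section distance (small slope)
        mask = r <= self.radius
        slope = self.bend * np.pi / self.length_z * np.cos(np.pi * z / self.length_z)
        direction = np.stack([slope, np.zeros_like(slope), np.ones_like(slope)],
                             axis=1)
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        prof = np.where(mask, self.v_max * (1.0 - (r / self.radius) ** 2), 0.0)
        return mask, prof[:, None] * direction

    @property
    def q_peak(self) -> float:
        return self.v_max * np.pi * self.radius ** 2 / 2.0 * ML_PER_CM_S_MM2


def _build_geometry(spec: PhantomSpec):
    """Return (branches, planes, plane_codes, vessel_names, code_of_branch)."""
    meta = spec.grid
    # assume an axis-aligned grid for phantom generation
    lx, ly, lz = np.asarray(spec.grid_shape) * meta.voxel_size
    cx, cy = lx / 2.0, ly / 2.0
    r = spec.radius
    wf = spec.waveform
    planes, plane_codes, vessel_names = [], {}, {}
    branch_code = {}

    def perp_plane(name, origin, direction, radius):
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        # any orthonormal pair completing the triad
        helper = np.array([1.0, 0.0, 0.0])
        if abs(direction @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(direction, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(direction, e1)
        ext = radius + 8.0
        return Plane(name=name, origin=origin, normal=direction,
                     in_plane_axes=[e1, e2], extent=[ext, ext])

    if spec.geometry == "straight_tube":
        b = _Branch([cx, cy, 0.0], [0, 0, 1], r, spec.v_max, None, "tube")
        branches = [b]
        vessel_names[1] = "aorta"
        branch_code["tube"] = 1
        planes.append(perp_plane("tube_proximal", [cx, cy, 0.40 * lz], [0, 0, 1], r))
        planes.append(perp_plane("tube_distal", [cx, cy, 0.60 * lz], [0, 0, 1], r))
        plane_codes = {"tube_proximal": 1, "tube_distal": 1}
    elif spec.geometry == "curved_tube":
        b = _CurvedTube([cx, cy], spec.bend_amplitude, r, spec.v_max, lz, "tube")
        branches = [b]
        vessel_names[1] = "aorta"
        branch_code["tube"] = 1
        planes.append(perp_plane("tube_mid", [cx + spec.bend_amplitude, cy,
                                              0.5 * lz], [0, 0, 1], r))
        plane_codes = {"tube_mid": 1}
    elif spec.geometry == "two_vessel":
        c1x, c2x = 0.32 * lx, 0.68 * lx
        if c2x - c1x < 2 * r + 2:
            raise ValueError("vessels overlap: radius too large for the grid")
        b1 = _Branch([c1x, cy, 0.0], [0, 0, 1], r, spec.v_max, None, "vessel_1")
        b2 = _Branch([c2x, cy, 0.0], [0, 0, 1], r, spec.v_max, None, "vessel_2")
        branches = [b1, b2]
        vessel_names = {1: "aorta", 2: "pulmonary_artery"}
        branch_code = {"vessel_1": 1, "vessel_2": 2}
        planes.append(perp_plane("aorta_plane", [c1x, cy, 0.5 * lz], [0, 0, 1], r))
        planes.append(perp_plane("pa_plane", [c2x, cy, 0.5 * lz], [0, 0, 1], r))
        plane_codes = {"aorta_plane": 1, "pa_plane": 2}
    else:  # y_bifurcation
        z_split = 0.5 * lz
        s = spec.branch_slope
        f_left, f_right = spec.split_fractions
        trunk = _Branch([cx, cy, 0.0], [0, 0, 1], r, spec.v_max,
                        (-np.inf, z_split), "trunk")
        dir_l = [-s, 0.0, 1.0]
        dir_r = [+s, 0.0, 1.0]
        r_l, r_r = r * np.sqrt(f_left), r * np.sqrt(f_right)
        left = _Branch([cx, cy, z_split], dir_l, r_l, spec.v_max,
                       (z_split, np.inf), "left")
        right = _Branch([cx, cy, z_split], dir_r, r_r, spec.v_max,
                        (z_split, np.inf), "right")
        branches = [trunk, left, right]
        vessel_names = {1: "pulmonary_artery"}
        branch_code = {"trunk": 1, "left": 1, "right": 1}
        planes.append(perp_plane("trunk_plane", [cx, cy, 0.30 * lz], [0, 0, 1], r))
        zp = 0.80 * lz
        norm_l = np.asarray(dir_l) / np.linalg.norm(dir_l)
        norm_r = np.asarray(dir_r) / np.linalg.norm(dir_r)
        cl = np.array([cx, cy, z_split]) + norm_l * ((zp - z_split) / norm_l[2])
        cr = np.array([cx, cy, z_split]) + norm_r * ((zp - z_split) / norm_r[2])
        planes.append(perp_plane("left_branch_plane", cl, dir_l, r_l))
        planes.append(perp_plane("right_branch_plane", cr, dir_r, r_r))
        plane_codes = {"trunk_plane": 1, "left_branch_plane": 1,
                       "right_branch_plane": 1}
    return branches, planes, plane_codes, vessel_names, branch_code


def _plane_truth(spec: PhantomSpec, branches, plane_codes, integral_s) -> dict:
    truth = {}
    for name in plane_codes:
        if spec.geometry == "y_bifurcation":
            trunk, left, right = branches
            q = {"trunk_plane": trunk.q_peak,
                 "left_branch_plane": left.q_peak,
                 "right_branch_plane": right.q_peak}[name]
        elif spec.geometry == "two_vessel":
            q = branches[0].q_peak  # equal radii and waveform in both vessels
        else:
            q = branches[0].q_peak
        truth[name] = q * integral_s
    return truth


def make_phantom(spec: PhantomSpec):
    """Generate a synthetic 4D flow dataset and its analytic ground truth.

    Returns ``(flow, truth)``.  Raises when the lumen touches the lateral
    grid boundary (including after motion) or when vessels overlap.
    """
    meta = spec.grid
    shape = tuple(spec.grid_shape)
    nt = meta.n_frames
    mult, integral_s = make_waveform(spec.waveform, nt, meta.frame_duration)
    peak_frame = int(np.argmax(mult))
    branches, planes, plane_codes, vessel_names, branch_code = _build_geometry(spec)

    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    pts = meta.voxel_to_world(idx)

    offsets = np.zeros((nt, 3))
    radius_scale = np.ones(nt)
    if spec.motion_amplitude > 0:
        phase = np.sin(2.0 * np.pi * np.arange(nt) / nt)
        if spec.motion_mode == "bulk_sinusoidal":
            offsets[:, 0] = spec.motion_amplitude * phase
        else:  # radial_pulsation
            radius_scale = 1.0 + spec.motion_amplitude * phase / spec.radius

    rng = np.random.default_rng(spec.seed)
    magnitude = np.empty(shape + (nt,))
    velocity = np.zeros(shape + (nt, 3))
    labels_t = np.zeros(shape + (nt,), dtype=np.int16)
    shell = _static_shell(shape).reshape(-1)

    base_cache = {}
    for t in range(nt):
        key = (tuple(offsets[t]), radius_scale[t])
        if key not in base_cache:
            q = pts - offsets[t][None, :]
            mask_any = np.zeros(len(pts), dtype=bool)
            vel_unit = np.zeros((len(pts), 3))
            lab = np.zeros(len(pts), dtype=np.int16)
            for br in branches:
                saved_r = br.radius
                br.radius = saved_r * radius_scale[t]
                m, v = br.evaluate(q)
                br.radius = saved_r
                new = m & ~mask_any
                vel_unit[new] = v[new]
                lab[new] = branch_code[br.name]
                mask_any |= m
            _check_in_grid(mask_any.reshape(shape))
            base_cache[key] = (mask_any, vel_unit, lab)
        mask_any, vel_unit, lab = base_cache[key]
        velocity[..., t, :] = (vel_unit * mult[t]).reshape(shape + (3,))
        labels_t[..., t] = lab.reshape(shape)
        mag = np.full(len(pts), BACKGROUND_MAG)
        mag[shell] = SHELL_MAG
        mag[mask_any] = LUMEN_MAG
        magnitude[..., t] = mag.reshape(shape)

    if spec.background_poly is not None:
        offset_field = (_poly_design(shape) @ spec.background_poly.T)
        velocity += offset_field.reshape(shape + (3,))[:, :, :, None, :]
    if spec.noise_sigma_vel > 0:
        velocity += rng.normal(0.0, spec.noise_sigma_vel, velocity.shape)
    if spec.noise_sigma_mag > 0:
        magnitude += rng.normal(0.0, spec.noise_sigma_mag * LUMEN_MAG,
                                magnitude.shape)
        magnitude = np.clip(magnitude, 0.0, None)

    velocity_prewrap = None
    if spec.wrap_inject:
        venc = meta.venc
        if np.abs(velocity).max() > venc:
            velocity_prewrap = velocity.copy()
            velocity = np.mod(velocity + venc, 2.0 * venc) - venc

    flow = Flow4D(magnitude=magnitude, velocity=velocity, meta=meta)
    truth = PhantomTruth(
        labels_t=labels_t,
        plane_truth=_plane_truth(spec, branches, plane_codes, integral_s),
        planes=planes,
        vessel_names=vessel_names,
        plane_vessel_codes=plane_codes,
        motion_offsets_mm=offsets,
        peak_frame_true=peak_frame,
        waveform_multipliers=mult,
        waveform_integral_s=integral_s,
        spec=spec,
        velocity_prewrap=velocity_prewrap,
    )
    return flow, truth


def apply_motion(flow: Flow4D, truth: PhantomTruth, amplitude: float,
                 mode: str = "bulk_sinusoidal"):
    """Regenerate a phantom with per-frame geometric motion.

    ``amplitude`` is in mm; ``bulk_sinusoidal`` displaces the whole geometry
    along x by ``amplitude * sin(2 pi k / n)`` at frame k, while
    ``radial_pulsation`` modulates the lumen radius by the same factor.
    Amplitude 0 returns an identical phantom.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    spec = replace(truth.spec, motion_amplitude=amplitude, motion_mode=mode)
    return make_phantom(spec)


def _static_shell(shape) -> np.ndarray:
    """Boolean static-tissue shell: a 3-voxel-thick box 2 voxels in from the border."""
    inner = np.zeros(shape, dtype=bool)
    outer = np.zeros(shape, dtype=bool)
    outer[2:-2, 2:-2, 2:-2] = True
    inner[5:-5, 5:-5, 5:-5] = True
    return outer & ~inner


def _check_in_grid(lumen: np.ndarray) -> None:
    if (lumen[0, :, :].any() or lumen[-1, :, :].any()
            or lumen[:, 0, :].any() or lumen[:, -1, :].any()):
        raise ValueError("tube leaves the grid laterally (or motion pushes it off-grid)")
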