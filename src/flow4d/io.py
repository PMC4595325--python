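"""Data model and file I/O for 4D flow CMR datasets and atlases.

A 4D flow CMR acquisition yields a time-resolved magnitude volume plus three
time-resolved velocity-component volumes on a shared voxel grid.  Volumes are
stored one NIfTI file per component with a JSON sidecar carrying the
acquisition metadata (voxel size, frame duration, VENC, grid-to-world affine);
a single 5D container is also accepted on read.  Velocities are always held
internally in cm/s; phase-scaled inputs are converted at ingest.

Atlases bundle a phase-contrast MR angiogram (PC-MRA), an integer label
volume (one positive code per vessel), and named 2D analysis-plane
definitions.  All plane geometry is stored in world millimetres so atlases
survive resampling; voxel indices are 0-based and world coordinates come only
from the grid-to-world affine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionMeta",
    "Flow4D",
    "Plane",
    "Atlas",
    "Segmentation4D",
    "phase_to_velocity",
    "load_flow4d",
    "save_flow4d",
    "load_atlas",
    "save_atlas",
    "save_segmentation4d",
    "load_segmentation4d",
]


class GridMismatchError(ValueError):
    """Raised when volumes that must share one voxel grid do not."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Physical metadata of a 4D flow acquisition.

    Parameters
    ----------
    voxel_size : (3,) array-like
        Voxel edge lengths in mm per axis.
    frame_duration : float
        Duration of one cardiac frame in ms.
    n_frames : int
        Number of reconstructed cardiac frames (>= 2).
    venc : float
        Velocity-encoding limit in cm/s; velocities of +/-venc map to
        phase +/-pi.
    grid_to_world : (4, 4) array-like, optional
        Affine mapping 0-based voxel indices to physical mm.  Defaults to a
        diagonal scaling by ``voxel_size``.
    """

    voxel_size: np.ndarray
    frame_duration: float
    n_frames: int
    venc: float
    grid_to_world: np.ndarray = None

    def __post_init__(self):
        vs = np.asarray(self.voxel_size, dtype=float)
        if vs.shape != (3,) or np.any(vs <= 0):
            raise ValueError("voxel_size must be 3 positive lengths (mm)")
        object.__setattr__(self, "voxel_size", vs)
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive (ms)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.venc <= 0:
            raise ValueError("venc must be positive (cm/s)")
        g2w = self.grid_to_world
        if g2w is None:
            g2w = np.diag([vs[0], vs[1], vs[2], 1.0])
        g2w = np.asarray(g2w, dtype=float)
        if g2w.shape != (4, 4) or abs(np.linalg.det(g2w)) < 1e-12:
            raise ValueError("grid_to_world must be an invertible 4x4 affine")
        object.__setattr__(self, "grid_to_world", g2w)

    @property
    def cycle_duration_s(self) -> float:
        """Length of the reconstructed cardiac cycle in seconds."""
        return self.n_frames * self.frame_duration / 1000.0

    def voxel_to_world(self, pts_vox: np.ndarray) -> np.ndarray:
        """Map 0-based voxel coordinates (..., 3) to world mm."""
        pts = np.atleast_2d(np.asarray(pts_vox, dtype=float))
        out = pts @ self.grid_to_world[:3, :3].T + self.grid_to_world[:3, 3]
        return out.reshape(np.shape(pts_vox))

    def world_to_voxel(self, pts_mm: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to 0-based voxel coordinates."""
        inv = np.linalg.inv(self.grid_to_world)
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        out = pts @ inv[:3, :3].T + inv[:3, 3]
        return out.reshape(np.shape(pts_mm))

    def to_dict(self) -> dict:
        return {
            "voxel_size_mm": self.voxel_size.tolist(),
            "frame_duration_ms": float(self.frame_duration),
            "n_frames": int(self.n_frames),
            "venc_cm_s": float(self.venc),
            "grid_to_world": self.grid_to_world.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(
            voxel_size=np.asarray(d["voxel_size_mm"], dtype=float),
            frame_duration=float(d["frame_duration_ms"]),
            n_frames=int(d["n_frames"]),
            venc=float(d["venc_cm_s"]),
            grid_to_world=np.asarray(d["grid_to_world"], dtype=float),
        )


@dataclass
class Flow4D:
    """Time-resolved magnitude and three-directional velocity volumes.

    ``magnitude`` has shape (nx, ny, nz, nt) with nonnegative arbitrary
    units; ``velocity`` has shape (nx, ny, nz, nt, 3) in cm/s.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.magnitude.ndim != 4:
            raise ValueError("magnitude must be 4D (x, y, z, t)")
        if self.velocity.shape != self.magnitude.shape + (3,):
            raise GridMismatchError(
                "grid mismatch: velocity shape %s incompatible with magnitude %s"
                % (self.velocity.shape, self.magnitude.shape)
            )
        if self.magnitude.shape[3] != self.meta.n_frames:
            raise GridMismatchError("frame count differs from metadata n_frames")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.magnitude.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[3]

    def speed(self) -> np.ndarray:
        """Per-voxel, per-frame speed |v| in cm/s, shape (nx, ny, nz, nt)."""
        return np.sqrt(np.sum(self.velocity ** 2, axis=-1))

    def copy(self) -> "Flow4D":
        return Flow4D(self.magnitude.copy(), self.velocity.copy(), self.meta)


@dataclass
class Plane:
    """A named 2D analysis plane defined in world mm coordinates.

    ``normal`` and the two ``in_plane_axes`` form a right-handed orthonormal
    triad; ``sample_points`` is the (N, 3) patch of world points that is
    pushed through registration deformations before the plane is re-fitted.
    """

    name: str
    origin: np.ndarray
    normal: np.ndarray
    in_plane_axes: np.ndarray
    extent: np.ndarray
    sample_points: np.ndarray = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.in_plane_axes = np.asarray(self.in_plane_axes, dtype=float).reshape(2, 3)
        self.extent = np.asarray(self.extent, dtype=float).reshape(2)
        n_len = np.linalg.norm(self.normal)
        if not math.isclose(n_len, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError(f"plane {self.name!r}: normal must be unit length")
        for i, ax in enumerate(self.in_plane_axes):
            if not math.isclose(np.linalg.norm(ax), 1.0, rel_tol=0, abs_tol=1e-6):
                raise ValueError(f"plane {self.name!r}: in-plane axis {i} not unit length")
            if abs(np.dot(self.normal, ax)) > 1e-6:
                raise ValueError(f"plane {self.name!r}: normal not orthogonal to axis {i}")
        if self.sample_points is None:
            self.sample_points = self._default_patch()
        self.sample_points = np.asarray(self.sample_points, dtype=float).reshape(-1, 3)

    def _default_patch(self, n_per_axis: int = 7) -> np.ndarray:
        u = np.linspace(-self.extent[0], self.extent[0], n_per_axis)
        v = np.linspace(-self.extent[1], self.extent[1], n_per_axis)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        pts = (self.origin[None, :]
               + uu.reshape(-1, 1) * self.in_plane_axes[0][None, :]
               + vv.reshape(-1, 1) * self.in_plane_axes[1][None, :])
        return pts

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "origin_mm": self.origin.tolist(),
            "normal": self.normal.tolist(),
            "in_plane_axes": self.in_plane_axes.tolist(),
            "extent_mm": self.extent.tolist(),
            "sample_points_mm": self.sample_points.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls(
            name=d["name"],
            origin=d["origin_mm"],
            normal=d["normal"],
            in_plane_axes=d["in_plane_axes"],
            extent=d["extent_mm"],
            sample_points=d.get("sample_points_mm"),
        )


@dataclass
class Atlas:
    """Pre-labelled reference: PC-MRA, vessel label masks and analysis planes."""

    pcmra: np.ndarray
    labels: np.ndarray
    vessel_names: dict
    planes: list
    meta: AcquisitionMeta

    def __post_init__(self):
        self.pcmra = np.asarray(self.pcmra, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        if self.labels.shape != self.pcmra.shape:
            raise GridMismatchError("labels and pcmra must share one grid")
        if np.any(self.pcmra < 0):
            raise ValueError("pcmra must be nonnegative")
        codes = set(int(c) for c in np.unique(self.labels)) - {0}
        named = set(int(c) for c in self.vessel_names)
        if not codes <= named:
            raise ValueError(f"unnamed label codes: {sorted(codes - named)}")
        names = [p.name for p in self.planes]
        if len(names) != len(set(names)):
            raise ValueError("plane names must be unique")

    @property
    def codes(self) -> list:
        return sorted(int(c) for c in np.unique(self.labels) if c != 0)


@dataclass
class Segmentation4D:
    """Per-frame vessel label volumes following the vessels over the cycle."""

    labels_t: np.ndarray  # (nx, ny, nz, nt) integer
    source_frame: int

    def __post_init__(self):
        self.labels_t = np.asarray(self.labels_t)
        if self.labels_t.ndim != 4:
            raise ValueError("labels_t must be 4D (x, y, z, t)")
        if not np.issubdtype(self.labels_t.dtype, np.integer):
            raise ValueError("labels_t must be integer-valued")
        if not 0 <= self.source_frame < self.labels_t.shape[3]:
            raise ValueError("source_frame out of range")

    @property
    def n_frames(self) -> int:
        return self.labels_t.shape[3]

    def frame(self, t: int) -> np.ndarray:
        return self.labels_t[..., t]


def phase_to_velocity(phase_value, venc: float):
    """Convert phase-encoded values (radians in [-pi, pi]) to velocity in cm/s.

    The standard phase-contrast MRI convention maps phase +/-pi to velocity
    +/-venc linearly: ``v = phase / pi * venc``.
    """
    if venc <= 0:
        raise ValueError("venc must be positive")
    return np.asarray(phase_value, dtype=float) / np.pi * venc


# ---------------------------------------------------------------------------
# Flow4D file I/O

_COMPONENT_NAMES = ("mag", "vx", "vy", "vz")


def _read_nifti(path: Path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), np.asarray(img.affine, float)


def save_flow4d(flow: Flow4D, directory) -> None:
    """Write a Flow4D as four 4D NIfTI files plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = flow.meta.grid_to_world
    arrays = [flow.magnitude] + [flow.velocity[..., i] for i in range(3)]
    for name, arr in zip(_COMPONENT_NAMES, arrays):
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine),
                 str(directory / f"{name}.nii.gz"))
    meta = flow.meta.to_dict()
    meta["dialect"] = "velocity-cm/s"
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_flow4d(paths, dialect: str = "velocity-cm/s",
                meta: AcquisitionMeta = None) -> Flow4D:
    """Load a 4D flow dataset from NIfTI files.

    Parameters
    ----------
    paths : str, Path or sequence of 4 paths
        Either a directory written by :func:`save_flow4d`, a single 5D NIfTI
        container (last axis = [mag, vx, vy, vz]), or an explicit sequence
        ``[magnitude, vx, vy, vz]``.
    dialect : {"velocity-cm/s", "phase-scaled"}
        In the phase-scaled dialect the component volumes hold phase values
        in radians and are converted with :func:`phase_to_velocity`, which
        requires the sidecar (or ``meta``) to carry the VENC.
    meta : AcquisitionMeta, optional
        Overrides/replaces the JSON sidecar.
    """
    if dialect not in ("velocity-cm/s", "phase-scaled"):
        raise ValueError(f"unknown dialect {dialect!r}")

    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if p.is_dir():
            file_list = [p / f"{n}.nii.gz" for n in _COMPONENT_NAMES]
            for cand in list(file_list):
                if not cand.exists():
                    alt = cand.with_suffix("").with_suffix(".nii")
                    if alt.exists():
                        file_list[file_list.index(cand)] = alt
            sidecar = p / "meta.json"
            if meta is None:
                if not sidecar.exists():
                    raise FileNotFoundError(f"missing sidecar {sidecar}")
                meta = AcquisitionMeta.from_dict(json.loads(sidecar.read_text()))
            missing = [f for f in file_list if not f.exists()]
            if missing:
                raise FileNotFoundError(f"missing volume file(s): {missing}")
            vols = []
            for f in file_list:
                arr, _ = _read_nifti(f)
                vols.append(arr)
        else:
            # single 5D container
            arr, _ = _read_nifti(p)
            if arr.ndim != 5 or arr.shape[-1] != 4:
                raise ValueError("5D container must have shape (x, y, z, t, 4)")
            if meta is None:
                sidecar = p.with_suffix("").with_suffix(".json")
                if not sidecar.exists():
                    raise FileNotFoundError(f"missing sidecar {sidecar}")
                meta = AcquisitionMeta.from_dict(json.loads(sidecar.read_text()))
            vols = [arr[..., i] for i in range(4)]
    else:
        file_list = [Path(f) for f in paths]
        if len(file_list) != 4:
            raise ValueError("expected 4 paths: magnitude, vx, vy, vz")
        missing = [f for f in file_list if not f.exists()]
        if missing:
            raise FileNotFoundError(f"missing volume file(s): {missing}")
        if meta is None:
            sidecar = file_list[0].parent / "meta.json"
            if not sidecar.exists():
                raise FileNotFoundError(f"missing sidecar {sidecar}")
            meta = AcquisitionMeta.from_dict(json.loads(sidecar.read_text()))
        vols = [_read_nifti(f)[0] for f in file_list]

    mag = vols[0]
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise GridMismatchError(f"grid mismatch across component volumes: {shapes}")
    if mag.ndim != 4:
        raise ValueError("component volumes must be 4D (x, y, z, t)")

    vel = np.stack(vols[1:], axis=-1)
    if dialect == "phase-scaled":
        vel = phase_to_velocity(vel, meta.venc)
    return Flow4D(magnitude=mag, velocity=vel, meta=meta)


# ---------------------------------------------------------------------------
# Atlas file I/O

def save_atlas(atlas: Atlas, directory) -> None:
    """Write an atlas as pcmra + labels NIfTI files with a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = atlas.meta.grid_to_world
    nib.save(nib.Nifti1Image(atlas.pcmra.astype(np.float32), affine),
             str(directory / "pcmra.nii.gz"))
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine),
             str(directory / "labels.nii.gz"))
    sidecar = {
        "meta": atlas.meta.to_dict(),
        "vessel_names": {str(k): v for k, v in atlas.vessel_names.items()},
        "planes": [p.to_dict() for p in atlas.planes],
    }
    (directory / "atlas.json").write_text(json.dumps(sidecar, indent=2))


def load_atlas(directory) -> Atlas:
    """Load an atlas written by :func:`save_atlas`.

    Plane definitions are validated on load; a sidecar with a non-unit
    plane normal is rejected.
    """
    directory = Path(directory)
    sidecar_path = directory / "atlas.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing atlas sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        meta = AcquisitionMeta.from_dict(sidecar["meta"])
        vessel_names = {int(k): v for k, v in sidecar["vessel_names"].items()}
        planes = [Plane.from_dict(d) for d in sidecar["planes"]]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed atlas sidecar: {exc}") from exc
    pcmra, _ = _read_nifti(directory / "pcmra.nii.gz")
    labels_img = nib.load(str(directory / "labels.nii.gz"))
    labels = np.asarray(labels_img.dataobj).astype(np.int16)
    return Atlas(pcmra=pcmra, labels=labels, vessel_names=vessel_names,
                 planes=planes, meta=meta)


def save_segmentation4d(seg: Segmentation4D, path, meta: AcquisitionMeta) -> None:
    """Write a time-resolved segmentation as one 4D NIfTI label volume."""
    nib.save(nib.Nifti1Image(seg.labels_t.astype(np.int16), meta.grid_to_world),
             str(path))


def load_segmentation4d(path, source_frame: int = 0) -> Segmentation4D:
    img = nib.load(str(path))
    return Segmentation4D(np.asarray(img.dataobj).astype(np.int16), source_frame)
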