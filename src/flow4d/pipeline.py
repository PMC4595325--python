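"""End-to-end pipeline: preprocess -> PC-MRA -> atlas fit -> 4D segmentation
-> plane flow, with caching, diagnostics and deterministic reports.

A single JSON configuration file names the input 4D flow dataset, the atlas,
and the output directory, and exposes every stage parameter.  Registration
results are cached under ``<out>/cache`` so re-runs on the same subject skip
the expensive registration stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .angio import compute_pcmra, detect_systole
from .atlas_seg import fit_atlas, propagate_temporal
from .plane_flow import fit_plane_pca, linear_regression, quantify_plane
from .preprocess import (
    EmptyMaskError,
    correct_background,
    detect_static_tissue,
    fit_background,
    unwrap_temporal,
)
from .registration import AffineTransform, DisplacementField, RegistrationParams

log = logging.getLogger("flow4d.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_file``/``from_dict``)."""

    input_dir: str
    atlas_dir: str
    out_dir: str
    enable_unwrap: bool = True
    enable_background: bool = True
    mag_frac: float = 0.1
    vel_std_max: float = 2.0
    anchor_frame: int = 0
    systolic_frac: float = 0.7
    atlas_scales: int = 3
    temporal_scales: int = 5
    iters_per_scale: int = 5
    sigma_fluid: float = 2.0
    sigma_elastic: float = 1.5
    plane_spacing: float = None    # mm; None -> min(voxel)/2
    radius_px: int = 9
    keep_frac: float = 0.1
    use_cache: bool = True
    reference_volumes: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        for key in ("input_dir", "atlas_dir", "out_dir"):
            if key not in d:
                raise ConfigError(f"config missing required key {key!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        return cls.from_dict(json.loads(path.read_text()))

    def atlas_params(self) -> RegistrationParams:
        return RegistrationParams(n_scales=self.atlas_scales,
                                  iters_per_scale=self.iters_per_scale,
                                  sigma_fluid=self.sigma_fluid,
                                  sigma_elastic=self.sigma_elastic)

    def temporal_params(self) -> RegistrationParams:
        return RegistrationParams(n_scales=self.temporal_scales,
                                  iters_per_scale=self.iters_per_scale,
                                  sigma_fluid=self.sigma_fluid,
                                  sigma_elastic=self.sigma_elastic)

    def cache_key(self) -> str:
        """Stable hash of every parameter that affects registration outputs."""
        import hashlib
        payload = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)
                   if k not in ("out_dir", "use_cache", "reference_volumes")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the pipeline computed for one subject."""

    seg: fio.Segmentation4D
    flow_results: list            # list of FlowResult
    plane_vessel_codes: dict
    fit_diagnostics: dict
    temporal_diagnostics: list
    regressions: dict             # name -> RegressionResult
    peak_frame: int
    meta: fio.AcquisitionMeta
    stage_seconds: dict = field(default_factory=dict)


def _plane_vessel_code(atlas: fio.Atlas, plane: fio.Plane) -> int:
    """Vessel code a plane measures: the nearest nonzero atlas label."""
    vox = np.round(atlas.meta.world_to_voxel(plane.origin)).astype(int)
    vox = np.clip(vox, 0, np.array(atlas.labels.shape) - 1)
    code = int(atlas.labels[tuple(vox)])
    if code != 0:
        return code
    nz = np.argwhere(atlas.labels != 0)
    if nz.size == 0:
        raise ConfigError("atlas has no labelled voxels")
    dist = np.sum((nz - vox[None, :]) ** 2, axis=1)
    return int(atlas.labels[tuple(nz[np.argmin(dist)])])


def run_pipeline(config) -> PipelineResult:
    """Run the full analysis described by a config file, dict or object.

    Stages: optional velocity preprocessing (temporal unwrapping, background
    polynomial correction), PC-MRA computation and systole detection, atlas
    fitting, temporal propagation to a 4D segmentation, and flow
    quantification at every atlas plane.  Results and diagnostics are
    written to ``out_dir`` via :func:`write_report`.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_file(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seconds = {}

    def _timed(name, fn, *a, **kw):
        t0 = time.perf_counter()
        out = fn(*a, **kw)
        stage_seconds[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: %.2fs", name, stage_seconds[name])
        return out

    flow = _timed("load", fio.load_flow4d, config.input_dir)
    atlas = _timed("load_atlas", fio.load_atlas, config.atlas_dir)

    if config.enable_unwrap:
        flow = _timed("unwrap", unwrap_temporal, flow, config.anchor_frame)
    if config.enable_background:
        def _bg(flow):
            try:
                static = detect_static_tissue(flow, config.mag_frac,
                                              config.vel_std_max)
                model = fit_background(flow, static)
                return correct_background(flow, model)
            except (EmptyMaskError, ValueError) as exc:
                log.warning("background correction skipped: %s", exc)
                return flow
        flow = _timed("background", _bg, flow)

    curve = detect_systole(flow, config.systolic_frac)
    pcmra = _timed("pcmra", compute_pcmra, flow, curve.systolic_set)

    cache_dir = out_dir / "cache"
    key = config.cache_key()
    fit_cache = cache_dir / f"atlas_fit_{key}.npz"
    seg_cache = cache_dir / f"seg4d_{key}.npz"

    if config.use_cache and fit_cache.exists():
        log.info("atlas fit loaded from cache")
        fit = _load_fit_cache(fit_cache)
        stage_seconds["fit_atlas"] = 0.0
    else:
        fit = _timed("fit_atlas", fit_atlas, atlas, pcmra,
                     config.atlas_params(), flow.meta)
        if config.use_cache:
            cache_dir.mkdir(exist_ok=True)
            _save_fit_cache(fit_cache, fit)

    if config.use_cache and seg_cache.exists():
        log.info("4D segmentation loaded from cache")
        with np.load(seg_cache, allow_pickle=True) as z:
            seg = fio.Segmentation4D(z["labels_t"], int(z["source_frame"]))
            temporal_diag = list(z["diagnostics"])
        stage_seconds["propagate"] = 0.0
    else:
        seg, temporal_diag = _timed(
            "propagate", propagate_temporal, flow, fit.labels,
            curve.peak_frame, config.temporal_params(),
            return_diagnostics=True)
        if config.use_cache:
            cache_dir.mkdir(exist_ok=True)
            np.savez_compressed(seg_cache, labels_t=seg.labels_t,
                                source_frame=seg.source_frame,
                                diagnostics=np.array(temporal_diag, dtype=object))

    plane_codes = {p.name: _plane_vessel_code(atlas, p) for p in atlas.planes}
    flow_results = []
    t0 = time.perf_counter()
    for plane in atlas.planes:
        pts = fit.plane_points[plane.name]
        ok = fit.plane_in_bounds[plane.name]
        if ok.sum() >= 3:
            pts = pts[ok]
        fitted_plane = fit_plane_pca(pts, reference_normal=plane.normal)
        # a deformed plane patch cannot legitimately grow beyond twice the
        # atlas plane; larger extents indicate stray mapped points
        fitted_plane.extent = np.minimum(fitted_plane.extent, 2.0 * plane.extent)
        fitted_plane.name = plane.name
        result = quantify_plane(flow, seg, fitted_plane,
                                plane_codes[plane.name],
                                spacing=config.plane_spacing,
                                radius_px=config.radius_px,
                                keep_frac=config.keep_frac)
        flow_results.append(result)
    stage_seconds["plane_flow"] = round(time.perf_counter() - t0, 3)

    regressions = {}
    ref = config.reference_volumes
    if ref:
        auto = {r.plane_name: r.net_volume for r in flow_results}
        common = sorted(set(auto) & set(ref))
        if len(common) >= 3:
            x = [ref[n] for n in common]
            y = [auto[n] for n in common]
            try:
                regressions["auto_vs_reference"] = linear_regression(x, y)
            except ValueError as exc:
                log.warning("regression skipped: %s", exc)

    result = PipelineResult(
        seg=seg, flow_results=flow_results, plane_vessel_codes=plane_codes,
        fit_diagnostics=fit.diagnostics, temporal_diagnostics=temporal_diag,
        regressions=regressions, peak_frame=curve.peak_frame, meta=flow.meta,
        stage_seconds=stage_seconds)
    write_report(result, out_dir)
    return result


def _save_fit_cache(path, fit) -> None:
    np.savez_compressed(
        path, labels=fit.labels, matrix=fit.affine.matrix,
        translation=fit.affine.translation, d=fit.displacement.d,
        certainty=fit.displacement.certainty,
        plane_names=np.array(sorted(fit.plane_points), dtype=object),
        plane_points=np.array([fit.plane_points[n]
                               for n in sorted(fit.plane_points)], dtype=object),
        plane_ok=np.array([fit.plane_in_bounds[n]
                           for n in sorted(fit.plane_points)], dtype=object),
        diagnostics=json.dumps(fit.diagnostics))


def _load_fit_cache(path):
    from .atlas_seg import AtlasFitResult
    with np.load(path, allow_pickle=True) as z:
        names = list(z["plane_names"])
        return AtlasFitResult(
            labels=z["labels"],
            affine=AffineTransform(z["matrix"], z["translation"]),
            displacement=DisplacementField(z["d"], z["certainty"]),
            plane_points={n: np.asarray(p, dtype=float)
                          for n, p in zip(names, z["plane_points"])},
            plane_in_bounds={n: np.asarray(p, dtype=bool)
                             for n, p in zip(names, z["plane_ok"])},
            diagnostics=json.loads(str(z["diagnostics"])))


def write_report(result: PipelineResult, out_dir) -> dict:
    """Write the deterministic report file set; returns the file paths.

    Produces ``summary.json`` (net volumes, flow ratios, diagnostics,
    regressions; keys sorted, no timestamps), ``flows.csv`` (one row per
    plane and frame), ``diagnostics.csv`` (per-frame registration quality)
    and ``seg4d.nii.gz``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out_dir / "summary.json",
        "flows": out_dir / "flows.csv",
        "diagnostics": out_dir / "diagnostics.csv",
        "seg4d": out_dir / "seg4d.nii.gz",
    }

    rows = []
    for r in result.flow_results:
        for t, q in enumerate(r.flow_rate):
            rows.append({"plane": r.plane_name, "frame": t,
                         "flow_rate_ml_s": q})
    pd.DataFrame(rows, columns=["plane", "frame", "flow_rate_ml_s"]).to_csv(
        paths["flows"], index=False)

    pd.DataFrame(result.temporal_diagnostics).to_csv(paths["diagnostics"],
                                                     index=False)

    net = {r.plane_name: r.net_volume for r in result.flow_results}
    summary = {
        "net_volumes_ml": {k: round(v, 6) for k, v in sorted(net.items())},
        "plane_vessel_codes": dict(sorted(result.plane_vessel_codes.items())),
        "peak_frame": result.peak_frame,
        "fit_diagnostics": {k: round(float(v), 6)
                            for k, v in sorted(result.fit_diagnostics.items())},
        "volume_ratios": _volume_ratios(net),
        "regressions": {
            name: {"slope": reg.slope, "intercept": reg.intercept,
                   "r_squared": reg.r_squared, "p_value": reg.p_value,
                   "significant": reg.significant}
            for name, reg in sorted(result.regressions.items())},
        "stage_seconds": dict(sorted(result.stage_seconds.items())),
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))

    if result.seg is not None:
        fio.save_segmentation4d(result.seg, paths["seg4d"], result.meta)
    return paths


def _volume_ratios(net: dict) -> dict:
    """Ratios between each pair of measured planes (Qp/Qs-style summaries)."""
    ratios = {}
    names = sorted(net)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if net[b] != 0:
                ratios[f"{a}/{b}"] = round(net[a] / net[b], 6)
    return ratios
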