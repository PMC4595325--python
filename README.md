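# flow4d

Fully automatic atlas-based segmentation and flow quantification for
**4D flow cardiovascular MR** (time-resolved 3D phase-contrast CMR with
three-directional velocity encoding).

Clinically, net flow volumes in the great thoracic vessels — aorta,
pulmonary artery, caval veins — are measured by semi-automatically
segmenting a vessel in a manually placed 2D phase-contrast plane.  4D flow
CMR acquires velocity everywhere in the chest over the whole cardiac cycle,
so analysis planes can be placed retrospectively at any location; the
bottleneck is the analysis itself.  `flow4d` automates it end to end:

1. **PC-MRA** — a static angiogram is computed from the systolic frames,
   `PC_MRA = M·√(V̄x² + V̄y² + V̄z²)`, where the bars denote averages over
   systole and the magnitude `M` suppresses noise in low-signal regions.
2. **Atlas-based segmentation** — a pre-labelled reference PC-MRA (the
   *atlas*, carrying vessel masks and named analysis planes) is registered
   to the subject's PC-MRA with affine followed by Morphon-style non-rigid
   registration (3 scales × 5 iterations, diffeomorphic field accumulation,
   fluid + elastic regularization); the labels and planes are carried
   through the deformation.
3. **4D vessel segmentation** — the systolic magnitude frame with the
   highest angiographic signal is registered to every other cardiac frame
   independently (5 scales × 5 iterations, on a structure-tensor edge
   representation), giving a segmentation that follows vessel motion over
   the cycle.
4. **Flow quantification** — each deformed plane is re-fitted flat by PCA,
   velocities are sampled on it by linear interpolation masked by the
   time-resolved segmentation (the mask smoothed with a 9-pixel circular
   averaging filter), and the signed flow rate
   `Q(t) = Σ (v·n̂)·ΔA` is integrated over the cycle into a net volume in ml.

Because clinical 4D flow studies cannot be redistributed, the package ships
a **pulsatile phantom generator** with analytic ground truth (Poiseuille
tubes, bifurcations, bulk motion, phase wraps, background offsets) that
exercises every stage at the clinical resolution (2.7 × 2.7 × 2.8 mm voxels,
20 frames of 52.8 ms, VENC 120 cm/s).

## Worked example

```python
from pathlib import Path
from flow4d import io as fio
from flow4d.atlas_seg import build_atlas
from flow4d.phantom import PhantomSpec, default_meta, make_phantom
from flow4d.pipeline import run_pipeline

work = Path("example")
flow, truth = make_phantom(PhantomSpec(grid_shape=(64, 64, 64),
                                       grid=default_meta()))
fio.save_flow4d(flow, work / "input")
atlas = build_atlas(flow, threshold_frac=0.3, planes=truth.planes, n_vessels=1)
fio.save_atlas(atlas, work / "atlas")

result = run_pipeline({"input_dir": str(work / "input"),
                       "atlas_dir": str(work / "atlas"),
                       "out_dir": str(work / "out"),
                       "plane_spacing": 0.5})
for r in result.flow_results:
    print(f"{r.plane_name}: {r.net_volume:.2f} ml "
          f"(truth {truth.plane_truth[r.plane_name]:.2f} ml)")
```

prints

```
tube_proximal: 30.24 ml (truth 30.00 ml)
tube_distal: 30.24 ml (truth 30.00 ml)
```

i.e. the automatic pipeline recovers the analytic net volume of the
pulsatile Poiseuille tube (peak rate 157.1 ml/s, half-sine systole of
0.3 s → 30.0 ml per cycle) to better than 1% at clinical resolution.
`example/out/` then holds `summary.json` (net volumes, flow ratios,
registration diagnostics), `flows.csv` (per-plane flow-rate curves),
`diagnostics.csv` and the 4D segmentation `seg4d.nii.gz`.

The same stages are available from the shell:

```bash
flow4d phantom --geometry y_bifurcation out/phantom
flow4d run config.json
```

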