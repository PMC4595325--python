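# Methods

This note records the models, algorithms and numerical choices behind
`flow4d`, and what the phantom-based validation does and does not show.

## Data model and conventions

A 4D flow dataset is a nonnegative magnitude volume `M(x, t)` plus a
velocity vector field `v(x, t)` in cm/s on one voxel grid (NIfTI on disk,
one file per component, JSON sidecar for voxel size, frame duration, VENC
and the grid-to-world affine).  Velocities are always held in cm/s;
phase-scaled inputs are converted at ingest with `v = (φ/π)·VENC`.  Voxel
indices are 0-based; world coordinates come only from the grid-to-world
affine, and all plane geometry is stored in world millimetres so atlases
survive resampling.

Displacement fields use the pull-back convention — the warped image at
target voxel `x` samples the source at `x + d(x)` — and are stored in voxel
units of the target grid (multiply by the voxel size for mm).  Forward
point mapping (atlas plane points into the subject) always goes through
fixed-point field inversion.

## Preprocessing

**Temporal phase unwrapping.**  Phase-contrast velocities wrap by `2·VENC`
when the true velocity exceeds the encoding limit.  Scanning each voxel's
time series from an anchor frame assumed wrap-free (default frame 0, the
early-systolic frame where velocities are lowest; configurable), any
successive difference outside `(−VENC, VENC]` is folded back by the nearest
multiple of `2·VENC`, and the correction propagates to later frames.  The
operation is idempotent and only ever changes values by integer multiples
of `2·VENC`.  It is a *temporal* method: a voxel wrapped in every frame is
not recoverable, and no spatial unwrapping is attempted.

**Background (eddy-current) correction.**  Residual velocity offsets are
modelled per component as a full second-order polynomial in voxel
coordinates normalized to [−1, 1] per axis (10 terms; the normalization
keeps the design well conditioned).  Static tissue is detected as voxels
whose time-mean magnitude reaches `mag_frac` (default 0.1) of the volume's
95th magnitude percentile and whose temporal speed standard deviation is at
most `vel_std_max` (default 2 cm/s, roughly the noise floor of a clinical
acquisition); confidence weights fall linearly with that standard
deviation.  The fit is weighted least squares on the temporal-mean
velocity; it refuses to run on fewer than 10 usable voxels or a
rank-deficient design (e.g. coplanar static voxels), and the evaluated
polynomial is subtracted from every frame.  On noise-free phantoms with an
injected polynomial offset the recovery is exact to machine precision
provided the static mask contains no flowing voxels — in practice that
means a strict `vel_std_max` for synthetic data, since near-wall lumen
voxels with almost-zero velocity otherwise leak into the mask and bias the
fit by ~10⁻² cm/s.

## PC-MRA and systole detection

The angiogram is `PC_MRA(x) = M̄(x)·|v̄(x)|` with the means taken over the
systolic frames — component averages *inside* the norm, so opposing flow
cancels, and the magnitude factor suppresses regions like the lungs.  The
per-frame scalar used to find systole is the volume mean of `M·|v|`, the
single-frame analogue of the same product; frames reaching `systolic_frac`
(default 0.7) of the curve maximum form the systolic set and the argmax
(lowest index on ties) is the peak frame.  A relative threshold adapts to
waveform shape where a fixed window would not.  The magnitude image alone
was considered as the peak-frame criterion; the angiographic product is the
default because the peak frame must resemble the PC-MRA-built atlas as
closely as possible.

## Registration

**Affine stage.**  A 12-parameter transform (translation, rotation,
log-scale, shear), centred on the volume midpoint, is optimized with
Powell's method over a Gaussian pyramid (downsample ×2 per level; 3 levels,
5 refinement cycles each by default) against `1 − NCC` of the warped source
and target.  A translation-only pre-alignment runs at the coarsest level.
The objective carries a tiny (10⁻³-weighted) Tikhonov pull toward identity:
it is negligible against any real correlation gain but breaks ties along
directions in which the image is invariant — a straight tube constrains
neither translation along nor scaling about its own axis, and without the
penalty the optimizer drifts freely there, which is harmless for the warped
image but catastrophic for mapped plane points.  If the final objective is
worse than at identity the identity transform is returned with a warning.

**Non-rigid stage (Morphon-style).**  Per pyramid level and iteration:

1. *Local displacement estimate.*  With `W` the currently warped source,
   `T` the target, `g = (∇W + ∇T)/2` and `Δ = W − T`, every voxel
   contributes an optical-flow constraint `g·δ = −Δ`.  The constraints are
   aggregated over a Gaussian window of width `sigma_fluid` into a
   structure tensor `G*(g gᵀ)` and force `G*(−Δ g)`, and a Tikhonov-
   regularized 3×3 system is solved per voxel (regularizer: 5% of the
   tensor trace).  The spatial aggregation is essential: a per-voxel
   (demons-style normal-flow) force can only ever point along the local
   gradient, so on locally one-dimensional structures — vessel walls —
   the tangential motion component is unobservable per voxel and an
   orientation-decomposed per-voxel solve is degenerate; pooling
   differently oriented constraints from the neighbourhood resolves the
   aperture problem.  Certainty is the aggregated gradient energy (tensor
   trace).  Increments are capped at 1 voxel.
2. *Fluid regularization* is implicit in the same Gaussian aggregation of
   the constraint field (viscous-fluid behaviour of the increment).
3. *Diffeomorphic accumulation:* the increment is composed with the
   running field, `d ← δ + d∘(id + δ)` — never added voxel-wise — so the
   deformation can compress and stretch but not tear or fold.
4. *Elastic regularization:* the accumulated field is smoothed by
   certainty-weighted (normalized-convolution) Gaussian filtering with
   `sigma_elastic`.

After each level the field is *extended* into low-certainty regions
(vessel interiors, background) by long-range normalized convolution
(σ = 4 voxels): structureless regions provide no evidence and would
otherwise lag the well-determined field around them.  Between levels the
field is linearly upsampled and doubled.  If the final field's interior
Jacobian determinant is anywhere nonpositive, elastic smoothing is
reapplied (at most 5 times) until it is — in practice the 1-voxel step cap
plus composition makes this a no-op.

Defaults: atlas fitting 3 scales × 5 iterations on the raw PC-MRAs;
temporal propagation 5 scales × 5 iterations on edge representations;
`sigma_fluid = 2.0`, `sigma_elastic = 1.5` voxels.  Scale counts and
iteration counts are the method's published operating point; the kernel
widths are this implementation's choice and are exposed in the
configuration.

**Edge representation.**  For frame-to-frame registration the images are
replaced by the Frobenius norm of the local structure tensor (Gaussian-
averaged outer product of the smoothed gradient, σ_gradient = 1,
σ_tensor = 2 voxels).  This is invariant to intensity offsets and, up to a
global factor, to intensity scaling, which suits magnitude frames whose
contrast varies over the cycle.  Atlas fitting registers raw PC-MRAs.

**Inversion and point mapping.**  `d⁻¹` is computed by the fixed-point
iteration `d⁻¹(x) ← −d(x + d⁻¹(x))` to a composition-residual tolerance
(default 0.05 voxel); atlas points map forward via
`x = A⁻¹(p) + d⁻¹(A⁻¹(p))`.  Points landing outside the target grid are
kept but flagged.

## Temporal propagation

The peak-systolic frame is registered to *every* other frame independently
rather than chaining neighbouring frames, so single-frame registration
errors cannot accumulate around the cycle.  Labels are warped in mask mode
(per-code linear interpolation of the binary mask, 0.5 threshold, argmax on
overlap, so no new codes can appear).  A frame whose registration worsens
the edge-map correlation is flagged and filled from the nearest successful
frame.

## Atlas fit reliability

A fit is rejected as unreliable when the final warped-atlas correlation
fails to improve on the identity alignment (beyond a 0.02 numerical
allowance — a self-fit must not be rejected for rounding) **or** stays
below an absolute floor of 0.3.  The floor matters because non-rigid
registration can slightly *increase* the correlation of two structurally
unrelated images by chasing noise; improvement alone therefore cannot
detect the no-overlapping-structure failure mode.  Successful phantom and
self fits sit above 0.95.

## Plane flow quantification

Deformed plane point patches are re-fitted flat by PCA: centroid → origin,
first two principal directions → in-plane axes, third → normal with its
sign matched to the pre-deformation normal (and, in the pipeline, the
extent capped at twice the atlas plane's extent to be robust to stray
mapped points).  Velocities are sampled on a lattice (default spacing: half
the smallest voxel) by linear interpolation; the vessel mask is a
nearest-label lookup of the time-resolved segmentation (labels are
categorical — interpolating codes is meaningless) smoothed per frame by a
normalized disk kernel of radius 9 lattice pixels with keep-fraction 0.1,
chosen so the region becomes rounder and slightly larger; the output is
additionally unioned with the input mask so smoothing can never lose vessel
pixels.  Enlarging the mask is safe because the surrounding pixels carry
near-zero velocities.  The flow rate is
`Q(t) = Σ_masked (v·n̂) · spacing² · 10⁻²` ml/s and the net volume the
rectangle-rule sum `Σ Q(t)·Δt` — with retrospective gating the frames tile
the cycle equally, so the rectangle rule is exact for the sampled curve.
Simple linear regression (OLS; r² = squared Pearson correlation; two-sided
slope test, significance at p < 0.05) serves the comparison analyses, and
the Dice coefficient (defined as 1 for two empty masks) quantifies
segmentation overlap.

## Phantom generator

The generator emulates the target acquisition: 64³ voxels of
2.7 × 2.7 × 2.8 mm, 20 frames of 52.8 ms, VENC 120 cm/s (a 32³ fast preset
keeps registration-heavy tests quick).  Vessels are tubes with laminar
Poiseuille profiles `v(r,t) = v_max (1 − (r/R)²) w(t)` (default
v_max = 100 cm/s, R = 10 mm) under a half-sine systolic waveform (0.3 s
systole by default, sampled at frame midpoints), so every plane has the
analytic truth `V = (v_max πR²/2)·∫w dt`; a Y-bifurcation assigns branch
radii `R√fᵢ` so branch flows sum exactly to the trunk flow.  Magnitude is
1.0 in the lumen, 0.5 in a static-tissue shell, 0.05 elsewhere.  Optional
corruptions: bulk sinusoidal motion (`A·sin(2πk/n)` mm along x, truth
offsets recorded), radial pulsation, Gaussian velocity/magnitude noise, a
polynomial background offset, and `±2·VENC` wrapping wherever the corrupted
velocity exceeds VENC (the pre-wrap field is kept as truth).  All
randomness derives from one seed.

Deliberate simplifications: velocities are assigned from the analytic
profile at voxel centres with no subvoxel averaging (the truth stays
analytic; the resulting discretization error — about 1% on the net volume
at clinical resolution — is what the few-percent validation tolerances
absorb); the curved tube uses same-z cross-sections (valid for small
centreline slopes); no turbulence, valve jets, k-space effects or
contrast-agent dynamics.  Consequently the phantom validation demonstrates
geometric and numerical correctness of the pipeline, not robustness to the
full physics of clinical data: a real cohort adds wall motion, noise
structure and anatomical variability the phantoms only caricature.

## Validation summary

The acceptance suite runs the complete automatic pipeline (threshold-built
atlas → affine + non-rigid fit → 4D propagation → plane flow at 0.5 mm
spacing) on clinical-resolution phantoms and checks: analytic flow recovery
within 5% (measured ≈ 1%), trunk-versus-branch conservation within 5%,
equality of two identically fed circulations within 3%, plane-position
robustness within 3%, Morphon identity (≤ 0.1 voxel), 2-voxel warp
recovery (mean endpoint error ≤ 0.5 voxel inside the object), strictly
positive interior Jacobians, per-frame Dice ≥ 0.85 against moving truth,
(≥ 0.98 motion-free), atlas-fit Dice (self ≥ 0.99, warped subject ≥ 0.85),
voxel-exact unwrapping, machine-precision background recovery, and the
mask-smoothing and regression contracts.  Problem sizes: 64³ × 20 frames
for the flow criteria, 32³ for the registration-heavy segmentation
criteria.

The warp-recovery experiment deserves a design note.  It uses a multi-blob
object carrying internal intensity texture (as a PC-MRA does) and a
2-voxel-amplitude sinusoidal field of 64-voxel wavelength.  On a *flat*
object the displacement is fundamentally unobservable away from the walls
— per-voxel image evidence only ever constrains the along-gradient
component, and even pooled constraints vanish inside homogeneous regions —
so the endpoint error there measures the quality of certainty-based
interpolation, which for a wavelength-32 field across 4–5-voxel
structure-free holes sits near 0.5–0.7 voxels no matter how many
iterations run.  With texture the field is observable throughout the
object and the mean endpoint error is 0.19–0.39 voxels across seeds.

Similarly, atlas-fit quality is scored on an aorta-calibre tube (R = 14 mm,
about 5 voxels radius — the calibre of an adult ascending aorta at this
resolution): the Dice coefficient between two discretizations of a
~29-voxel cross-section already bottoms out near 0.8 for sub-voxel boundary
offsets, so on the thinner flow tube the metric measures the
discretization floor rather than the registration.

## Known limitations

- Temporal unwrapping cannot fix voxels wrapped identically in all frames.
- The affine identity-pull resolves degenerate geometries but would
  slightly bias a genuine near-identity fit of an invariant structure;
  clinical anatomies are never invariant in this sense.
- Plane angles are taken from the deformed atlas plane; no correction
  toward exact perpendicularity to the local lumen axis is attempted.
- Single atlas only; no multi-atlas fusion or pathology-specific atlases.
- CPU only; the temporal stage costs one non-rigid registration per frame.
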