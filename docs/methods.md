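# Methods

`vdmkit` measures aortic wall growth between two CT angiography (CTA)
volumes by deformable registration and quantifies it on triangular surface
meshes. Because clinical scan pairs come without ground truth, the package
also contains a complete synthetic-phantom validation framework: it
fabricates aorta-like geometry with *known* wall deformation, synthesizes
image pairs whose true displacement field is available by construction, and
measures how well the registration pipeline recovers the deformation under
clean and degraded imaging conditions.

## 1. The registration pipeline

Given fixed image `I_F` (baseline), moving image `I_M` (follow-up) and
binary aortic segmentations of both, the pipeline runs three stages. All
negative HU are clamped to zero first, which removes the influence of
aerated lung.

**Stage 1 — rigid.** Maximizes normalized cross-correlation (NCC) over the
fixed aortic mask dilated by 5 voxels. The translation is initialized from
the mask-centroid offset (giving a capture range far beyond any plausible
patient repositioning without multistart), and a derivative-free Powell
search refines 3 Euler angles + 3 translations at two sampling strides. NCC
is invariant to positive affine intensity changes, so contrast differences
between scans do not bias the alignment.

**Stage 2 — centerline alignment.** A coarse cubic-B-spline free-form
deformation (control spacing 14 mm) driven by Parzen-window mutual
information (MI, 48 bins) with two penalties: bending energy (weight 10) and
a local rigidity penalty (weight 20) applied inside the dilated aortic mask.
The rigidity penalty is the sum of squared linearity (second derivatives),
orthonormality (`‖JᵀJ − I‖_F`), and properness (`det J − 1`) terms of the
transform Jacobian. Surrounding tissue may deform freely while the aorta
itself moves near-rigidly, which implicitly aligns the aortic centerlines
(e.g. respiratory displacement of a whole segment) without letting the
stage absorb wall growth.

**Stage 3 — fine deformable.** A finer B-spline (control spacing 7 mm,
sampling down to the native voxel grid) with MI and a stronger bending term
(weight 100). This stage captures the growth signal.

The analysis field handed to the metrics is the composition
`T_rigid ∘ φ_coarse ∘ φ_fine` evaluated on the fixed grid (fixed-space x ↦
moving-space x + u(x)); the rigid transform is also reported separately so
bulk patient motion can be distinguished from tissue deformation.

### Numerical machinery

The B-spline transform, its adjoint, all similarity measures and penalties
are implemented in NumPy with analytic gradients and optimized with
L-BFGS-B; no stochastic sampling is used, so results are deterministic for
fixed inputs. Multiresolution uses a Gaussian pyramid: at sampling stride
`s` the images are smoothed with `σ = max((s−1)/2, σ_floor)` voxels. Plain
strided subsampling is *not* sufficient — a sharp wall displaced by more
than ~2 level-voxels is outside the basin of every level, and bumps of 5 mm
were unrecoverable without pyramid smoothing. The smoothing floor
(`σ_floor = 1` voxel by default) additionally denoises the full-resolution
level; empirically it improves accuracy on clean images as well, because
partial-volume boundaries are smooth at that scale anyway.

### Correspondence (null-space) regularization

A near-tubular structure is almost symmetric under sliding along its own
surface: image similarity cannot determine tangential correspondence, and
two registrations of the same scan pair can agree perfectly on the surface
while disagreeing by millimeters in vertex correspondence. That
disagreement projects into the growth metrics wherever the surface is
curved or tilted. Both the ground-truth registration and the VDM stages
therefore carry the *same* null-space regularization: a weak penalty
(weight 1e-3) on the component of the displacement transverse to the local
intensity-gradient direction, confidence-weighted by gradient magnitude and
high-pass filtered at 25 mm. The high-pass is essential — smooth bulk
motion such as respiratory drag is genuinely tangential over large regions
and must pass free (an un-high-passed version at any useful weight
suppresses it entirely); only oscillatory sliding is pinned. Because both
pipelines resolve the null space by the same rule, their correspondences
agree and the metric comparison measures registration error, not arbitrary
gauge choices.

## 2. Synthetic phantoms

The generator replaces interactive mesh sculpting with parametric
operators, so the per-vertex displacement is known analytically.

* **Geometry.** A C¹ candy-cane centerline (ascending limb 40 mm, 180°
  arch of radius 26 mm, descending limb 55 mm; ≈177 mm total) swept with
  rotation-minimizing frames into a closed triangular tube (192
  circumferential × 0.4 mm axial vertex spacing; ~85k vertices). The dense
  spacing makes the binary vertex-occupancy image (below) a hole-free
  one-voxel shell at clinical resolution. Each vertex records its
  generating `(s, θ)` coordinates for analytic oracles.
* **Wall irregularity.** The tube radius (12 mm) is modulated by a seeded
  band-limited random field (6% amplitude, wavelengths 22–60 mm,
  circumferential orders ≤ 5). Clinical aortic walls are not surfaces of
  revolution; without such landmarks, tangential correspondence is
  mathematically unidentifiable from images and validation of
  vertex-resolved metrics is ill-posed.
* **Growth operators.** Radial (fusiform) and sculpted (saccular/eccentric)
  bulges displace vertices outward along the local radial direction with a
  compactly supported cos² profile in `s` (and `θ` for sculpt); peak
  displacement equals the requested magnitude exactly at the apex and is
  zero with zero slope outside the support. A drag operator translates an
  arc-length region rigidly with cos² falloff, emulating respiratory
  motion of aortic segments.
* **Rasterization.** Watertight-capped meshes are voxelized by parity ray
  casting with exact axial coverage integration and 4× in-plane
  supersampling, producing partial-volume-antialiased images (lumen 350 HU,
  background 40 HU) and 0.5-occupancy masks. A smooth seeded background
  texture (30 HU, 10 mm scale, outside the lumen) stands in for mediastinal
  structure; a perfectly uniform background would make similarity metrics
  degenerate off the aorta. Default analysis grids use 1.25×1.25×1.0 mm
  voxels over a reduced field of view — a desk-scale stand-in for clinical
  CTA sampling chosen so a full validation study runs on one CPU.

The generator's baseline images carry no noise; noise, slice thickness and
motion are applied only by the perturbation module, so each degradation is
isolated.

## 3. Registration-based ground truth

The declared ground truth is *not* the analytic mesh displacement but a
dense displacement field obtained by registering **boundary images** of the
fixed and deformed meshes: voxels occupied by any mesh vertex are set to
one, the binary images are blurred with a Gaussian (σ = 5 voxels), and a
single-stage B-spline registration (sum of squared differences + bending
energy + the null-space penalty above) aligns them. Boundary images are
always built on a 0.64×0.64×0.75 mm grid — at coarser desk-scale spacing
the 5-voxel blur merges the opposing tube walls and the deformation signal
washes out. The field maps fixed-space points to moving-space points;
warping the fixed mesh through it yields V̂, and resampling the fixed image
through the numerically inverted field yields the synthetic moving
image/mask. V̂ and the synthetic image are exactly concordant by
construction, so downstream comparisons isolate measurement error.

On the reference phantom (2.5 mm fusiform bulge) the GT field reproduces
the analytic vertex displacement with 99th-percentile error < 0.5 mm; the
residual grows to roughly 0.1–0.15 × magnitude for the largest bumps and
drags, dominated by the tangential component that no image-based method can
observe. This is a known property of the construction, shared with the
original boundary-image design; the field, not the analytic displacement,
is the reference for all downstream error statistics.

## 4. Growth metrics

For corresponding meshes (identical connectivity), the **area ratio** (AR)
is the deformed/fixed area of each face, and **DiN** is the signed
projection of each vertex displacement onto the angle-weighted outward
fixed-surface normal (growth positive; pure tangential sliding projects to
zero). Error statistics are restricted to the *deformed region* — vertices
whose ground-truth |DiN| exceeds a threshold (1e-3 mm for population
summaries, 0.01 mm for the 99th-percentile robustness statistics) and faces
touching them. Relative perturbation errors follow the convention
`(err_perturbed − err_original) / GT99`, in percent, with GT99 the raw AR
(respectively |DiN|) 99th percentile of the ground-truth deformation.

One sign convention is worth noting: with outward normals, defining DiN as
the projection of `v − v̂` makes growth negative; the package uses
`n̂ · (v̂ − v)` so outward growth is positive, consistent with how growth
maps are displayed.

## 5. Validation studies and their scale

* **Population study:** 10 phantoms (default; configurable) spanning
  0.25–5.4 mm magnitudes, radial and sculpt modes, ascending/arch/
  descending locations (ascending-weighted). Headline numbers are pooled
  element-wise medians of |GT − VDM| for AR and DiN; medians of per-case
  medians are reported alongside.
* **Robustness arms:** Gaussian noise calibrated per-image to target
  contrast-to-noise ratios (CNR 6.84/3.88/2.66, matching the clinical
  noise levels by CNR rather than by sigma, since the synthetic contrast
  differs); slice-thickness box-average resampling to 1.0/1.5/2.0 mm;
  bulk rigid motion (one shared random transform applied to both scans —
  a patient-position change; translations 20/40/60 mm, per-axis rotations
  uniform in ±5°). Ground truth is never perturbed.
* **Respiratory arm:** six growth phantoms (1.5–6.5 mm) additionally
  dragged at the ascending/arch/proximal-descending segment by 3–10 mm
  translations (magnitudes spanning published respiratory aortic
  displacement; pairing of drag size with growth size is randomized). Each
  combined case gets its own boundary-registration ground truth; reported
  are the error increases relative to the growth-only baseline.
* **Diameter study:** centerlines are extracted from masks by a
  Dijkstra ridge walk on the interior distance transform with mean-shift
  recentering, profiled every 0.5 mm by plane–mesh intersection (maximal
  chord of the nearest closed contour — the standard convention for
  "maximum diameter" in aortic measurement), and the maximal |Δdiameter|
  and its location are compared between the GT-warped and VDM-warped
  surfaces.

What these phantoms do *not* emulate: arch branch vessels, wall
calcification, intraluminal thrombus, cardiac-phase (pulsatile)
deformation, CT physics (beam hardening, structured reconstruction noise),
and observer segmentation variability. Passing the suite shows the
registration and metrics recover known deformations under the stated image
degradations; it does not certify accuracy on pathology the generator does
not produce.

## 6. Tunable parameters (defaults)

| Parameter | Default | Notes |
|---|---|---|
| lumen / background / texture HU | 350 / 40 / 30 | arterial-phase CTA scale |
| analysis voxel spacing | 1.25×1.25×1.0 mm | desk-scale; clinical ≈ 0.64×0.64×0.75 |
| boundary-image spacing | 0.64×0.64×0.75 mm | σ=5 voxel blur ≈ 3.2 mm |
| mask dilation (rigidity/domain) | 5 voxels | |
| stage weights (bending, rigidity) | 10/20 coarse, 100/0 fine | |
| control spacing | 14 mm coarse, 7 mm fine, 8 mm GT | |
| MI bins / max samples | 48 / 30000 | |
| null-space penalty (weight, high-pass) | 1e-3, 25 mm | all deformable stages |
| pyramid smoothing floor | 1.0 voxel | registration stages only |
| tube mesh density | 192 × 0.4 mm | hole-free occupancy shell |
| undulation amplitude | 6% | wall-shape irregularity |
| noise / thickness / motion menus | 50,100,150 HU; 1.0,1.5,2.0 mm; 20,40,60 mm ±5° | noise arms calibrated by CNR |

Degenerate inputs are rejected early (empty masks, constant images over a
similarity domain, zero-area faces, non-tubular masks); per-case failures
in experiment sweeps are recorded in the results table rather than aborting
the sweep. Optimizers are deterministic; every randomized generator step
takes an explicit seed.

## 7. Known limitations

* Tangential wall motion is fundamentally unobservable on smooth wall
  segments; both GT and measurement resolve it by the shared regularization
  rule, and AR (which is sensitive to tangential stretch) inherits more of
  this gauge than DiN.
* The GT field's concordance with the analytic deformation degrades to
  ~0.1×magnitude for the largest deformations; element-wise error
  statistics against the GT field remain well-defined, but analytic
  comparisons at >3 mm magnitudes should use the stored per-vertex
  analytic displacement directly.
* Rotation about the near-symmetry axis of a synthetic tube is
  unidentifiable for the rigid stage; synthetic rigid-recovery checks
  rotate about transverse axes.
* Gaussian noise is an idealization of CT noise; the slice profile is a
  box average, not a scanner SSP.
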