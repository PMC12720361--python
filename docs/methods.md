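# Methods

## Problem

Infrared thermography of poultry needs accurate regions of interest: the
featherless head appendages (comb, eye, beak, wattle) are where surface
temperature tracks heat stress, but segmentation models run on the RGB
channel of a dual-channel camera, while temperatures live on the much
coarser IR channel (2688×1520 vs. 384×288 here). thermomap transfers
segmentation masks from the RGB grid to the IR grid through the rig's
calibrated geometry, then reads temperature statistics off the camera's
per-pixel temperature matrix.

## Cross-modal mapping model

Each channel is a pinhole camera with Brown–Conrady distortion
(k₁, k₂, p₁, p₂, k₃ on normalized coordinates). For a pixel (u, v) observed
in the RGB channel:

1. normalize: x = (u − cₓ)/fₓ, y = (v − c_y)/f_y;
2. undistort by fixed-point iteration
   x ← (x_obs − tangential(x))/radial(x), tolerance 1e-10 on normalized
   coordinates, ≤ 50 iterations; non-convergence (e.g. coefficients far
   outside the model's valid branch) raises an error rather than passing
   through silently;
3. back-project onto the working plane: P = (x·d, y·d, d) with d the
   working depth in mm (single scalar per frame — a fronto-parallel plane
   assumption; the acquisition protocol fixes d = 600 mm);
4. apply the rigid RGB→IR transform P' = R·P + t (t in mm);
5. project through the IR channel, applying its forward distortion, to get
   the IR pixel.

Normalizing before undistorting is mathematically equivalent to
undistorting pixel coordinates first and is the numerically standard order.
Pixel coordinates are 0-based, (u, v) = (column, row), integer coordinates
at pixel centers. Mapped points outside the IR frame are returned and
flagged, not discarded: bounds bookkeeping belongs to the mask stage.

## Mask-level transfer

A label mask (codes: background 0, comb 1, eye 2, beak 3, wattle 4) is
decomposed per region into 8-connected components (components under
5 px are treated as segmentation specks and dropped; configurable). Each
component's outer boundary is traced with Moore-neighbor border following
— outer contours only, interior holes filled, since the head regions are
simply connected. Every contour point is mapped as above and the mapped
polygon is filled on the IR grid: a pixel is set iff its center is inside
under the nonzero winding rule, with centers exactly on an edge counting
as inside (a scanline implementation with signed crossings keeps this at
O(rows × edges)). Per-region masks are kept separately so overlaps created
by projection are preserved for thermometry; the optional flattened label
map writes comb, wattle, beak, eye in that order so the smallest structure
wins ties.

## Calibration

`calibrate_rig` implements Zhang's planar-checkerboard method directly on
numpy/scipy: per-channel homographies (normalized DLT), closed-form
intrinsics from the absolute-conic constraints, pose extraction, then
Levenberg–Marquardt bundle refinement per channel followed by a joint
refinement in which both channels share the board poses and a single rigid
RGB→IR transform (scipy.optimize.least_squares). The default board is a
15×16 array of 25 mm squares, i.e. a 14×15 inner-corner grid (210 corners).
With 10 varied noiseless synthetic poses the generating parameters are
recovered to machine precision (far inside the 0.1 % intrinsics / 0.1 mm
translation bands); with 0.1 px corner noise, intrinsics stay within 1 %.
Near-degenerate pose sets produce a conditioning warning and a best-effort
result; fewer than 3 poses is an error.

## Depth-error sensitivity

The mapping depends on the assumed working depth only through the
back-projection, so with a pure horizontal stereo baseline b and no
distortion, mapping at depth d instead of the true 600 mm shifts every
point horizontally by exactly fₓ·b·|1/600 − 1/d|. The sweep protocol maps
each frame at every depth in [580, 620] mm (1 mm steps, endpoints
inclusive) and compares each region's mask against the same frame's
600 mm mask — the baseline-depth *mapped* mask, not ground truth — by IoU
and centroid offset, averaged over frames. At the baseline the comparison
is a self-comparison, so IoU = 1 and offset = 0 hold exactly, by
construction. Contours are extracted once per frame and reused across
depths (they do not depend on depth); tests assert this equals the naive
per-depth recomputation.

Because masks are binary on a 384×288 grid, per-frame IoU and centroid
curves carry raster granularity: monotone-trend diagnostics treat IoU
increases ≤ 0.005 and offset decreases ≤ 0.05 px as noise (these
tolerances were fixed from the granularity argument, not fitted). The
closed-form comparison instead uses four ~100 mm disks per frame
(`make_plane_disks_mask`, ~12 000 IR px each) and 8 frames, which keeps
mask-centroid quantization near 0.03 px — head-sized templates (the beak
covers only ~130 IR px) would bury the 0.05 px band in quantization.

## Segmentation evaluation

Metrics come from a pooled k×k confusion matrix: IoU_i = p_ii/(Σ_j p_ij +
Σ_j p_ji − p_ii), per-class accuracy (recall) PA_i = p_ii/Σ_j p_ij, with
MIoU and MPA their means over classes present in truth or prediction;
classes absent from both are excluded (0/0) and reported. Background
participates by default, with `restrict_to` narrowing the means to the
four head regions. MIoU ≤ MPA holds for every matrix since each class's
IoU denominator dominates its recall denominator. Per-image evaluation is
available by building one matrix per image; pooling is the default.

## Losses

Focal loss FL(p_t) = −α(1−p_t)^γ·ln(p_t), mean-reduced, p_t floored at
1e-7; defaults α = 0.25, γ = 2 (the originating focal-loss convention). At γ = 0, α = 1 it reduces
exactly to cross-entropy and never exceeds it for γ > 0. Dice loss uses
ε = 1 smoothing; the combined mask loss is focal + dice with equal,
configurable weights.

## Synthetic scenes

No suitable chicken RGB-IR dataset is publicly available, so the
generator emulates realistic acquisition conditions: a Hikvision-like rig (RGB 2688×1520 at f ≈ 2100 px, IR
384×288 at f ≈ 380 px, X-dominant 47 mm baseline, sub-degree relative
rotation, mild barrel distortion — plausible values for this camera
class, chosen once, with ±2 % seeded jitter across rigs), head regions as polygon templates on the
600 mm plane (serrated crown ≈ 60×30 mm, eye ellipse ≈ 32×24 mm, beak
triangle ≈ 40×17 mm, wattle lobe ≈ 28×42 mm), and temperature fields with
a low-order polynomial background (26–30 °C), per-region means (control:
comb 38.5, eye 36.5, beak 33.5, wattle 38.0 °C; heat stress adds 2.5 °C to
comb and wattle, within the 2–3 °C surface-temperature rise typical of
heat-stressed birds), and pixel noise
σ = 0.3 °C. Region interiors sit exactly at the generating mean, and each
region's warmth decays into the background over ~3 px (Gaussian), because
real thermograms are continuous — a hard step at the boundary would be
unphysical and would make single-pixel mask differences dominate region
means. Ground-truth IR masks are produced by projecting the generating
3-D geometry directly through the IR channel and rasterizing with shapely
— never through the mapping pipeline under test, so agreement between the
two paths is a result, not an input. Everything is a pure function of
(spec, seed); a quarter-resolution preset (672×380 / 96×72) preserves the
angular geometry for fast runs.

What the scenes do not model: feathers and occlusion, specular/emissivity
variation, motion, per-pixel depth variation across the head (the plane
assumption is exact in the generator, only approximate on a real bird),
and radiometric error. Passing tests therefore demonstrate geometric and
statistical correctness of the measurement chain, not segmentation
performance on real birds — the segmentation stage is a pluggable
contract, with a color-table reference segmenter standing in for trained
networks.

## Thermometry and group reporting

Region statistics are plain mean/min/max over the mask's pixels; no
emissivity or distance correction is applied (the camera applies its 0.96
emissivity internally; the value and the ±0.5 °C accuracy ride along as
rig metadata). Group reports average each bird's frame means first, then
across birds within each (density, age, condition) cell — densities
{4, 8, 12} birds/m², ages 5–8 weeks, experimental vs. control — with a
pixel-pooled alternative behind a flag. Cells without records are absent,
never imputed.

## Verification at a glance

End-to-end checks run the full pipeline (scene → reference segmenter →
contour mapping → thermometry) over 20 paired trials: across-trial mean
temperature error per region stays within a single frame's 2σ/√n bound
(the pooled estimator is far tighter, so this is conservative); per-region
IoU against the directly projected ground truth averages ≥ 0.95 (measured
≈ 0.96–0.99; single frames on the small beak dip to ≈ 0.92 from the
half-pixel contour quantization every contour-fill pipeline shares); and
the comb/wattle heat-stress contrast direction is recovered in every
trial. Problem sizes (20 rigs × 200 points, 10 calibration poses, 8-frame
parallax sweeps, 6-frame monotonicity sweeps, 20 end-to-end pairs) were
chosen to keep quantization and sampling noise well inside each band.

## Known limitations

- The working depth is one scalar per frame; strongly non-planar targets
  violate the model in proportion to the parallax f·b·Δ(1/Z).
- Contour transfer is only as good as the RGB segmentation's pixel grid;
  sub-pixel mask edges are not modelled (no anti-aliasing).
- Overlap handling after projection (independent per-region masks,
  smallest-wins flattening) and IR-boundary clipping are this package's
  choices; acquisition-protocol details for those cases are not published.
- The calibration assumes zero skew and the five-parameter Brown–Conrady
  model; fisheye or rational models are out of scope.
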