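# Methods

## Problem and model

`fluoropose` estimates the pose of a small radio-opaque surgical fiducial —
a titanium micro-screw, a drill tip, or a prototype drilling robot — from a
single X-ray-like projection, given a coarse initial guess.  The single-view
pose is the 5-tuple

    theta = (x, y, alpha, tau, d)

with detector-plane position `(x, y)` in pixels, in-plane *forward angle*
`alpha` between the projected instrument axis and the image x-axis (degrees,
measured toward +y with x right / y down), out-of-plane *projection angle*
`tau` (degrees; a single view determines only `|tau|`, since the projection
of an axisymmetric instrument is identical under `tau -> -tau`), and *depth*
`d` — the source-to-object distance along the projection normal (mm).

Rather than regressing the pose directly, the pipeline regresses six
**pseudo-landmarks**: geometrically defined points at fixed metric offsets
from the instrument, 15 mm apart in a cross — four along the instrument axis
(offsets −15, 0, +15, +30 mm; the asymmetric +30 disambiguates the forward
direction) and three along the in-plane normal (−15, 0, +15 mm), sharing the
central landmark.  Under a pinhole geometry with source–detector distance
`d_sdd` and detector pixel spacing `delta_ds` (conversion factor
`c_d2p = delta_ds / d_sdd`), a landmark with local offset
`(x_lp, y_lp)` projects to

    p_i = (x, y) + 1/(c_d2p * d) * R(alpha) @ (x_lp * cos(tau), y_lp).

This map inverts geometrically: total-least-squares lines through the two
legs intersect at `(x, y)` and the axis-leg direction gives `alpha`; pairwise
image distances on the normal leg (unaffected by `tau`) give `d`; the
foreshortening of the axis leg gives `cos(tau)` (clamped to [0, 1], clamps
surfaced in diagnostics).  Pair estimates for `d` and `cos(tau)` are averaged
over all distinct-offset pairs of the leg, which is exact in the noise-free
case and reduces variance under noise.

The estimator iterates three times: crop a normalized patch at the current
prior, predict landmarks, reconstruct the pose, re-crop at the refined pose.
In-plane components are updated every iteration; `d` and `|tau|` are reported
from the final reconstruction.

### Assumptions

* The initial pose is accurate to 2.5 mm radially and 30 degrees in the
  forward angle (training perturbations are drawn from exactly this model:
  radius ~ U(0, 2.5 mm), direction ~ U(0, 360 deg), angle ~ N(0, (30/3)^2)).
* The instrument is rigid and effectively axisymmetric; rotation about its
  own axis is not recoverable and not modeled.
* The projection geometry (`d_sdd`, `delta_ds`) is known.

## Appearance normalization

The 92x48 patch places the instrument in a *standard pose*: reference point
at the anchor (32, 24) — off-center in x so the +30 mm landmark stays inside
the patch — axis along patch +x, and a fixed metric scale of 1.5 patch px
per mm at the object (the largest scale that keeps the ±15 mm normal-leg
landmarks inside the 48 px height; at 2 px/mm they would fall outside).
The patch-to-image map is a similarity transform whose scale uses the
*current depth estimate* (the nominal source–object distance on the first
iteration); resampling is bilinear with edge padding, followed by a
per-patch z-score (constant crops map to zeros).  Regression targets are
landmark patch coordinates divided by patch width/height; they concentrate
in [0, 1] for well-initialized priors and are deliberately not clipped.

## Regressor

A VGG-style network maps the normalized patch to the 12 target values:
blocks of 3x3 ReLU convolutions each ending in 2x2 pooling, channels
doubling per block from 32, then fully connected layers with a linear
12-output head.  The full-scale 13-weight-layer reference configuration
(five 2-conv blocks + three FC layers) is constructible; the desk-scale
default used throughout the tests is 3 blocks x 1 conv, base 32 channels,
one hidden FC layer of 256, average pooling, no dropout.  Average pooling
and zero dropout were chosen for this precision-regression setting: max
pooling discards subpixel amplitude gradations and dropout injects noise
into an essentially deterministic clean-data mapping (both remain available
via `ArchConfig`).

Because the network is trained and run on a single CPU, the layers are
implemented directly in NumPy: convolutions as an im2col gather plus BLAS
matrix products (tap-major ordering keeps the channel axis contiguous), the
input gradient accumulated tap-by-tap, and the first layer skipping its
input gradient.  All randomness flows through explicit seeded generators, so
builds and training runs are bit-reproducible.

Training minimizes mean squared error with Adam (standard parameters) under
the staircase schedule lr = 5e-3 x 10^-floor(epoch / drop_every); the best
checkpoint is selected by validation loss, with the validation split made by
source image *before* patch expansion.  Two initialization details matter at
this scale: the output bias is set to the training-target mean, and the
output weights are scaled down 10x, so the first epochs refine rather than
re-derive the target offsets (without this the 5e-3 stage starts with a
destabilizing excursion and converges to a visibly worse optimum).

## Synthetic radiographs

The simulator stands in for CT-based digitally rendered radiographs.  Each
fiducial is a constructive union of axisymmetric solids: screw = head disk +
shaft + conical tip scaled to a 6.5 mm bounding-box diagonal (pose origin at
the head center); drill = 3 mm diameter cylinder with conical tip, modeled
only near the tip, pose origin at the apex; robot = spherical drilling head
+ two body cylinders with a joint gap, 13.15 mm head-to-joint diagonal, pose
origin at the head center.  A watertight triangle mesh is generated from the
same solids for export (STL) and ray-parity audits.

Rendering casts one ray per detector pixel from the point source and
accumulates the *analytic* chord length through each solid (quadratic
intersections clipped to axial slabs), composing attenuation in the log
domain (Beer–Lambert, display-effective mu = 1.0/mm) over an anatomy
surrogate: a non-negative band-limited Gaussian random field (correlation
length 30 px) that reproduces low fiducial-to-anatomy contrast alongside
high anatomy-to-anatomy contrast.  The fiducial transmission is rendered
with 2x2 supersampled rays and blurred by a Gaussian detector PSF (sigma
0.6 px) before downsampling: real detectors are band-limited, and an
unblurred analytic silhouette would alias subpixel edge information that
both real c-arms and CT-derived renderings retain.  Additive Gaussian
detector noise and clipping to [0, 1] complete the image; files are 16-bit
PNG with JSON-lines annotations and a manifest snapshotting config + seed.

Pose sampling is statistical and component-independent: position uniform
over the central 20% of the field of view, alpha ~ U(−180, 180], tau ~
U(−90, 90) (evaluation filters |tau| > 80 deg; generation does not), depth ~
U(850, 950) mm — an object near the isocenter of a c-arm with 1000 mm
source–detector distance, kept strictly inside the source–detector span so
every pose is renderable.  Small Gaussian pose jitter emulates noise around
nominal placements, with the test magnitude (0.5 mm / 2.5 deg) below the
training magnitude (1.0 mm / 5 deg).

### What the simulator does not emulate

Real anatomy (trabecular structure, air cavities, projected skull edges),
scatter and beam hardening, detector gain inhomogeneity, and geometric
calibration error.  Passing the scaled-down accuracy suite therefore
demonstrates that the *pipeline* — normalization, regression, geometric
inversion, iteration — recovers poses to sub-pixel accuracy when appearance
is governed by the stated projection model; it does not demonstrate
robustness to real-tissue clutter or sim-to-real transfer.

## Scaled-down study conditions

The turnkey benchmark (`fluoropose.benchmarks.scaled_screw_accuracy`, also
run by `scripts/acceptance.py`) uses: 1500 training / 200 test clean-
background screw images at 256x256 (d_sdd = 1000 mm, delta_ds = 0.5 mm/px),
3 prior perturbations per training image, the desk network, batch 64, 12
epochs with the learning-rate exponent dropping every 4 epochs (the
80-epoch / 35-epoch full-scale schedule compressed to desk scale), 2 sampled initial
poses per test image, 3 estimation iterations, and the |tau| <= 80 deg
evaluation filter.  These sizes keep a full from-scratch run (render, train,
evaluate) in the ten-minute range on one CPU core.  The patch scale is not
updated from the reconstructed depth inside the loop by default
(`update_depth=False` in the benchmark): the depth estimate's residual noise
(~3% std) would otherwise perturb the apparent scale between iterations;
the option remains available for ablation.

## Numerical choices

* A leg is degenerate when its landmark RMS spread is below 0.25 px, and leg
  lines are "near-parallel" below 1 degree; both raise explicit errors
  rather than returning silently patched poses (near |tau| = 90 deg the
  inversion is meaningless at subpixel noise).
* `cos(tau)` is clamped to [0, 1]; clamp events are reported in diagnostics.
* Total-least-squares line fits use the 2x2 scatter eigen-decomposition;
  two-point legs reduce to the exact line.
* Angles are stored in degrees, computed in radians; `alpha` wraps to
  (−180, 180].
* Reconstruction failures truncate the iteration trace with a reason; the
  evaluator flags them instead of scoring them.

## Known limitations

* Depth and projection angle are intrinsically weak single-view quantities
  (depth std ~30 mm, |tau| error ~3-4 deg at desk scale); position and
  forward angle are the precise outputs, consistent with the geometry: a 1%
  landmark-spacing error is a 1% depth error but only a ~0.1 px transverse
  one.
* Estimation quality degrades monotonically as |tau| approaches 90 deg (the
  axis leg collapses by cos tau); beyond 80 deg reconstruction is excluded
  from evaluation and may fail outright.
* The desk-scale network is trained on one fiducial and one geometry; no
  claim of cross-instrument transfer is made without retraining.
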