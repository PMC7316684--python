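# fluoropose

Single-view pose estimation of small surgical fiducials from X-ray-like
images, for navigation in minimally invasive temporal-bone procedures —
settings where optical tracking has no line of sight and intra-operative CT
costs too much dose.  A c-arm snapshot of a millimeter-scale titanium screw
(or drill tip, or miniature drilling robot), together with a coarse initial
guess, is enough to recover the instrument's pose to sub-pixel accuracy.

## The model

The single-view pose is `theta = (x, y, alpha, tau, d)`: detector-plane
position (px), in-plane forward angle (deg), out-of-plane projection angle
(deg, only `|tau|` is observable), and source-to-object depth (mm).  The
pipeline is modular:

1. **Appearance normalization** — crop a 92x48 patch around the prior pose
   so the instrument sits in a *standard pose* (fixed anchor, axis along
   patch x, fixed metric scale), z-score the intensities.
2. **Pseudo-landmark regression** — a small VGG-style CNN (NumPy, trained
   with Adam on MSE) predicts six pseudo-landmarks: points at fixed metric
   offsets in a 15 mm cross on the instrument axis and its in-plane normal,

       p_i = (x, y) + 1/(c_d2p * d) * R(alpha) @ (x_lp cos(tau), y_lp),

   with `c_d2p = delta_ds / d_sdd` the detector-to-projection conversion.
3. **Geometric reconstruction** — total-least-squares lines through the two
   cross legs intersect at `(x, y)` and give `alpha`; normal-leg spacing
   gives `d`; axis-leg foreshortening gives `|tau| = arccos(...)`.

The estimate is refined by re-cropping at the reconstructed pose (three
iterations by default).  A parametric radiograph simulator — analytic
ray-solid projection of constructive fiducial models over a Gaussian
random-field anatomy surrogate, with exact ground-truth export — provides
training and evaluation data end to end.

## Worked example

Simulate screw radiographs over the default anatomy-surrogate background,
train the desk-scale regressor, and evaluate the three-iteration estimator
from two sampled initial guesses per test image:

```sh
cat > train.yaml <<'YAML'
arch:  {blocks: 3, convs_per_block: 1, base_channels: 32, fc_layers: 2, dropout_rate: 0.0}
train: {lr_drop_every: 4, batch_size: 64, variations_per_image: 3}
YAML
fluoropose simulate --out data/train --n 1500 --split train --seed 101
fluoropose train --dataset data/train --out models/screw \
    --config train.yaml --epochs 12 --seed 7
fluoropose simulate --out data/test --n 200 --split test --seed 202
fluoropose experiment --dataset data/test --model models/screw \
    --out results/exp --k 2 --n-iter 3 --seed 11
```

The experiment command prints the aggregate error report (abridged; the run
is seed-for-seed reproducible):

```json
{
 "pos_err_px":  {"mean": 0.709, "std": 0.490, "max": 2.825},
 "pos_err_mm":  {"mean": 0.319, "std": 0.220},
 "fwd_err_deg": {"mean": 0.63, "std": 5.42},
 "proj_err_deg": {"mean": 6.98, "std": 6.59},
 "depth_err_mm": {"mean": 16.1, "std": 42.3},
 "n_evaluated": 358, "n_filtered": 42, "n_failed": 0
}
```

So against a low-contrast anatomy-like background the screw is localized to
~0.7 px (~0.3 mm in the plane through the fiducial) with the forward angle
good to a few degrees; depth and projection angle are intrinsically weak
single-view quantities (a 1% landmark-spacing error is a 1% depth error).
Cases with ground-truth `|tau| > 80 deg` are excluded ("n_filtered"): near
edge-on views the instrument axis aligns with the projection direction and
the out-of-plane inversion degenerates.  On the clean-background
configuration (no anatomy field, no detector noise) the same protocol
reaches a mean position error of ~0.07 mm (~0.15 px) — that run is exactly
what the acceptance script below reproduces.

The same pipeline is callable as a library (`fluoropose.estimate_pose_iterative`,
`fluoropose.run_experiment`, ...); see `docs/methods.md` for the model's
assumptions, the simulator's scope, and all numerical choices.

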