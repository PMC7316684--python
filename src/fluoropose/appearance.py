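"""Region-of-interest appearance normalization.

Megapixel radiographs are dominated by content irrelevant to the pose of a
millimeter-scale fiducial.  Given a prior pose estimate, this module cuts a
92x48 patch that is rotated, translated and scaled so the instrument sits in
a *standard pose*: reference point at a fixed anchor, forward axis along the
patch x-axis, fixed apparent size.  Under a perfect prior the instrument
looks (nearly) identical in every patch; the residual appearance encodes the
prior error, which is what the regressor learns to read out.

Regression targets are the six pseudo-landmarks mapped into patch
coordinates and normalized by the patch width/height; training priors are
drawn by perturbing the ground-truth pose in polar coordinates
(``R ~ U(0, dx_initial)``, ``beta ~ U(0, 360)``) with a normal forward-angle
offset (``dalpha ~ N(0, (dalpha_initial/3)^2)``), which skews samples toward
the standard pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .geometry import (
    ImageLandmarks,
    LandmarkPlacement,
    Pose,
    ProjectionGeometry,
    landmarks_from_pose,
    rotation_matrix,
    wrap_angle,
)

__all__ = [
    "PatchSpec",
    "PerturbationConfig",
    "PerturbationSample",
    "Patch",
    "sample_prior_perturbation",
    "perturb_pose",
    "extract_patch",
    "encode_targets",
    "decode_targets",
    "encode_pose_targets",
    "decode_pose_targets",
]


@dataclass(frozen=True)
class PatchSpec:
    """Standard-pose patch layout.

    The anchor is off-center in x so the asymmetric +30 mm axis landmark
    stays inside the 92 px width; ``px_per_mm`` fixes the apparent instrument
    size inside the patch (1.5 keeps the +/-15 mm normal-leg landmarks inside
    the 48 px height).
    """

    width: int = 92
    height: int = 48
    anchor: tuple[float, float] = (32.0, 24.0)
    px_per_mm: float = 1.5

    def __post_init__(self) -> None:
        ax, ay = self.anchor
        if not (0 < ax < self.width and 0 < ay < self.height):
            raise ValueError("anchor must lie strictly inside the patch")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")


@dataclass(frozen=True)
class PerturbationConfig:
    """Assumed accuracy of the initial pose (radial mm, angular deg)."""

    dx_initial: float = 2.5
    dalpha_initial: float = 30.0

    def __post_init__(self) -> None:
        if self.dx_initial <= 0 or self.dalpha_initial <= 0:
            raise ValueError("perturbation bounds must be strictly positive")


@dataclass(frozen=True)
class PerturbationSample:
    R: float        # radial offset, mm (in the object plane)
    beta: float     # offset direction, deg
    dalpha: float   # forward-angle offset, deg


def sample_prior_perturbation(
    config: PerturbationConfig, rng: np.random.Generator
) -> PerturbationSample:
    """Draw one in-plane prior perturbation (polar position + normal angle)."""
    return PerturbationSample(
        R=float(rng.uniform(0.0, config.dx_initial)),
        beta=float(rng.uniform(0.0, 360.0)),
        dalpha=float(rng.normal(0.0, config.dalpha_initial / 3.0)),
    )


def perturb_pose(
    pose: Pose,
    sample: PerturbationSample,
    geom: ProjectionGeometry,
    d_prior: float | None = None,
    clamp_dalpha: float | None = None,
) -> Pose:
    """Apply an in-plane perturbation to a pose, producing a prior guess.

    The metric radial offset is converted to pixels at the pose's true depth.
    ``d_prior`` overrides the depth stored in the prior (test-time priors
    carry the nominal source-object distance, not the unknown truth); the
    prior's tau is zeroed, since no out-of-plane prior is assumed.
    ``clamp_dalpha`` clips the angular offset (test-time initial guesses
    honor the stated +/-dalpha_initial accuracy; training draws are left
    unbounded).
    """
    scale = geom.px_per_mm(pose.d)
    b = math.radians(sample.beta)
    dalpha = sample.dalpha
    if clamp_dalpha is not None:
        dalpha = min(max(dalpha, -clamp_dalpha), clamp_dalpha)
    return Pose(
        x=pose.x + scale * sample.R * math.cos(b),
        y=pose.y + scale * sample.R * math.sin(b),
        alpha=wrap_angle(pose.alpha + dalpha),
        tau=0.0,
        d=pose.d if d_prior is None else d_prior,
    )


@dataclass(frozen=True)
class Patch:
    """Intensity-normalized standard-pose crop plus its image transform.

    ``to_image`` is the 3x3 homogeneous similarity mapping patch (col, row)
    coordinates to image (x, y) coordinates.
    """

    pixels: np.ndarray
    to_image: np.ndarray

    @property
    def from_image(self) -> np.ndarray:
        return np.linalg.inv(self.to_image)


def _patch_transform(prior: Pose, geom: ProjectionGeometry, spec: PatchSpec) -> np.ndarray:
    # image px per patch px at the prior's depth estimate
    s = geom.px_per_mm(prior.d) / spec.px_per_mm
    rot = rotation_matrix(prior.alpha)
    matrix = np.eye(3)
    matrix[:2, :2] = s * rot
    matrix[:2, 2] = np.array([prior.x, prior.y]) - s * rot @ np.asarray(spec.anchor)
    return matrix


def extract_patch(
    image: np.ndarray,
    prior: Pose,
    geom: ProjectionGeometry,
    spec: PatchSpec = PatchSpec(),
    interp_order: int = 1,
) -> Patch:
    """Resample the standard-pose patch around a prior pose estimate.

    Bilinear interpolation with edge-value padding, followed by a per-patch
    z-score; a constant crop normalizes to all zeros.  Raises ``ValueError``
    if the prior position falls outside the image.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if not (0 <= prior.x < w and 0 <= prior.y < h):
        raise ValueError(
            f"prior position ({prior.x:.1f}, {prior.y:.1f}) outside {w}x{h} image"
        )
    matrix = _patch_transform(prior, geom, spec)
    # skimage's warp takes the output->input (patch->image) map as inverse_map
    pixels = warp(
        img,
        inverse_map=AffineTransform(matrix=matrix),
        output_shape=(spec.height, spec.width),
        order=interp_order,
        mode="edge",
        preserve_range=True,
    )
    std = float(pixels.std())
    if std < 1e-12:
        pixels = np.zeros_like(pixels)
    else:
        pixels = (pixels - pixels.mean()) / std
    return Patch(pixels=pixels.astype(np.float32), to_image=matrix)


def _to_patch_coords(points: np.ndarray, patch: Patch) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    hom = np.column_stack([pts, np.ones(len(pts))])
    return (hom @ patch.from_image.T)[:, :2]


def _to_image_coords(points: np.ndarray, patch: Patch) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    hom = np.column_stack([pts, np.ones(len(pts))])
    return (hom @ patch.to_image.T)[:, :2]


def encode_targets(
    landmarks: ImageLandmarks, patch: Patch, spec: PatchSpec = PatchSpec()
) -> np.ndarray:
    """Landmarks -> flat regression target: patch coords over width/height.

    Targets of well-initialized standard-pose samples concentrate in [0, 1];
    values are deliberately not clipped (clipping would corrupt targets of
    poorly initialized priors).  Layout: (u1, v1, u2, v2, ..., u6, v6).
    """
    uv = _to_patch_coords(landmarks.points, patch)
    uv = uv / np.array([spec.width, spec.height], dtype=float)
    return uv.ravel()


def decode_targets(
    vec: np.ndarray, patch: Patch, spec: PatchSpec = PatchSpec()
) -> ImageLandmarks:
    """Exact inverse of :func:`encode_targets`."""
    uv = np.asarray(vec, dtype=float).reshape(-1, 2)
    uv = uv * np.array([spec.width, spec.height], dtype=float)
    return ImageLandmarks(points=_to_image_coords(uv, patch))


def encode_pose_targets(
    pose: Pose,
    patch: Patch,
    prior: Pose,
    geom: ProjectionGeometry,
    spec: PatchSpec = PatchSpec(),
) -> np.ndarray:
    """Direct-regression target vector for the end-to-end pipeline variant.

    Five values: normalized patch coordinates of the reference point, the
    forward-angle residual w.r.t. the prior in degrees, |tau| in degrees and
    the relative depth offset w.r.t. the prior's depth estimate.
    """
    uv = _to_patch_coords(np.array([[pose.x, pose.y]]), patch)[0]
    return np.array(
        [
            uv[0] / spec.width,
            uv[1] / spec.height,
            wrap_angle(pose.alpha - prior.alpha),
            abs(pose.tau),
            pose.d / prior.d - 1.0,
        ]
    )


def decode_pose_targets(
    vec: np.ndarray,
    patch: Patch,
    prior: Pose,
    spec: PatchSpec = PatchSpec(),
) -> Pose:
    """Inverse of :func:`encode_pose_targets`."""
    vec = np.asarray(vec, dtype=float)
    xy = _to_image_coords(
        np.array([[vec[0] * spec.width, vec[1] * spec.height]]), patch
    )[0]
    return Pose(
        x=float(xy[0]),
        y=float(xy[1]),
        alpha=wrap_angle(prior.alpha + float(vec[2])),
        tau=float(min(max(vec[3], 0.0), 90.0)),
        d=max(float(prior.d * (1.0 + vec[4])), 1e-6),
    )


def ground_truth_targets(
    gt_pose: Pose,
    patch: Patch,
    geom: ProjectionGeometry,
    placement: LandmarkPlacement,
    spec: PatchSpec = PatchSpec(),
) -> np.ndarray:
    """Encoded ground-truth landmarks for a patch (training targets)."""
    return encode_targets(landmarks_from_pose(gt_pose, geom, placement), patch, spec)
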