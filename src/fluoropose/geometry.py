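"""Pose parameterization and the forward/inverse projective landmark maps.

A single X-ray view of a small rigid fiducial is summarized by the 5-parameter
pose ``theta = (x, y, alpha, tau, d)``:

* ``x, y``  — sub-pixel detector-plane coordinates of the instrument's
  reference point (pixels; x right, y down),
* ``alpha`` — forward angle: in-plane angle between the projected instrument
  axis and the image x-axis, measured toward +y (degrees),
* ``tau``   — projection angle: tilt of the instrument axis out of the
  detector plane (degrees); a single view only constrains ``|tau|``,
* ``d``     — depth: distance from the X-ray source to the instrument along
  the projection normal (mm).

Six *pseudo-landmarks* are placed on the instrument axis and on its in-plane
normal, 15 mm apart in a cross shape.  Their image positions follow the
pinhole magnification model

    p_i = (x, y) + 1/(c_d2p * d) * R(alpha) @ (x_lp * cos(tau), y_lp)

with ``c_d2p = delta_ds / d_sdd`` (detector pixel spacing over
source-detector distance).  Because the cross legs are axis-aligned in the
instrument frame, the map inverts geometrically: total-least-squares lines
through the two legs intersect at ``(x, y)`` and give ``alpha``; pairwise
image distances on the in-plane leg give ``d``; pairwise distances on the
axis leg give ``cos(tau)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Pose",
    "ProjectionGeometry",
    "LandmarkPlacement",
    "ImageLandmarks",
    "ReconstructionDiagnostics",
    "GeometryError",
    "DegenerateLegError",
    "ReconstructionError",
    "InvalidLandmarksError",
    "wrap_angle",
    "landmarks_from_pose",
    "fit_leg_line",
    "estimate_depth",
    "estimate_projection_angle",
    "pose_from_landmarks",
]

#: a leg whose landmarks have RMS spread below this (px) is degenerate
DEGENERATE_LEG_RMS_PX = 0.25
#: leg lines meeting at less than this angle (deg) cannot be intersected
PARALLEL_LINE_ANGLE_DEG = 1.0


class GeometryError(ValueError):
    """Base class for geometric reconstruction failures."""


class DegenerateLegError(GeometryError):
    """A landmark leg collapsed to (numerically) a single point.

    This is the signature of the projection-angle degeneracy: as |tau|
    approaches 90 deg the axis leg shrinks by cos(tau) and carries no
    in-plane information.
    """


class ReconstructionError(GeometryError):
    """Leg lines are near-parallel; no stable intersection exists."""


class InvalidLandmarksError(GeometryError):
    """Landmark configuration violates the model (e.g. coincident pair)."""


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


@dataclass
class Pose:
    """5-parameter single-view pose (px, px, deg, deg, mm)."""

    x: float
    y: float
    alpha: float
    tau: float
    d: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"depth must be positive, got d={self.d}")
        self.alpha = wrap_angle(self.alpha)
        if not -90.0 <= self.tau <= 90.0:
            raise ValueError(f"tau must lie in [-90, 90], got {self.tau}")

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "alpha": self.alpha,
                "tau": self.tau, "d": self.d}

    @classmethod
    def from_dict(cls, data: dict) -> "Pose":
        return cls(x=data["x"], y=data["y"], alpha=data["alpha"],
                   tau=data["tau"], d=data["d"])


@dataclass(frozen=True)
class ProjectionGeometry:
    """Pinhole c-arm geometry: source-detector distance and pixel spacing."""

    d_sdd: float = 1000.0       # source-detector distance, mm
    delta_ds: float = 0.5       # detector pixel spacing, mm/px
    width: int = 1024
    height: int = 1024

    def __post_init__(self) -> None:
        if not self.d_sdd > 0:
            raise ValueError("d_sdd must be positive")
        if not self.delta_ds > 0:
            raise ValueError("delta_ds must be positive")

    @property
    def c_d2p(self) -> float:
        """Detector-to-projection conversion, (mm/px)/mm = 1/px."""
        return self.delta_ds / self.d_sdd

    def px_per_mm(self, d: float) -> float:
        """Image pixels per mm in the object plane at depth ``d``."""
        return 1.0 / (self.c_d2p * d)

    def to_dict(self) -> dict:
        return {"d_sdd": self.d_sdd, "delta_ds": self.delta_ds,
                "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, data: dict) -> "ProjectionGeometry":
        return cls(**data)


def _default_offsets() -> np.ndarray:
    # axis (x) leg: 3+1 landmarks; in-plane normal (y) leg: 2+1; shared center.
    # The asymmetric +30 mm landmark disambiguates the forward direction.
    return np.array(
        [[-15.0, 0.0], [0.0, 0.0], [15.0, 0.0], [30.0, 0.0],
         [0.0, -15.0], [0.0, 15.0]]
    )


@dataclass(frozen=True)
class LandmarkPlacement:
    """Local (instrument-frame) pseudo-landmark offsets in mm.

    Each offset has at most one nonzero component; exactly one offset is the
    shared central landmark (0, 0).  Landmarks with ``y_lp == 0`` form the
    axis ("x") leg, those with ``x_lp == 0`` the in-plane-normal ("y") leg.
    """

    offsets: np.ndarray = field(default_factory=_default_offsets)

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "offsets", arr)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("offsets must be an (n, 2) array")
        mixed = np.all(arr != 0.0, axis=1)
        if np.any(mixed):
            raise ValueError("each offset must have at most one nonzero component")
        central = np.all(arr == 0.0, axis=1)
        if central.sum() != 1:
            raise ValueError("exactly one central (0, 0) landmark is required")

    @property
    def x_leg(self) -> np.ndarray:
        """Indices of axis-leg landmarks (y_lp == 0, center included)."""
        return np.flatnonzero(self.offsets[:, 1] == 0.0)

    @property
    def y_leg(self) -> np.ndarray:
        """Indices of normal-leg landmarks (x_lp == 0, center included)."""
        return np.flatnonzero(self.offsets[:, 0] == 0.0)

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass(frozen=True)
class ImageLandmarks:
    """Projected landmark coordinates (px), index-aligned with a placement."""

    points: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", arr)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")

    def __len__(self) -> int:
        return len(self.points)


def rotation_matrix(alpha_deg: float) -> np.ndarray:
    """2D rotation taking the +x image axis toward +y for positive angles."""
    a = math.radians(alpha_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


def landmarks_from_pose(
    pose: Pose, geom: ProjectionGeometry, placement: LandmarkPlacement
) -> ImageLandmarks:
    """Forward map: project the local landmark cross into image coordinates."""
    scale = geom.px_per_mm(pose.d)
    cos_tau = math.cos(math.radians(pose.tau))
    local = placement.offsets * np.array([cos_tau, 1.0])
    pts = np.array([pose.x, pose.y]) + scale * local @ rotation_matrix(pose.alpha).T
    return ImageLandmarks(points=pts)


def fit_leg_line(
    points: np.ndarray, offsets: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal (total-least-squares) line through >= 2 image points.

    Returns ``(centroid, direction)`` with ``direction`` a unit vector.  When
    the 1D ``offsets`` of the leg landmarks are given, the direction sign is
    chosen to point from the most-negative-offset landmark toward the
    most-positive one, which fixes the forward-angle sign.

    Raises :class:`DegenerateLegError` if the points coincide within the
    RMS-spread tolerance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    rms = math.sqrt(float(np.mean(np.sum(centered**2, axis=1))))
    if rms < DEGENERATE_LEG_RMS_PX:
        raise DegenerateLegError(
            f"leg landmarks coincide (RMS spread {rms:.3g} px); "
            "projection-angle degeneracy"
        )
    scatter = centered.T @ centered
    _, vecs = np.linalg.eigh(scatter)
    direction = vecs[:, -1]  # eigenvector of the largest eigenvalue
    if offsets is not None:
        off = np.asarray(offsets, dtype=float)
        span = pts[int(np.argmax(off))] - pts[int(np.argmin(off))]
        if float(direction @ span) < 0.0:
            direction = -direction
    return centroid, direction


def _leg_pairs(indices: np.ndarray, offsets_1d: np.ndarray):
    """Unordered index pairs of a leg with distinct local offsets."""
    for a in range(len(indices)):
        for b in range(a + 1, len(indices)):
            if offsets_1d[a] != offsets_1d[b]:
                yield indices[a], indices[b], abs(offsets_1d[a] - offsets_1d[b])


def estimate_depth(
    landmarks: ImageLandmarks,
    placement: LandmarkPlacement,
    geom: ProjectionGeometry,
) -> float:
    """Depth from the in-plane (y) leg: image spacing is pure magnification.

    For every pair of y-leg landmarks, ``d = |y_lp_i - y_lp_j| /
    (c_d2p * ||p_i - p_j||)``; estimates are averaged (exact when noise-free).
    """
    idx = placement.y_leg
    off = placement.offsets[idx, 1]
    pts = landmarks.points
    estimates = []
    for i, j, d_lp in _leg_pairs(idx, off):
        dist = float(np.linalg.norm(pts[i] - pts[j]))
        if dist == 0.0:
            raise InvalidLandmarksError(
                f"coincident y-leg landmarks {i} and {j}: depth undefined"
            )
        estimates.append(d_lp / (geom.c_d2p * dist))
    if not estimates:
        raise InvalidLandmarksError("y-leg has no pair with distinct offsets")
    return float(np.mean(estimates))


def estimate_projection_angle(
    landmarks: ImageLandmarks,
    placement: LandmarkPlacement,
    geom: ProjectionGeometry,
    d: float,
) -> tuple[float, bool]:
    """|tau| in degrees from the foreshortening of the axis (x) leg.

    ``cos(tau) = c_d2p * d * ||p_i - p_j|| / |x_lp_i - x_lp_j|`` averaged over
    distinct x-leg pairs.  The mean cosine is clamped to [0, 1]; the returned
    flag reports whether clamping occurred (a symptom of noisy landmarks).
    Only the magnitude of tau is recoverable from one view.
    """
    if not d > 0:
        raise ValueError("d must be positive")
    idx = placement.x_leg
    off = placement.offsets[idx, 0]
    pts = landmarks.points
    cosines = []
    for i, j, d_lp in _leg_pairs(idx, off):
        dist = float(np.linalg.norm(pts[i] - pts[j]))
        cosines.append(geom.c_d2p * d * dist / d_lp)
    if not cosines:
        raise InvalidLandmarksError("x-leg has no pair with distinct offsets")
    mean_cos = float(np.mean(cosines))
    clamped = not 0.0 <= mean_cos <= 1.0
    mean_cos = min(max(mean_cos, 0.0), 1.0)
    return math.degrees(math.acos(mean_cos)), clamped


@dataclass
class ReconstructionDiagnostics:
    """Numerical health of a landmark->pose inversion."""

    x_leg_rms_px: float
    y_leg_rms_px: float
    leg_angle_deg: float
    cos_tau_clamped: bool


def pose_from_landmarks(
    landmarks: ImageLandmarks,
    placement: LandmarkPlacement,
    geom: ProjectionGeometry,
) -> tuple[Pose, ReconstructionDiagnostics]:
    """Invert the landmark projection geometrically.

    Total-least-squares lines through the two legs intersect at ``(x, y)``;
    the axis-leg direction gives ``alpha``; pairwise distances give ``d`` and
    ``|tau|``.  Raises :class:`DegenerateLegError` for collapsed legs and
    :class:`ReconstructionError` for near-parallel leg lines.
    """
    pts = landmarks.points
    xi, yi = placement.x_leg, placement.y_leg
    cx, dx = fit_leg_line(pts[xi], placement.offsets[xi, 0])
    cy, dy = fit_leg_line(pts[yi], placement.offsets[yi, 1])

    cross = float(dx[0] * dy[1] - dx[1] * dy[0])
    leg_angle = math.degrees(math.asin(min(abs(cross), 1.0)))
    if leg_angle < PARALLEL_LINE_ANGLE_DEG:
        raise ReconstructionError(
            f"leg lines are near-parallel ({leg_angle:.3g} deg apart)"
        )
    # intersection: cx + t*dx = cy + u*dy
    t = float(np.linalg.solve(np.column_stack([dx, -dy]), cy - cx)[0])
    position = cx + t * dx

    alpha = math.degrees(math.atan2(dx[1], dx[0]))
    d = estimate_depth(landmarks, placement, geom)
    tau, clamped = estimate_projection_angle(landmarks, placement, geom, d)

    def _rms(leg_pts, c, u):
        resid = (leg_pts - c) - np.outer((leg_pts - c) @ u, u)
        return math.sqrt(float(np.mean(np.sum(resid**2, axis=1))))

    diags = ReconstructionDiagnostics(
        x_leg_rms_px=_rms(pts[xi], cx, dx),
        y_leg_rms_px=_rms(pts[yi], cy, dy),
        leg_angle_deg=leg_angle,
        cos_tau_clamped=clamped,
    )
    pose = Pose(x=float(position[0]), y=float(position[1]),
                alpha=alpha, tau=tau, d=d)
    return pose, diags
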