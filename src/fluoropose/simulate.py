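"""Synthetic radiograph simulator with exact ground-truth pose export.

Stands in for CT-derived digitally rendered radiographs: a parametric
high-attenuation fiducial (surgical micro-screw, drill tip or a prototype
drilling robot) is projected through a c-arm-like pinhole geometry over an
anatomy-surrogate background, and the generating pose is exported exactly.

The fiducials are constructive unions of axisymmetric solids (cylinders,
cones, spheres).  The renderer casts one ray per detector pixel from the
point source and accumulates the exact analytic chord length through each
solid; the fiducial attenuates by Beer-Lambert ``exp(-mu * path)``.  A
triangle mesh is built from the same solids for export and geometric audits.
The anatomy surrogate is a band-limited Gaussian random field: it reproduces
the low fiducial-to-anatomy contrast alongside high anatomy-to-anatomy
contrast of real skull radiographs without requiring CT volumes.
"""

from __future__ import annotations

import dataclasses
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter

from .geometry import Pose, ProjectionGeometry, wrap_angle
from .io import AnnotationRecord, DatasetManifest, save_image, write_manifest

__all__ = [
    "FiducialModel",
    "SimPoseRanges",
    "BackgroundConfig",
    "DatasetConfig",
    "make_fiducial",
    "render_radiograph",
    "path_lengths",
    "sample_pose",
    "generate_dataset",
    "instrument_axis",
]

_MESH_SECTIONS = 96


# ---------------------------------------------------------------------------
# fiducial construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiducialModel:
    """A rigid radio-opaque instrument model.

    ``primitives`` are axisymmetric solids expressed in the instrument frame
    (axis = +x through the reference point at the origin, units mm):
    ``("cylinder", s0, s1, r)``, ``("cone", s_apex, s_base, r_base)`` and
    ``("sphere", s_center, r)`` where ``s`` is the axial coordinate.
    """

    kind: str
    mesh: trimesh.Trimesh
    primitives: tuple
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    reference_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    attenuation: float = 1.0  # display-effective linear coefficient, 1/mm

    @property
    def bounding_radius(self) -> float:
        """Radius of a reference-point-centered sphere enclosing all solids."""
        r = 0.0
        for prim in self.primitives:
            if prim[0] == "cylinder":
                _, s0, s1, rad = prim
                r = max(r, math.hypot(s0, rad), math.hypot(s1, rad))
            elif prim[0] == "cone":
                _, s_apex, s_base, rad = prim
                r = max(r, abs(s_apex), math.hypot(s_base, rad))
            else:
                _, s_c, rad = prim
                r = max(r, abs(s_c) + rad)
        return r

    def export_stl(self, path: str | Path) -> None:
        self.mesh.export(Path(path), file_type="stl")


def _primitive_bounds(primitives) -> tuple[float, float, float]:
    """(x_min, x_max, max radius) of the union in the instrument frame."""
    lo, hi, rmax = math.inf, -math.inf, 0.0
    for prim in primitives:
        if prim[0] == "cylinder":
            _, s0, s1, r = prim
            lo, hi, rmax = min(lo, s0), max(hi, s1), max(rmax, r)
        elif prim[0] == "cone":
            _, s_apex, s_base, r = prim
            lo = min(lo, s_apex, s_base)
            hi = max(hi, s_apex, s_base)
            rmax = max(rmax, r)
        else:
            _, s_c, r = prim
            lo, hi, rmax = min(lo, s_c - r), max(hi, s_c + r), max(rmax, r)
    return lo, hi, rmax


def _bbox_diagonal(primitives) -> float:
    lo, hi, rmax = _primitive_bounds(primitives)
    return math.sqrt((hi - lo) ** 2 + (2 * rmax) ** 2 + (2 * rmax) ** 2)


def _scale_primitives(primitives, factor: float) -> tuple:
    scaled = []
    for prim in primitives:
        scaled.append((prim[0],) + tuple(v * factor for v in prim[1:]))
    return tuple(scaled)


def _x_align() -> np.ndarray:
    """Homogeneous rotation mapping the +z axis onto +x."""
    return trimesh.transformations.rotation_matrix(math.pi / 2, [0.0, 1.0, 0.0])


def _cylinder_mesh(s0: float, s1: float, r: float) -> trimesh.Trimesh:
    mesh = trimesh.creation.cylinder(radius=r, height=s1 - s0, sections=_MESH_SECTIONS)
    mesh.apply_transform(_x_align())
    mesh.apply_translation([(s0 + s1) / 2 - mesh.bounds.mean(axis=0)[0], 0, 0])
    return mesh


def _cone_mesh(s_apex: float, s_base: float, r: float) -> trimesh.Trimesh:
    mesh = trimesh.creation.cone(radius=r, height=abs(s_apex - s_base),
                                 sections=_MESH_SECTIONS)
    mesh.apply_transform(_x_align())
    # after alignment the apex sits at max x; mirror if it must point backward
    if s_apex < s_base:
        mesh.apply_transform(trimesh.transformations.rotation_matrix(
            math.pi, [0.0, 0.0, 1.0]))
    base_x = mesh.bounds[0][0] if s_apex > s_base else mesh.bounds[1][0]
    mesh.apply_translation([s_base - base_x, 0, 0])
    return mesh


def _sphere_mesh(s_c: float, r: float) -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=r)
    mesh.apply_translation([s_c, 0, 0])
    return mesh


def _mesh_from_primitives(primitives) -> trimesh.Trimesh:
    parts = []
    for prim in primitives:
        if prim[0] == "cylinder":
            parts.append(_cylinder_mesh(*prim[1:]))
        elif prim[0] == "cone":
            parts.append(_cone_mesh(*prim[1:]))
        else:
            parts.append(_sphere_mesh(*prim[1:]))
    return trimesh.util.concatenate(parts)


SCREW_DIAGONAL_MM = 6.5
DRILL_DIAMETER_MM = 3.0
ROBOT_DIAGONAL_MM = 13.15  # bounding-box diagonal up to the joint


def make_fiducial(kind: str, attenuation: float = 1.0) -> FiducialModel:
    """Build one of the three supported instruments.

    * ``screw``: head disk + shaft cylinder + conical tip, scaled to a 6.5 mm
      bounding-box diagonal; the pose reference point is the head center.
    * ``drill``: 3 mm diameter cylinder with a conical tip; only the tip
      region is modeled (drill bending makes the shank pose meaningless) and
      the reference point is the tip apex.
    * ``robot``: spherical drilling head + two body cylinders separated by a
      flexible-joint gap; the head-to-joint bounding-box diagonal is
      13.15 mm and the reference point is the drill-head center.
    """
    if kind == "screw":
        prims = (
            ("cylinder", -0.4, 0.4, 1.25),   # head
            ("cylinder", 0.4, 4.05, 0.6),    # shaft
            ("cone", 5.05, 4.05, 0.6),       # tip (apex forward)
        )
        prims = _scale_primitives(prims, SCREW_DIAGONAL_MM / _bbox_diagonal(prims))
    elif kind == "drill":
        r = DRILL_DIAMETER_MM / 2.0
        prims = (
            ("cone", 0.0, -2.25, r),         # tip apex at the reference point
            ("cylinder", -9.0, -2.25, r),    # modeled tip section of the shank
        )
    elif kind == "robot":
        prims = (
            ("sphere", 0.0, 2.5),            # drilling head
            ("cylinder", 2.5, 10.0, 2.0),    # first body segment (to the joint)
            ("cylinder", 11.0, 18.0, 2.0),   # second segment behind the gap
        )
        head_to_joint = prims[:2]
        prims = _scale_primitives(prims, ROBOT_DIAGONAL_MM / _bbox_diagonal(head_to_joint))
    else:
        raise ValueError(f"unknown fiducial kind {kind!r}")
    return FiducialModel(
        kind=kind,
        mesh=_mesh_from_primitives(prims),
        primitives=prims,
        attenuation=attenuation,
    )


# ---------------------------------------------------------------------------
# analytic ray-solid chords
# ---------------------------------------------------------------------------

def _interval_overlap(lo1, hi1, lo2, hi2):
    return np.maximum(0.0, np.minimum(hi1, hi2) - np.maximum(lo1, lo2))


def _slab_interval(w_a, u_a, s0, s1):
    """t-interval where the axial coordinate s(t) = w_a + t*u_a is in [s0, s1]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (s0 - w_a) / u_a
        tb = (s1 - w_a) / u_a
    lo = np.minimum(ta, tb)
    hi = np.maximum(ta, tb)
    parallel = np.abs(u_a) < 1e-12
    inside = (w_a >= s0) & (w_a <= s1)
    lo = np.where(parallel, np.where(inside, -np.inf, np.inf), lo)
    hi = np.where(parallel, np.where(inside, np.inf, -np.inf), hi)
    return lo, hi


def _chord_cylinder(w_p, u_p, w_a, u_a, s0, s1, r):
    a = np.einsum("ij,ij->i", u_p, u_p)
    b = 2.0 * u_p @ w_p
    c = float(w_p @ w_p) - r * r
    disc = b * b - 4.0 * a * c
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-b - sq) / (2.0 * a)
        t2 = (-b + sq) / (2.0 * a)
    axial = a < 1e-14  # ray parallel to the cylinder axis
    inside_axial = axial & (c < 0.0)
    t1 = np.where(axial, np.where(inside_axial, -np.inf, np.inf), t1)
    t2 = np.where(axial, np.where(inside_axial, np.inf, -np.inf), t2)
    miss = (~axial) & (disc <= 0.0)
    t1 = np.where(miss, np.inf, t1)
    t2 = np.where(miss, -np.inf, t2)
    sl, sh = _slab_interval(w_a, u_a, s0, s1)
    return _interval_overlap(t1, t2, sl, sh)


def _chord_cone(w_p, u_p, w_a, u_a, s_apex, s_base, r_base):
    k2 = (r_base / (s_base - s_apex)) ** 2
    da = w_a - s_apex
    a = np.einsum("ij,ij->i", u_p, u_p) - k2 * u_a * u_a
    b = 2.0 * (u_p @ w_p - k2 * u_a * da)
    c = float(w_p @ w_p) - k2 * da * da
    disc = b * b - 4.0 * a * c
    sq = np.sqrt(np.maximum(disc, 0.0))
    sl, sh = _slab_interval(w_a, u_a, min(s_apex, s_base), max(s_apex, s_base))

    eps = 1e-12
    quad = np.abs(a) > eps
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(quad, (-b - sq) / (2.0 * a), 0.0)
        r2 = np.where(quad, (-b + sq) / (2.0 * a), 0.0)
    lo = np.minimum(r1, r2)
    hi = np.maximum(r1, r2)

    chord = np.zeros_like(u_a)
    # opening-up quadratic: inside set is [lo, hi]
    pos = quad & (a > 0) & (disc > 0.0)
    chord = np.where(pos, _interval_overlap(lo, hi, sl, sh), chord)
    # opening-down: inside set is the complement (-inf, lo] U [hi, inf)
    neg_two = quad & (a < 0) & (disc > 0.0)
    both = (_interval_overlap(-np.inf, lo, sl, sh)
            + _interval_overlap(hi, np.inf, sl, sh))
    chord = np.where(neg_two, both, chord)
    neg_all = quad & (a < 0) & (disc <= 0.0)  # whole slab inside the double cone
    chord = np.where(neg_all, _interval_overlap(-np.inf, np.inf, sl, sh), chord)
    # (near-)linear boundary: b*t + c <= 0 is a half line
    lin = ~quad
    if np.any(lin):
        with np.errstate(divide="ignore", invalid="ignore"):
            tstar = -c / b
        half = np.where(
            b > eps,
            _interval_overlap(-np.inf, tstar, sl, sh),
            np.where(
                b < -eps,
                _interval_overlap(tstar, np.inf, sl, sh),
                np.where(c <= 0.0, _interval_overlap(-np.inf, np.inf, sl, sh), 0.0),
            ),
        )
        chord = np.where(lin, half, chord)
    return chord


def _chord_sphere(origin_to_center, u, r):
    b = -2.0 * u @ origin_to_center
    c = float(origin_to_center @ origin_to_center) - r * r
    disc = b * b - 4.0 * c
    return np.where(disc > 0.0, np.sqrt(np.maximum(disc, 0.0)), 0.0)


def instrument_axis(pose: Pose) -> np.ndarray:
    """3D unit axis in detector-aligned coordinates (x right, y down, z = normal)."""
    a = math.radians(pose.alpha)
    t = math.radians(pose.tau)
    return np.array([math.cos(a) * math.cos(t),
                     math.sin(a) * math.cos(t),
                     math.sin(t)])


def _instrument_position(pose: Pose, geom: ProjectionGeometry) -> np.ndarray:
    cx = (geom.width - 1) / 2.0
    cy = (geom.height - 1) / 2.0
    scale = geom.delta_ds * pose.d / geom.d_sdd
    return np.array([(pose.x - cx) * scale, (pose.y - cy) * scale, pose.d])


def path_lengths(fid: FiducialModel, pose: Pose, geom: ProjectionGeometry,
                 directions: np.ndarray) -> np.ndarray:
    """Exact chord length (mm) of unit rays from the source through the solids."""
    p = _instrument_position(pose, geom)
    axis = instrument_axis(pose)
    u = np.asarray(directions, dtype=float)
    w = -p  # source at the origin
    w_a = float(w @ axis)
    w_perp = w - w_a * axis
    u_a = u @ axis
    u_perp = u - u_a[:, None] * axis
    total = np.zeros(len(u))
    for prim in fid.primitives:
        if prim[0] == "cylinder":
            total += _chord_cylinder(w_perp, u_perp, w_a, u_a, *prim[1:])
        elif prim[0] == "cone":
            total += _chord_cone(w_perp, u_perp, w_a, u_a, *prim[1:])
        else:
            s_c, r = prim[1], prim[2]
            center = p + s_c * axis
            total += _chord_sphere(-center, u, r)
    return total


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundConfig:
    """Anatomy-surrogate and detector-noise parameters.

    ``amplitude`` scales a non-negative band-limited Gaussian random field
    added to the attenuation line integral (anatomy surrogate);
    ``correlation_length`` is its smoothing scale in px; ``noise_sigma`` is
    additive detector noise on the display intensity; ``contrast`` scales all
    attenuation.  ``psf_sigma_px`` is the detector point-spread (focal spot +
    scintillator blur) applied to the fiducial transmission, rendered with
    ``supersample``^2 rays per pixel — real detectors are band-limited, and
    without this the fiducial silhouette would alias at the pixel grid.  The
    all-zero configuration yields noise-free, unblurred images.
    """

    amplitude: float = 0.8
    correlation_length: float = 30.0
    noise_sigma: float = 0.01
    contrast: float = 1.0
    psf_sigma_px: float = 0.6
    supersample: int = 2

    def __post_init__(self) -> None:
        if min(self.amplitude, self.correlation_length,
               self.noise_sigma, self.contrast, self.psf_sigma_px) < 0:
            raise ValueError("background parameters must be non-negative")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    @classmethod
    def clean(cls) -> "BackgroundConfig":
        """No anatomy surrogate, no detector noise (detector PSF retained)."""
        return cls(amplitude=0.0, correlation_length=0.0, noise_sigma=0.0,
                   contrast=1.0)


def _pixel_directions(geom: ProjectionGeometry, xs: np.ndarray,
                      ys: np.ndarray) -> np.ndarray:
    cx = (geom.width - 1) / 2.0
    cy = (geom.height - 1) / 2.0
    pts = np.stack(
        [(xs - cx) * geom.delta_ds, (ys - cy) * geom.delta_ds,
         np.full_like(xs, geom.d_sdd, dtype=float)], axis=-1)
    return pts / np.linalg.norm(pts, axis=-1, keepdims=True)


def render_radiograph(
    fid: FiducialModel,
    pose: Pose,
    geom: ProjectionGeometry,
    bg: BackgroundConfig = BackgroundConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one radiograph; returns a (height, width) float image in [0, 1].

    Per-pixel rays from the point source accumulate the analytic path length
    through the fiducial solids; attenuations compose in the log domain
    (Beer-Lambert) with the anatomy-surrogate field, followed by additive
    detector noise and clipping to the display range.
    """
    if not (0.0 < pose.d < geom.d_sdd):
        raise ValueError(
            f"pose depth {pose.d} mm outside the source-detector span")
    if not (0 <= pose.x < geom.width and 0 <= pose.y < geom.height):
        raise ValueError("pose projects outside the field of view")
    if rng is None:
        rng = np.random.default_rng(0)

    attenuation = np.zeros((geom.height, geom.width))
    if bg.amplitude > 0.0:
        fld = rng.standard_normal((geom.height, geom.width))
        fld = gaussian_filter(fld, sigma=max(bg.correlation_length, 1e-6))
        lo, hi = fld.min(), fld.max()
        if hi > lo:
            fld = (fld - lo) / (hi - lo)
        attenuation += bg.amplitude * fld

    # only rays inside the projected bounding circle can hit the fiducial
    margin_px = fid.bounding_radius * geom.px_per_mm(
        max(pose.d - fid.bounding_radius, 1e-6)) + 2.0 + 4.0 * bg.psf_sigma_px
    x0 = max(int(pose.x - margin_px), 0)
    x1 = min(int(pose.x + margin_px) + 1, geom.width)
    y0 = max(int(pose.y - margin_px), 0)
    y1 = min(int(pose.y + margin_px) + 1, geom.height)
    image = np.exp(-bg.contrast * attenuation)
    if x1 > x0 and y1 > y0:
        ss = bg.supersample
        # ss^2 rays per pixel on the subpixel grid (pixel centers at i + 0.5/ss
        # offsets), blurred by the detector PSF, then box-downsampled
        fine_x = x0 + (np.arange((x1 - x0) * ss) + 0.5) / ss - 0.5
        fine_y = y0 + (np.arange((y1 - y0) * ss) + 0.5) / ss - 0.5
        ys_f, xs_f = np.meshgrid(fine_y, fine_x, indexing="ij")
        dirs = _pixel_directions(geom, xs_f.ravel(), ys_f.ravel())
        lengths = path_lengths(fid, pose, geom, dirs).reshape(ys_f.shape)
        transmission = np.exp(-bg.contrast * fid.attenuation * lengths)
        if bg.psf_sigma_px > 0.0:
            transmission = gaussian_filter(transmission, sigma=ss * bg.psf_sigma_px,
                                           mode="nearest")
        if ss > 1:
            transmission = transmission.reshape(
                y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
        image[y0:y1, x0:x1] *= transmission
    if bg.noise_sigma > 0.0:
        image = image + rng.normal(0.0, bg.noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0)


# ---------------------------------------------------------------------------
# statistical pose sampling and dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimPoseRanges:
    """Statistical pose-sampling ranges plus train/test pose jitter.

    Jitter emulates the noise added around nominal instrument placements;
    the test magnitude must not exceed the training magnitude (test sets
    stay closer to realistic placements).
    """

    depth_mm: tuple[float, float] = (850.0, 950.0)
    x_px: tuple[float, float] | None = None  # None: central 20% of the image
    y_px: tuple[float, float] | None = None
    alpha_deg: tuple[float, float] = (-180.0, 180.0)
    tau_deg: tuple[float, float] = (-90.0, 90.0)
    train_jitter_mm: float = 1.0
    train_jitter_deg: float = 5.0
    test_jitter_mm: float = 0.5
    test_jitter_deg: float = 2.5

    def __post_init__(self) -> None:
        if self.test_jitter_mm > self.train_jitter_mm or \
                self.test_jitter_deg > self.train_jitter_deg:
            raise ValueError("test jitter must not exceed train jitter")

    def resolve(self, geom: ProjectionGeometry) -> "SimPoseRanges":
        x = self.x_px or (0.4 * geom.width, 0.6 * geom.width)
        y = self.y_px or (0.4 * geom.height, 0.6 * geom.height)
        return dataclasses.replace(self, x_px=tuple(x), y_px=tuple(y))


def sample_pose(ranges: SimPoseRanges, rng: np.random.Generator) -> Pose:
    """Independent uniform draws per pose component (ranges must be resolved)."""
    if ranges.x_px is None or ranges.y_px is None:
        raise ValueError("position ranges unresolved; call ranges.resolve(geom)")
    return Pose(
        x=float(rng.uniform(*ranges.x_px)),
        y=float(rng.uniform(*ranges.y_px)),
        alpha=float(rng.uniform(*ranges.alpha_deg)),
        tau=float(rng.uniform(*ranges.tau_deg)),
        d=float(rng.uniform(*ranges.depth_mm)),
    )


def _jitter_pose(pose: Pose, ranges: SimPoseRanges, split: str,
                 geom: ProjectionGeometry, rng: np.random.Generator) -> Pose:
    mm = ranges.train_jitter_mm if split == "train" else ranges.test_jitter_mm
    deg = ranges.train_jitter_deg if split == "train" else ranges.test_jitter_deg
    px = mm * geom.px_per_mm(pose.d)
    return Pose(
        x=float(np.clip(pose.x + rng.normal(0.0, px), 0, geom.width - 1)),
        y=float(np.clip(pose.y + rng.normal(0.0, px), 0, geom.height - 1)),
        alpha=wrap_angle(pose.alpha + rng.normal(0.0, deg)),
        tau=float(np.clip(pose.tau + rng.normal(0.0, deg), -90.0, 90.0)),
        d=pose.d,
    )


@dataclass(frozen=True)
class DatasetConfig:
    """Everything needed to regenerate a dataset (with a seed)."""

    n_images: int = 100
    split: str = "train"
    fiducial: str = "screw"
    geom: ProjectionGeometry = ProjectionGeometry(width=256, height=256)
    ranges: SimPoseRanges = SimPoseRanges()
    background: BackgroundConfig = BackgroundConfig()
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValueError("split must be 'train' or 'test'")

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["geom"] = self.geom.to_dict()
        return data


def generate_dataset(config: DatasetConfig, out_dir: str | Path,
                     seed: int = 0) -> DatasetManifest:
    """Render a dataset: PNG images + JSON-lines annotations + manifest.

    Fully reproducible from ``(config, seed)``; partially written output is
    removed if generation fails.
    """
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    fid = make_fiducial(config.fiducial, attenuation=config.attenuation)
    ranges = config.ranges.resolve(config.geom)
    master = np.random.default_rng(seed)
    records: list[AnnotationRecord] = []
    try:
        for i in range(config.n_images):
            pose_seed = int(master.integers(2**31))
            render_seed = int(master.integers(2**31))
            pose_rng = np.random.default_rng(pose_seed)
            pose = _jitter_pose(sample_pose(ranges, pose_rng), ranges,
                                config.split, config.geom, pose_rng)
            image = render_radiograph(fid, pose, config.geom, config.background,
                                      rng=np.random.default_rng(render_seed))
            name = f"{config.split}_{i:05d}.png"
            save_image(out / name, image)
            records.append(AnnotationRecord(
                image=name, pose=pose, geometry=config.geom,
                fiducial=config.fiducial, seed=render_seed))
        manifest = DatasetManifest(root=out, config=config.to_dict(),
                                   seed=seed, records=records)
        write_manifest(manifest)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for rec in records:
                (out / rec.image).unlink(missing_ok=True)
        raise
    return manifest
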