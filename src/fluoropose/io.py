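"""Annotation and dataset-manifest serialization.

Annotations are JSON-lines (one record per image) next to a single JSON
manifest that snapshots the generation config and seed.  The schema is
versioned and states units and coordinate conventions explicitly; poses
round-trip bit-exactly (JSON shortest-repr floats are lossless).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import Pose, ProjectionGeometry

__all__ = [
    "SCHEMA_VERSION",
    "AnnotationRecord",
    "DatasetManifest",
    "AnnotationError",
    "write_annotations",
    "read_annotations",
    "write_manifest",
    "read_manifest",
    "save_image",
    "load_image",
]

SCHEMA_VERSION = 1

HEADER = {
    "schema_version": SCHEMA_VERSION,
    "units": {"x": "px", "y": "px", "alpha": "deg", "tau": "deg", "d": "mm"},
    "coordinate_convention": (
        "image x right, y down; alpha from +x toward +y; "
        "d = source-object distance along the projection normal"
    ),
}


class AnnotationError(ValueError):
    """Malformed annotation file or record."""


@dataclass(frozen=True)
class AnnotationRecord:
    """Ground truth for one rendered image."""

    image: str                       # path relative to the manifest
    pose: Pose
    geometry: ProjectionGeometry
    fiducial: str
    seed: int                        # render-noise seed (regeneration audit)

    def to_dict(self) -> dict:
        return {
            "image": self.image,
            "pose": self.pose.to_dict(),
            "geometry": self.geometry.to_dict(),
            "fiducial": self.fiducial,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict, line: int | None = None) -> "AnnotationRecord":
        where = f" (line {line})" if line is not None else ""
        for key in ("image", "pose", "geometry", "fiducial", "seed"):
            if key not in data:
                raise AnnotationError(f"record missing field {key!r}{where}")
        for key in ("x", "y", "alpha", "tau", "d"):
            if key not in data["pose"]:
                raise AnnotationError(f"pose missing field {key!r}{where}")
        return cls(
            image=data["image"],
            pose=Pose.from_dict(data["pose"]),
            geometry=ProjectionGeometry.from_dict(data["geometry"]),
            fiducial=data["fiducial"],
            seed=int(data["seed"]),
        )


def write_annotations(path: str | Path, records: list[AnnotationRecord]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"header": HEADER}) + "\n")
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    records: list[AnnotationRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                data = json.loads(line)
            except json.JSONDecodeError as exc:
                raise AnnotationError(f"malformed JSON on line {lineno}: {exc}") from exc
            if lineno == 1 and "header" in data:
                version = data["header"].get("schema_version")
                if version != SCHEMA_VERSION:
                    raise AnnotationError(
                        f"schema version mismatch: file has {version}, "
                        f"reader supports {SCHEMA_VERSION}"
                    )
                continue
            records.append(AnnotationRecord.from_dict(data, line=lineno))
    return records


@dataclass
class DatasetManifest:
    """Dataset root, generation config snapshot and its records."""

    root: Path
    config: dict
    seed: int
    records: list[AnnotationRecord] = field(default_factory=list)
    annotations_file: str = "annotations.jsonl"

    def image_path(self, record: AnnotationRecord) -> Path:
        return self.root / record.image


def write_manifest(manifest: DatasetManifest) -> Path:
    root = Path(manifest.root)
    write_annotations(root / manifest.annotations_file, manifest.records)
    payload = {
        **HEADER,
        "seed": manifest.seed,
        "config": manifest.config,
        "n_images": len(manifest.records),
        "annotations": manifest.annotations_file,
        "images": [rec.image for rec in manifest.records],
    }
    path = root / "manifest.json"
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    data = json.loads(path.read_text())
    if data.get("schema_version") != SCHEMA_VERSION:
        raise AnnotationError(
            f"schema version mismatch: manifest has {data.get('schema_version')}"
        )
    root = path.parent
    records = read_annotations(root / data["annotations"])
    manifest = DatasetManifest(
        root=root,
        config=data["config"],
        seed=data["seed"],
        records=records,
        annotations_file=data["annotations"],
    )
    missing = [rec.image for rec in records if not manifest.image_path(rec).exists()]
    if missing:
        raise AnnotationError(
            f"manifest references missing image(s), e.g. {missing[0]!r}"
        )
    return manifest


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Store a [0, 1] float image as 16-bit grayscale PNG (or TIFF)."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535.0).astype(np.uint16))


def load_image(path: str | Path) -> np.ndarray:
    """Load a stored radiograph back to float in [0, 1]."""
    raw = iio.imread(Path(path))
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    return raw.astype(float)
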