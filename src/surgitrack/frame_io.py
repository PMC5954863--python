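"""Frame-sequence and annotation I/O.

Conventions used throughout the package
---------------------------------------
* Images are 8-bit RGB arrays of shape ``(height, width, 3)``.
* Pixel coordinates are 0-based with the origin at the centre of the
  top-left pixel, ``x`` increasing rightward (columns) and ``y``
  increasing downward (rows).  All centroids are ``(x, y)`` pairs.
* Frame time is ``index / fps`` seconds.

Annotations use this package's own JSON schema (one record per object per
frame) with a CSV fallback that drops the optional boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Frame",
    "AnnotationRecord",
    "FrameFormatError",
    "AnnotationSchemaError",
    "read_frames",
    "write_frames",
    "read_annotations",
    "write_annotations",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


class FrameFormatError(ValueError):
    """Raised when a frame sequence is malformed (shape/dtype mismatch)."""


class AnnotationSchemaError(ValueError):
    """Raised when an annotation file violates the documented schema."""


@dataclass(frozen=True)
class Frame:
    """A single RGB video frame.

    Parameters
    ----------
    index : int
        Non-negative frame number within the sequence.
    time_s : float
        Timestamp in seconds, ``index / fps``.
    pixels : ndarray
        ``(H, W, 3)`` uint8 array, channel order RGB.
    """

    index: int
    time_s: float
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"frame index must be non-negative, got {self.index}")
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FrameFormatError(f"pixels must be (H, W, 3), got shape {px.shape}")
        if px.dtype != np.uint8:
            raise FrameFormatError(f"pixels must be uint8, got {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class AnnotationRecord:
    """Ground-truth (or detection) record for one object in one frame.

    ``object_label`` is the instrument number; hemorrhage regions use 0.
    ``boundary`` is an optional ordered list of (x, y) boundary pixels and
    ``area_px`` the pixel count enclosed by it.
    """

    frame_index: int
    object_kind: str  # "hemorrhage" | "instrument"
    object_label: int
    centroid: tuple[float, float]
    boundary: list[tuple[float, float]] | None = None
    area_px: int | None = None

    def __post_init__(self) -> None:
        if self.object_kind not in ("hemorrhage", "instrument"):
            raise AnnotationSchemaError(
                f"object_kind must be 'hemorrhage' or 'instrument', got {self.object_kind!r}"
            )
        self.centroid = (float(self.centroid[0]), float(self.centroid[1]))
        if self.boundary is not None:
            self.boundary = [(float(x), float(y)) for x, y in self.boundary]


def read_frames(path: str | Path, fps: float = 10.0) -> list[Frame]:
    """Read an ordered frame sequence from a directory of images or a video file.

    Image files in a directory are taken in lexicographic order.  An empty
    directory yields an empty list.  All frames must share one size.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        images = []
        for p in files:
            try:
                images.append(_to_rgb8(iio.imread(p)))
            except FrameFormatError:
                raise
            except Exception as exc:  # unreadable entry
                raise IOError(f"could not read frame file {p}") from exc
    else:
        if not path.exists():
            raise IOError(f"no such frame source: {path}")
        try:
            images = [_to_rgb8(im) for im in iio.imiter(path)]
        except FrameFormatError:
            raise
        except Exception as exc:
            raise IOError(f"could not decode video file {path}") from exc

    frames: list[Frame] = []
    shape = None
    for i, px in enumerate(images):
        if shape is None:
            shape = px.shape
        elif px.shape != shape:
            raise FrameFormatError(
                f"inconsistent frame dimensions: frame {i} has {px.shape}, expected {shape}"
            )
        frames.append(Frame(index=i, time_s=i / fps, pixels=px))
    return frames


def _to_rgb8(im: np.ndarray) -> np.ndarray:
    im = np.asarray(im)
    if im.ndim == 2:
        im = np.stack([im] * 3, axis=-1)
    if im.shape[-1] == 4:  # drop alpha
        im = im[..., :3]
    if im.ndim != 3 or im.shape[-1] != 3:
        raise FrameFormatError(f"unsupported image shape {im.shape}")
    if im.dtype != np.uint8:
        im = np.clip(im, 0, 255).astype(np.uint8)
    return im


def write_frames(frames: Iterable[Frame], out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded PNG files; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fr in frames:
        p = out_dir / f"frame_{fr.index:06d}.png"
        iio.imwrite(p, fr.pixels)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("frame_index", "object_kind", "object_label", "centroid")


def write_annotations(
    records: Sequence[AnnotationRecord],
    path: str | Path,
    width: int | None = None,
    height: int | None = None,
) -> None:
    """Write annotation records to JSON (``.json``) or CSV (``.csv``).

    The JSON form carries optional image ``width``/``height`` metadata used
    for bounds validation on read.  CSV drops boundaries.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["frame_index", "object_kind", "object_label", "x", "y", "area_px"]
            if width is not None and height is not None:
                header += ["width", "height"]
            w.writerow(header)
            for r in records:
                row = [
                    r.frame_index,
                    r.object_kind,
                    r.object_label,
                    r.centroid[0],
                    r.centroid[1],
                    "" if r.area_px is None else r.area_px,
                ]
                if width is not None and height is not None:
                    row += [width, height]
                w.writerow(row)
        return
    payload = {
        "schema": "surgitrack-annotations-v1",
        "width": width,
        "height": height,
        "records": [
            {
                "frame_index": r.frame_index,
                "object_kind": r.object_kind,
                "object_label": r.object_label,
                "centroid": list(r.centroid),
                "boundary": None if r.boundary is None else [list(b) for b in r.boundary],
                "area_px": r.area_px,
            }
            for r in records
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read annotation records from JSON or CSV; validates the schema.

    Raises :class:`AnnotationSchemaError` (with the record index) on a
    missing required field or a centroid outside the stated image bounds.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    with open(path) as fh:
        payload = json.load(fh)
    width = payload.get("width")
    height = payload.get("height")
    records = []
    for i, raw in enumerate(payload.get("records", [])):
        for f in _REQUIRED_FIELDS:
            if raw.get(f) is None:
                raise AnnotationSchemaError(f"record {i}: missing required field {f!r}")
        try:
            rec = AnnotationRecord(
                frame_index=int(raw["frame_index"]),
                object_kind=str(raw["object_kind"]),
                object_label=int(raw["object_label"]),
                centroid=tuple(raw["centroid"]),
                boundary=None
                if raw.get("boundary") is None
                else [tuple(b) for b in raw["boundary"]],
                area_px=None if raw.get("area_px") is None else int(raw["area_px"]),
            )
        except (TypeError, ValueError, AnnotationSchemaError) as exc:
            raise AnnotationSchemaError(f"record {i}: {exc}") from exc
        _check_bounds(rec, width, height, i)
        records.append(rec)
    return records


def _read_csv(path: Path) -> list[AnnotationRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader):
            for f in ("frame_index", "object_kind", "object_label", "x", "y"):
                if row.get(f) in (None, ""):
                    raise AnnotationSchemaError(f"record {i}: missing required field {f!r}")
            try:
                rec = AnnotationRecord(
                    frame_index=int(row["frame_index"]),
                    object_kind=row["object_kind"],
                    object_label=int(row["object_label"]),
                    centroid=(float(row["x"]), float(row["y"])),
                    area_px=None if row.get("area_px") in (None, "") else int(row["area_px"]),
                )
            except (TypeError, ValueError, AnnotationSchemaError) as exc:
                raise AnnotationSchemaError(f"record {i}: {exc}") from exc
            width = int(row["width"]) if row.get("width") not in (None, "") else None
            height = int(row["height"]) if row.get("height") not in (None, "") else None
            _check_bounds(rec, width, height, i)
            records.append(rec)
    return records


def _check_bounds(
    rec: AnnotationRecord, width: int | None, height: int | None, idx: int
) -> None:
    x, y = rec.centroid
    if width is not None and not (0 <= x <= width - 1):
        raise AnnotationSchemaError(
            f"record {idx}: centroid x={x} outside image width {width}"
        )
    if height is not None and not (0 <= y <= height - 1):
        raise AnnotationSchemaError(
            f"record {idx}: centroid y={y} outside image height {height}"
        )
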