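"""Image, depth and intrinsics readers/writers plus run reporting.

Images are 8-bit RGB PNG (JPEG accepted as a convenience); depth maps are
16-bit grayscale PNG or whitespace-delimited matrix text with values in
depth units (millimeters by default).  Results serialize to a small
versioned JSON schema, and a debug directory can receive every intermediate
stage image of a pipeline run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .branch_pipeline import BranchSegmentation, GripPoint
from .color_spaces import FeatureChannel
from .fruit_pipeline import CameraIntrinsics, FruitDetection, FruitSegmentation

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_VERSION",
    "InputError",
    "DimensionMismatchError",
    "RunReport",
    "read_rgb",
    "read_depth",
    "read_intrinsics",
    "check_depth_matches",
    "detections_to_json",
    "grip_to_json",
    "write_json",
    "write_debug_images",
    "write_fruit_overlay",
    "write_grip_overlay",
]

SCHEMA_VERSION = 1


class InputError(ValueError):
    """Unreadable or malformed input file."""


class DimensionMismatchError(InputError):
    """RGB image and depth map shapes disagree."""


@dataclass
class RunReport:
    """Metadata emitted once per pipeline run."""

    command: str
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB raster; an alpha channel is dropped with a warning."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        img = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if img.ndim == 2:
        raise InputError(f"{path} is single-channel; an RGB image is required")
    if img.ndim != 3 or img.shape[2] not in (3, 4):
        raise InputError(f"{path} has unsupported shape {img.shape}")
    if img.shape[2] == 4:
        logger.warning("%s has an alpha channel; dropping it", path)
        img = img[..., :3]
    if img.dtype != np.uint8:
        raise InputError(f"{path} is not 8-bit (dtype {img.dtype})")
    return img


def read_depth(path: str | Path) -> np.ndarray:
    """Read a depth map: 16-bit grayscale PNG or whitespace-matrix text."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"depth file not found: {path}")
    if path.suffix.lower() in (".txt", ".dat", ".csv"):
        try:
            depth = np.loadtxt(path)
        except Exception as exc:
            raise InputError(f"cannot parse depth matrix {path}: {exc}") from exc
    else:
        depth = iio.imread(path)
        if depth.ndim != 2:
            raise InputError(f"{path} is not a single-channel depth image")
        if depth.dtype not in (np.uint16, np.uint8):
            raise InputError(f"{path} has unsupported depth dtype {depth.dtype}")
    depth = np.asarray(depth)
    if depth.ndim != 2:
        raise InputError(f"depth map must be 2-D, got shape {depth.shape}")
    if np.any(depth < 0):
        raise InputError("depth values must be non-negative")
    return depth


def read_intrinsics(path: str | Path) -> CameraIntrinsics:
    """Load fx, fy, cx, cy (and optional depth_scale) from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    required = {"fx", "fy", "cx", "cy"}
    missing = sorted(required - set(data))
    if missing:
        raise InputError(f"intrinsics file {path} missing keys: {', '.join(missing)}")
    return CameraIntrinsics(
        fx=float(data["fx"]),
        fy=float(data["fy"]),
        cx=float(data["cx"]),
        cy=float(data["cy"]),
        depth_scale=float(data.get("depth_scale", 0.001)),
    )


def check_depth_matches(rgb: np.ndarray, depth: np.ndarray) -> None:
    if rgb.shape[:2] != depth.shape:
        raise DimensionMismatchError(
            f"RGB shape {rgb.shape[:2]} does not match depth shape {depth.shape}"
        )


def _point3d_dict(p) -> dict | None:
    if p is None:
        return None
    return {"X": p.X, "Y": p.Y, "Z": p.Z, "valid": p.valid}


def detections_to_json(result: FruitSegmentation, report: RunReport | None = None) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "threshold": result.threshold.threshold,
        "threshold_method": result.threshold.method,
        "detections": [
            {
                "centroid_x": d.centroid_x,
                "centroid_y": d.centroid_y,
                "area": d.area,
                "bbox": list(d.bbox),
                "point3d": _point3d_dict(d.point3d),
            }
            for d in result.detections
        ],
        "report": report.to_dict() if report else None,
    }


def grip_to_json(result: BranchSegmentation, report: RunReport | None = None) -> dict:
    g = result.grip
    return {
        "schema_version": SCHEMA_VERSION,
        "grip": {
            "x": g.x,
            "y": g.y,
            "on_centroid": g.on_centroid,
            "depth": g.depth,
            "point3d": _point3d_dict(g.point3d),
        },
        "bbox_height": result.region.bbox_height,
        "report": report.to_dict() if report else None,
    }


def write_json(data: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def _stage_to_uint8(value) -> np.ndarray | None:
    if isinstance(value, FeatureChannel):
        return value.as_8bit()
    arr = np.asarray(value) if isinstance(value, np.ndarray) else None
    if arr is None:
        return None
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    if arr.ndim == 2 and arr.dtype == np.uint8:
        return arr
    return None


def write_debug_images(intermediates: dict, debug_dir: str | Path) -> list[Path]:
    """Write each renderable pipeline intermediate as an 8-bit PNG."""
    debug_dir = Path(debug_dir)
    debug_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, (name, value) in enumerate(intermediates.items()):
        img = _stage_to_uint8(value)
        if img is None:
            continue
        out = debug_dir / f"{i:02d}_{name}.png"
        iio.imwrite(out, img)
        written.append(out)
    return written


def _draw_cross(canvas: np.ndarray, x: int, y: int, color=(255, 255, 0), arm: int = 6) -> None:
    h, w = canvas.shape[:2]
    y0, y1 = max(0, y - arm), min(h, y + arm + 1)
    x0, x1 = max(0, x - arm), min(w, x + arm + 1)
    if 0 <= x < w:
        canvas[y0:y1, x] = color
    if 0 <= y < h:
        canvas[y, x0:x1] = color


def write_fruit_overlay(rgb: np.ndarray, detections: list[FruitDetection], path: str | Path) -> None:
    """Annotate detected centroids on a copy of the input image."""
    canvas = np.asarray(rgb).copy()
    for det in detections:
        _draw_cross(canvas, int(round(det.centroid_x)), int(round(det.centroid_y)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), canvas)


def write_grip_overlay(rgb: np.ndarray, grip: GripPoint, path: str | Path) -> None:
    """Annotate the grip point on a copy of the input image."""
    canvas = np.asarray(rgb).copy()
    _draw_cross(canvas, grip.x, grip.y, color=(0, 255, 255), arm=8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), canvas)
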