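"""Fruit segmentation and centroid localization from the fused feature image.

The fused feature image of a wolfberry scene is bimodal: a tall background
mode (foliage, branches, sky) and a smaller high-grayscale mode from the red
fruit.  Segmentation proceeds by valley thresholding of the 8-bit grayscale
histogram, a morphological opening to knock out small noise blobs, and a
connected-component area filter that drops regions of fewer than
``min_area`` (default 100) pixels.  Each surviving component yields a
detection whose centroid is the first moment (mean pixel coordinate) of its
member pixels; with a depth map and camera intrinsics the centroid is
back-projected to camera-frame 3D coordinates through the pinhole model.

Coordinate convention throughout: x = column index, y = row index, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .color_spaces import FeatureChannel, extract_feature_channel, rescale_to_8bit
from .wavelet_fusion import FusionWeights, fuse_feature_images

__all__ = [
    "GrayHistogram",
    "ThresholdResult",
    "FruitDetection",
    "CameraIntrinsics",
    "Point3D",
    "FruitSegmentation",
    "compute_histogram",
    "valley_threshold",
    "binarize",
    "morphological_open",
    "area_filter",
    "fruit_centroids",
    "pixel_to_3d",
    "segment_fruits",
]

#: moving-average window used to smooth the histogram before peak search
HISTOGRAM_SMOOTHING_WIDTH = 5


@dataclass
class GrayHistogram:
    """256-bin grayscale histogram of an 8-bit image."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (256,):
            raise ValueError("histogram must have exactly 256 bins")
        if int(self.counts.sum()) != self.total:
            raise ValueError("histogram counts do not sum to the stated total")


@dataclass(frozen=True)
class ThresholdResult:
    """A chosen binarization threshold plus the method that produced it."""

    threshold: int
    method: str  # "valley" or "otsu_fallback"


@dataclass
class FruitDetection:
    """One segmented fruit: centroid, pixel area, bounding box, optional 3D."""

    centroid_x: float
    centroid_y: float
    area: int
    bbox: tuple[int, int, int, int]  # (min_x, min_y, max_x, max_y), inclusive
    point3d: "Point3D | None" = None


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera parameters; depth_scale converts depth units to meters."""

    fx: float
    fy: float
    cx: float
    cy: float
    depth_scale: float = 0.001

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


@dataclass(frozen=True)
class Point3D:
    """Camera-frame 3D point in meters; ``valid`` is False for missing depth."""

    X: float
    Y: float
    Z: float
    valid: bool = True


@dataclass
class FruitSegmentation:
    """Full result of the fruit pipeline with all intermediates retrievable."""

    detections: list[FruitDetection]
    threshold: ThresholdResult
    intermediates: dict = field(default_factory=dict)


def compute_histogram(image8: np.ndarray) -> GrayHistogram:
    """Histogram of an 8-bit (integer-valued, 0–255) image."""
    image8 = np.asarray(image8)
    if image8.size == 0:
        raise ValueError("cannot histogram an empty image")
    values = np.rint(image8).astype(np.int64).ravel()
    if values.min() < 0 or values.max() > 255:
        raise ValueError("histogram input must lie in [0, 255]")
    counts = np.bincount(values, minlength=256)
    return GrayHistogram(counts=counts, total=int(values.size))


def _smooth_counts(counts: np.ndarray, width: int = HISTOGRAM_SMOOTHING_WIDTH) -> np.ndarray:
    kernel = np.ones(width) / width
    # reflect padding so boundary bins keep full support
    padded = np.pad(counts.astype(float), width // 2, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def valley_threshold(hist: GrayHistogram) -> ThresholdResult:
    """Pick the threshold at the histogram valley between the two main peaks.

    The histogram is smoothed with a short moving average, the two highest
    local maxima are located, and the threshold is the minimum-count bin
    strictly between them (a plateau of equal minima resolves to its
    midpoint).  When fewer than two peaks exist — e.g. a unimodal histogram,
    or the fruit mode submerged at low fruit counts — the method falls back
    to the variance-maximizing (Otsu) split and flags it.
    """
    if hist.total == 0:
        raise ValueError("cannot threshold an empty histogram")
    smoothed = _smooth_counts(hist.counts)
    # pad so maxima at bins 0 / 255 are still detected as peaks
    padded = np.concatenate(([-1.0], smoothed, [-1.0]))
    peaks, props = find_peaks(padded, height=0)
    peaks = peaks - 1
    if len(peaks) >= 2:
        heights = props["peak_heights"]
        top_two = peaks[np.argsort(heights)[-2:]]
        left, right = int(top_two.min()), int(top_two.max())
        if right - left > 1:
            between = hist.counts[left + 1 : right]
            min_count = between.min()
            min_bins = np.flatnonzero(between == min_count) + left + 1
            # midpoint of a flat minimum plateau
            threshold = int(round((min_bins[0] + min_bins[-1]) / 2))
            return ThresholdResult(threshold=threshold, method="valley")
    # fallback: variance-maximizing split over the populated range
    lo = int(np.flatnonzero(hist.counts)[0])
    hi = int(np.flatnonzero(hist.counts)[-1])
    if lo == hi:
        return ThresholdResult(threshold=lo, method="otsu_fallback")
    threshold = int(threshold_otsu(hist=(hist.counts.astype(float), np.arange(256.0))))
    return ThresholdResult(threshold=threshold, method="otsu_fallback")


def binarize(image8: np.ndarray, threshold: int, bright_foreground: bool = True) -> np.ndarray:
    """Threshold an 8-bit image into a boolean mask.

    Fruit grayscale sits above the background in the fused image, so the
    default takes values strictly greater than the threshold as foreground;
    ``bright_foreground=False`` flips the polarity.
    """
    image8 = np.asarray(image8)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return image8 > threshold if bright_foreground else image8 < threshold


def morphological_open(mask: np.ndarray, kernel: np.ndarray | int = 3) -> np.ndarray:
    """Binary opening (erosion then dilation) with a square or given kernel."""
    mask = np.asarray(mask, dtype=bool)
    if np.isscalar(kernel):
        kernel = np.ones((int(kernel), int(kernel)), dtype=bool)
    return ndi.binary_opening(mask, structure=np.asarray(kernel, dtype=bool))


def area_filter(mask: np.ndarray, min_area: int = 100) -> np.ndarray:
    """Remove 8-connected components with area strictly below ``min_area``.

    A component of exactly ``min_area`` pixels survives.
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def fruit_centroids(mask: np.ndarray) -> list[FruitDetection]:
    """One detection per 8-connected component; centroid is the first moment."""
    mask = np.asarray(mask, dtype=bool)
    labels = label(mask, connectivity=2)
    detections = []
    for region in regionprops(labels):
        cy, cx = region.centroid  # (row, col) mean of member pixels
        min_row, min_col, max_row, max_col = region.bbox  # half-open
        detections.append(
            FruitDetection(
                centroid_x=float(cx),
                centroid_y=float(cy),
                area=int(region.area),
                bbox=(int(min_col), int(min_row), int(max_col) - 1, int(max_row) - 1),
            )
        )
    return detections


def pixel_to_3d(x: float, y: float, depth_value: float, intr: CameraIntrinsics) -> Point3D:
    """Pinhole back-projection of a pixel with a depth reading.

    Z = depth * depth_scale, X = (x - cx) Z / fx, Y = (y - cy) Z / fy.
    A zero or negative depth yields an invalid point rather than an error.
    """
    if depth_value is None or not np.isfinite(depth_value) or depth_value <= 0:
        return Point3D(0.0, 0.0, 0.0, valid=False)
    Z = float(depth_value) * intr.depth_scale
    X = (float(x) - intr.cx) * Z / intr.fx
    Y = (float(y) - intr.cy) * Z / intr.fy
    return Point3D(X, Y, Z, valid=True)


def _depth_at(depth: np.ndarray, x: float, y: float) -> float:
    row = int(np.clip(round(y), 0, depth.shape[0] - 1))
    col = int(np.clip(round(x), 0, depth.shape[1] - 1))
    return float(depth[row, col])


def segment_fruits(
    rgb: np.ndarray,
    depth: np.ndarray | None = None,
    intrinsics: CameraIntrinsics | None = None,
    *,
    weights: FusionWeights = FusionWeights(),
    levels: int = 3,
    wavelet: str = "db2",
    open_kernel: int = 3,
    min_area: int = 100,
    bright_foreground: bool = True,
    channel: str = "fused",
) -> FruitSegmentation:
    """Run the full fruit segmentation pipeline on an RGB image.

    ``channel`` selects the feature image to segment: ``"fused"`` (default)
    runs the wavelet fusion of the a* and I planes; ``"a_channel"`` or
    ``"i_channel"`` segments a single plane, which is how the single-feature
    baselines are evaluated.

    Every stage's intermediate is stored under ``result.intermediates`` for
    debugging and export.
    """
    chan_a = extract_feature_channel(rgb, "a_channel")
    chan_i = extract_feature_channel(rgb, "i_channel")
    if channel == "fused":
        feature = fuse_feature_images(chan_a, chan_i, weights, levels=levels, wavelet=wavelet)
    elif channel == "a_channel":
        feature = chan_a
    elif channel == "i_channel":
        feature = chan_i
    else:
        raise ValueError(f"unknown channel selector {channel!r}")

    image8 = rescale_to_8bit(feature.values)
    hist = compute_histogram(image8)
    thr = valley_threshold(hist)
    mask_raw = binarize(image8, thr.threshold, bright_foreground=bright_foreground)
    mask_open = morphological_open(mask_raw, open_kernel)
    mask_final = area_filter(mask_open, min_area=min_area)
    detections = fruit_centroids(mask_final)

    if depth is not None and intrinsics is not None:
        depth = np.asarray(depth)
        if depth.shape != mask_final.shape:
            raise ValueError(
                f"depth map shape {depth.shape} does not match image shape {mask_final.shape}"
            )
        for det in detections:
            d = _depth_at(depth, det.centroid_x, det.centroid_y)
            det.point3d = pixel_to_3d(det.centroid_x, det.centroid_y, d, intrinsics)

    return FruitSegmentation(
        detections=detections,
        threshold=thr,
        intermediates={
            "a_channel": chan_a,
            "i_channel": chan_i,
            "feature": feature,
            "feature_8bit": image8,
            "histogram": hist,
            "mask_raw": mask_raw,
            "mask_open": mask_open,
            "mask_final": mask_final,
        },
    )
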