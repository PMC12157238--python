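"""Branch segmentation and gripping-point localization.

Wolfberry branches are chromatically close to the background, so the fruit
pipeline's bimodal thresholding does not isolate them.  Instead the scene is
clustered by color: every pixel's Lab vector is partitioned with K-means
(Lloyd's algorithm, K = 8 by default), the clustered image is rendered as a
K-level grayscale image, and valley thresholding of that histogram selects
the dark (branch-like) level group.  Because branches are long continuous
regions while fruit and noise blobs are compact, the component with the
tallest bounding rectangle is kept, the mask is cleaned with a size-3 median
filter and a 2x2 morphological opening, the tallest component is re-selected,
and the gripping point is computed: the mask centroid if it lies on the
branch, otherwise the branch pixel nearest to the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .color_spaces import FeatureChannel, rgb_to_lab
from .fruit_pipeline import (
    CameraIntrinsics,
    Point3D,
    _depth_at,
    compute_histogram,
    pixel_to_3d,
    valley_threshold,
)

__all__ = [
    "ClusterModel",
    "BranchRegion",
    "GripPoint",
    "BranchSegmentation",
    "NoRegionError",
    "kmeans_cluster",
    "cluster_to_gray",
    "threshold_clusters",
    "longest_region",
    "median_filter",
    "locate_grip_point",
    "segment_branch",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class NoRegionError(RuntimeError):
    """Raised when no candidate branch region exists in the mask."""


@dataclass
class ClusterModel:
    """Converged K-means state over an H×W×d feature image."""

    k: int
    centers: np.ndarray  # (k, d)
    labels: np.ndarray  # (H, W) ints in [0, k)
    inertia: float
    n_iter: int
    inertia_history: list[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class BranchRegion:
    """A single connected candidate branch component."""

    mask: np.ndarray
    bbox_height: int
    centroid: tuple[float, float]  # (x, y)


@dataclass
class GripPoint:
    """Pixel-level grasp target on the segmented branch."""

    x: int
    y: int
    on_centroid: bool
    depth: float | None = None
    point3d: Point3D | None = None


@dataclass
class BranchSegmentation:
    """Full branch-pipeline result with retrievable intermediates."""

    grip: GripPoint
    region: BranchRegion
    intermediates: dict = field(default_factory=dict)


def kmeans_cluster(
    features: np.ndarray,
    k: int = 8,
    seed: int | np.random.Generator = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterModel:
    """Lloyd's algorithm over the pixels of an H×W×d feature image.

    Centers are initialized by sampling ``k`` distinct pixel positions
    uniformly at random.  Each iteration assigns every pixel to its nearest
    center (Euclidean distance) and replaces each center by the mean of its
    members; a cluster left empty is re-seeded from the point currently
    farthest from its assigned center.  Iteration stops when assignments no
    longer change, when every center moves less than ``tol``, or after
    ``max_iter`` iterations.  The within-cluster sum of squared distances
    (inertia) is recorded after every assignment step.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 2:
        features = features[..., None]
    if features.ndim != 3:
        raise ValueError("features must be an HxW or HxWxd image")
    h, w, d = features.shape
    n = h * w
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of pixels ({n})")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    points = features.reshape(n, d)
    init_idx = rng.choice(n, size=k, replace=False)
    centers = points[init_idx].copy()

    labels = np.full(n, -1, dtype=np.int32)
    inertia_history: list[float] = []
    inertia = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # squared distances to every center, (n, k)
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1).astype(np.int32)
        member_d2 = d2[np.arange(n), new_labels]
        # re-seed empty clusters from the farthest point
        counts = np.bincount(new_labels, minlength=k)
        claim = member_d2.copy()
        for empty in np.flatnonzero(counts == 0):
            far = int(np.argmax(claim))
            centers[empty] = points[far]
            new_labels[far] = empty
            member_d2[far] = 0.0
            claim[far] = -np.inf  # point is spoken for; pick a fresh one next
        counts = np.bincount(new_labels, minlength=k)
        inertia = float(member_d2.sum())
        inertia_history.append(inertia)
        unchanged = np.array_equal(new_labels, labels)
        labels = new_labels
        # mean update
        new_centers = np.zeros_like(centers)
        for j in range(d):
            sums = np.bincount(labels, weights=points[:, j], minlength=k)
            new_centers[:, j] = sums / counts
        shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        if unchanged or shift < tol:
            converged = True
            break

    return ClusterModel(
        k=k,
        centers=centers,
        labels=labels.reshape(h, w),
        inertia=inertia,
        n_iter=n_iter,
        inertia_history=inertia_history,
        converged=converged,
    )


def cluster_to_gray(model: ClusterModel) -> FeatureChannel:
    """Render the clustered image as a K-level grayscale image.

    Every pixel is replaced by the luminance of its cluster center — the L
    component of the center's Lab vector, mapped from the nominal [0, 100]
    lightness range onto [0, 255].  (For feature spaces without an explicit
    lightness axis the mean of the center's components is used.)
    """
    if model.centers.shape[1] >= 3:
        luminance = model.centers[:, 0]
        raw = np.clip(luminance, 0.0, 100.0) * 2.55
    else:
        luminance = model.centers.mean(axis=1)
        lo, hi = luminance.min(), luminance.max()
        raw = (
            np.zeros_like(luminance)
            if hi <= lo
            else (luminance - lo) * (255.0 / (hi - lo))
        )
    # distinct centers must land on distinct levels even when their
    # luminances round to the same bin; identical centers share a level
    order = sorted(range(model.k), key=lambda j: (raw[j], tuple(model.centers[j])))
    levels = np.empty(model.k)
    prev_level = None
    prev_center = None
    for j in order:
        level = float(np.rint(raw[j]))
        if prev_center is not None and np.array_equal(model.centers[j], prev_center):
            level = prev_level
        elif prev_level is not None and level <= prev_level:
            level = prev_level + 1.0
        levels[j] = level
        prev_level, prev_center = level, model.centers[j]
    gray = np.clip(levels, 0.0, 255.0)[model.labels]
    return FeatureChannel(values=gray, source="cluster_gray", display_range=(0.0, 255.0))


def threshold_clusters(gray: FeatureChannel, dark_foreground: bool = True) -> np.ndarray:
    """Binarize the K-level cluster image by valley thresholding.

    The K-level histogram is a set of spikes; the valley between its two
    dominant spikes separates the bright background group (foliage, sky)
    from the dark group that contains the branch.  ``dark_foreground=True``
    (default) keeps the dark side.  Because thresholding acts on the K
    rendered levels, whole clusters are kept or dropped — no cluster is ever
    split.
    """
    image8 = np.rint(np.clip(gray.values, 0, 255)).astype(np.uint8)
    hist = compute_histogram(image8)
    thr = valley_threshold(hist)
    if dark_foreground:
        return image8 < thr.threshold
    return image8 > thr.threshold


def longest_region(mask: np.ndarray) -> BranchRegion:
    """Select the component with the tallest bounding rectangle.

    "Longest" is measured as the row extent (height) of each component's
    bounding box, matching the idea that a branch is a long continuous
    region.  Ties resolve to the larger area, then to the smaller top-row
    index.  Note this ranking favors vertically extended regions; a purely
    horizontal branch would be mis-ranked.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        raise NoRegionError("mask contains no connected component")
    slices = ndi.find_objects(labels)
    best = None
    for idx, sl in enumerate(slices, start=1):
        height = sl[0].stop - sl[0].start
        area = int((labels[sl] == idx).sum())
        key = (height, area, -sl[0].start)
        if best is None or key > best[0]:
            best = (key, idx, sl)
    _, idx, sl = best
    component = labels == idx
    ys, xs = np.nonzero(component)
    centroid = (float(xs.mean()), float(ys.mean()))
    return BranchRegion(mask=component, bbox_height=int(sl[0].stop - sl[0].start), centroid=centroid)


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with symmetric border extension.

    Each pixel is replaced by the median of its ``window``×``window``
    neighborhood.  On a binary mask this removes isolated impulse pixels.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("median filter window must be an odd integer >= 3")
    image = np.asarray(image)
    if image.dtype == bool:
        filtered = ndi.median_filter(image.astype(np.uint8), size=window, mode="reflect")
        return filtered.astype(bool)
    return ndi.median_filter(image, size=window, mode="reflect")


def locate_grip_point(
    region: BranchRegion,
    depth: np.ndarray | None = None,
    intrinsics: CameraIntrinsics | None = None,
) -> GripPoint:
    """Compute the grasp target for a branch region.

    The mask centroid, rounded to the nearest pixel, is the grip point when
    it falls on the branch; otherwise the foreground pixel closest (Euclidean
    distance) to the unrounded centroid is chosen, with ties broken by the
    smaller row then the smaller column.
    """
    mask = np.asarray(region.mask, dtype=bool)
    if not mask.any():
        raise NoRegionError("branch region is empty")
    cx, cy = region.centroid
    px = int(np.floor(cx + 0.5))
    py = int(np.floor(cy + 0.5))
    h, w = mask.shape
    if 0 <= py < h and 0 <= px < w and mask[py, px]:
        grip = GripPoint(x=px, y=py, on_centroid=True)
    else:
        ys, xs = np.nonzero(mask)
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        # stable tie-break: nonzero() yields row-major order (smaller y, then x)
        best = int(np.argmin(d2))
        grip = GripPoint(x=int(xs[best]), y=int(ys[best]), on_centroid=False)
    if depth is not None:
        grip.depth = _depth_at(np.asarray(depth), grip.x, grip.y)
        if intrinsics is not None:
            grip.point3d = pixel_to_3d(grip.x, grip.y, grip.depth, intrinsics)
    return grip


def segment_branch(
    rgb: np.ndarray,
    depth: np.ndarray | None = None,
    intrinsics: CameraIntrinsics | None = None,
    *,
    k: int = 8,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
    feature_space: str = "lab",
    dark_foreground: bool = True,
    median_window: int = 3,
    open_kernel: int = 2,
) -> BranchSegmentation:
    """Run the full branch localization pipeline on an RGB image.

    ``feature_space`` selects the clustering features: ``"lab"`` (default)
    uses the full (L, a*, b*) vector per pixel; ``"ab"`` uses the chroma
    pair only.
    """
    lab = rgb_to_lab(rgb)
    if feature_space == "lab":
        features = lab
    elif feature_space == "ab":
        features = lab[..., 1:]
    else:
        raise ValueError(f"unknown feature space {feature_space!r}")

    model = kmeans_cluster(features, k=k, seed=seed, max_iter=max_iter, tol=tol)
    gray = cluster_to_gray(model)
    mask_clusters = threshold_clusters(gray, dark_foreground=dark_foreground)
    region_initial = longest_region(mask_clusters)
    mask_median = median_filter(region_initial.mask, window=median_window)
    structure = np.ones((open_kernel, open_kernel), dtype=bool)
    mask_open = ndi.binary_opening(mask_median, structure=structure)
    region = longest_region(mask_open)
    grip = locate_grip_point(region, depth=depth, intrinsics=intrinsics)
    return BranchSegmentation(
        grip=grip,
        region=region,
        intermediates={
            "cluster_model": model,
            "cluster_gray": gray,
            "mask_clusters": mask_clusters,
            "region_initial": region_initial,
            "mask_median": mask_median,
            "mask_open": mask_open,
        },
    )
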