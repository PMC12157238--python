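"""Seeded synthetic orchard scenes with ground truth.

No wolfberry field imagery ships with this package, so every pipeline stage
is exercised on synthetic scenes that emulate the acquisition conditions the
method targets: red elliptical fruits on a green foliage background, an
optional elongated brown branch, a linear illumination gradient (the
front-lit / backlit / side-lit / cloudy regimes), partial occlusion of
fruits by foliage-colored patches, and salt-and-pepper impulse noise.
Matching 16-bit depth maps place fruit and branch at a 20–30 cm working
distance (200–300 mm) against a farther background.

Each scene is fully determined by a single integer seed and carries ground
truth recorded before illumination and noise are applied: per-fruit masks
and centroids, the branch mask and its analytic midline, and the depth map.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .color_spaces import extract_feature_channel

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "Scene",
    "PlacementError",
    "generate_scene",
    "scene_battery",
    "ILLUMINATION_PRESETS",
]


class PlacementError(RuntimeError):
    """Raised when the requested fruits cannot be placed without overlap."""


#: analogues of the field lighting regimes: (gradient angle deg, strength)
ILLUMINATION_PRESETS = {
    "front_lit": (90.0, 0.10),
    "backlit": (270.0, 0.50),
    "side_lit": (0.0, 0.35),
    "cloudy": (45.0, 0.05),
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Colors are RGB triples of the un-shaded object surfaces; the
    illumination gradient multiplies all channels by a factor falling from 1
    to ``1 - illumination_strength`` along ``illumination_angle_deg``.
    ``occlusion_fraction`` is the share of each fruit's pixels hidden behind
    foliage-colored patches; ``impulse_noise_rate`` is the fraction of
    pixels replaced by salt or pepper values.
    """

    width: int = 640
    height: int = 480
    n_fruits: int = 6
    fruit_radius_range: tuple[float, float] = (12.0, 22.0)
    fruit_color: tuple[int, int, int] = (200, 30, 40)
    foliage_color: tuple[int, int, int] = (60, 115, 45)
    branch_color: tuple[int, int, int] = (90, 40, 30)
    sky_color: tuple[int, int, int] = (190, 205, 225)
    color_jitter: float = 4.0
    sky_fraction: float = 0.0
    branch_present: bool = False
    branch_width: float = 12.0
    branch_angle_deg: float = 8.0
    branch_curvature: float = 20.0
    illumination_angle_deg: float = 0.0
    illumination_strength: float = 0.0
    texture_strength: float = 0.0
    occlusion_fraction: float = 0.0
    impulse_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8x8 pixels")
        if self.n_fruits < 0:
            raise ValueError("n_fruits must be non-negative")
        lo, hi = self.fruit_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("fruit_radius_range must be positive and ordered")
        for name in ("illumination_strength", "texture_strength",
                     "occlusion_fraction", "impulse_noise_rate", "sky_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-scene ground truth, recorded before illumination and noise."""

    fruit_centroids: list[tuple[float, float]]  # (x, y)
    fruit_masks: list[np.ndarray]
    branch_mask: np.ndarray | None
    branch_midline: np.ndarray | None  # (N, 2) array of (x, y)
    depth: np.ndarray  # uint16 depth units (mm)


@dataclass
class Scene:
    """A generated scene: image, depth, ground truth and the spec used."""

    spec: SceneSpec
    rgb: np.ndarray
    depth: np.ndarray
    truth: GroundTruth


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], cells: int = 6) -> np.ndarray:
    """Smooth random field in [0, 1] from upsampled low-resolution noise."""
    coarse = rng.random((cells, cells))
    zoom = (shape[0] / cells, shape[1] / cells)
    fine = ndi.zoom(coarse, zoom, order=3, mode="nearest")[: shape[0], : shape[1]]
    lo, hi = fine.min(), fine.max()
    return (fine - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _ellipse_coverage(h: int, w: int, cx: float, cy: float, rx: float, ry: float,
                      theta: float, supersample: int = 2) -> np.ndarray:
    """Anti-aliased coverage (0..1) of a rotated ellipse, local-patch only."""
    pad = int(np.ceil(max(rx, ry))) + 2
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    cov = np.zeros((h, w))
    if x0 >= x1 or y0 >= y1:
        return cov
    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5
    ys = np.arange(y0, y1)
    xs = np.arange(x0, x1)
    acc = np.zeros((y1 - y0, x1 - x0))
    ct, st = np.cos(theta), np.sin(theta)
    for oy in offs:
        for ox in offs:
            yy = ys[:, None] + oy - cy
            xx = xs[None, :] + ox - cx
            u = (xx * ct + yy * st) / rx
            v = (-xx * st + yy * ct) / ry
            acc += (u * u + v * v) <= 1.0
    cov[y0:y1, x0:x1] = acc / (s * s)
    return cov


def _branch_midline(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Analytic branch midline as an (H, 2) polyline of (x, y) points."""
    h, w = spec.height, spec.width
    ys = np.arange(h, dtype=float)
    slope = np.tan(np.deg2rad(spec.branch_angle_deg))
    xc = w / 2 + rng.uniform(-w / 8, w / 8)
    xs = xc + slope * (ys - h / 2) + spec.branch_curvature * np.sin(np.pi * ys / h)
    xs = np.clip(xs, spec.branch_width, w - 1 - spec.branch_width)
    return np.stack([xs, ys], axis=1)


def _check_color_contract(spec: SceneSpec) -> None:
    # precondition of the whole method: fruit must sit on the red side of
    # the a* axis relative to foliage
    def a_star(color):
        img = np.array(color, dtype=np.uint8).reshape(1, 1, 3)
        return float(extract_feature_channel(img, "a_channel").values[0, 0])

    if not a_star(spec.fruit_color) > a_star(spec.foliage_color):
        raise ValueError(
            "scene colors violate the a*(fruit) > a*(foliage) contract the "
            "segmentation method requires"
        )


def generate_scene(spec: SceneSpec) -> Scene:
    """Render one deterministic scene from its spec.

    Raises
    ------
    PlacementError
        If the requested number of fruits cannot be placed without overlap
        after a bounded number of retries.
    """
    _check_color_contract(spec)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.broadcast_to(np.asarray(spec.foliage_color, dtype=float), (h, w, 3)).copy()

    if spec.texture_strength > 0:
        shade = 1.0 + spec.texture_strength * (2.0 * _smooth_field(rng, (h, w)) - 1.0)
        img *= shade[..., None]

    sky_rows = int(round(spec.sky_fraction * h))
    if sky_rows > 0:
        img[:sky_rows] = np.asarray(spec.sky_color, dtype=float)

    depth = np.zeros((h, w), dtype=float)
    depth_bg = 900.0 + 400.0 * (2.0 * _smooth_field(rng, (h, w)) - 1.0) * 0.75
    depth[:] = np.clip(depth_bg, 500.0, 1500.0)

    # --- branch -----------------------------------------------------------
    branch_mask = None
    midline = None
    if spec.branch_present:
        midline = _branch_midline(spec, rng)
        xs_line = midline[:, 0]
        cols = np.arange(w, dtype=float)
        dist = np.abs(cols[None, :] - xs_line[:, None])
        cov = np.clip(spec.branch_width / 2 + 0.5 - dist, 0.0, 1.0)
        branch_color = np.asarray(spec.branch_color, dtype=float)
        jitter = rng.normal(0.0, spec.color_jitter * 0.5, size=(h, w, 1))
        img = img * (1 - cov[..., None]) + (branch_color + jitter) * cov[..., None]
        branch_mask = cov >= 0.5
        branch_depth = rng.uniform(200.0, 260.0) + 40.0 * (np.arange(h) / h)
        depth = np.where(branch_mask, branch_depth[:, None], depth)

    # --- fruits -----------------------------------------------------------
    r_lo, r_hi = spec.fruit_radius_range
    placed: list[tuple[float, float, float]] = []  # (cx, cy, r)
    fruit_masks: list[np.ndarray] = []
    fruit_centroids: list[tuple[float, float]] = []
    fruit_params: list[tuple[float, float, float, float, float]] = []
    max_tries = 300 * max(spec.n_fruits, 1)
    tries = 0
    while len(placed) < spec.n_fruits:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {spec.n_fruits} fruits of radius {r_lo}-{r_hi} "
                f"in a {w}x{h} scene after {max_tries} attempts"
            )
        tries += 1
        r = rng.uniform(r_lo, r_hi)
        margin = r + 4
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(max(margin, sky_rows + margin), h - margin)
        if any(np.hypot(cx - px, cy - py) < r + pr + 6 for px, py, pr in placed):
            continue
        if midline is not None:
            y_idx = int(round(np.clip(cy, 0, h - 1)))
            lo_y = max(0, y_idx - int(r) - 2)
            hi_y = min(h, y_idx + int(r) + 3)
            if np.min(np.abs(midline[lo_y:hi_y, 0] - cx)) < r + spec.branch_width / 2 + 4:
                continue
        placed.append((cx, cy, r))

    fruit_color = np.asarray(spec.fruit_color, dtype=float)
    for cx, cy, r in placed:
        ry = r * rng.uniform(0.85, 1.15)
        theta = rng.uniform(0, np.pi)
        cov = _ellipse_coverage(h, w, cx, cy, r, ry, theta)
        jitter = rng.normal(0.0, spec.color_jitter, size=3)
        img = img * (1 - cov[..., None]) + (fruit_color + jitter) * cov[..., None]
        mask = cov >= 0.5
        ys, xs = np.nonzero(mask)
        fruit_masks.append(mask)
        fruit_centroids.append((float(xs.mean()), float(ys.mean())))
        fruit_params.append((cx, cy, r, ry, theta))
        fruit_depth = rng.uniform(200.0, 300.0)
        depth = np.where(mask, fruit_depth - 10.0 * cov, depth)

    depth_map = np.clip(np.rint(depth), 0, 65535).astype(np.uint16)
    truth = GroundTruth(
        fruit_centroids=fruit_centroids,
        fruit_masks=fruit_masks,
        branch_mask=branch_mask,
        branch_midline=midline,
        depth=depth_map,
    )

    # --- occlusion (after ground truth is frozen) -------------------------
    foliage = np.asarray(spec.foliage_color, dtype=float)
    if spec.occlusion_fraction > 0:
        for (cx, cy, r, ry, theta), mask in zip(fruit_params, fruit_masks):
            target = spec.occlusion_fraction * mask.sum()
            phi = rng.uniform(0, 2 * np.pi)
            bx = cx + r * np.cos(phi)
            by = cy + ry * np.sin(phi)
            lo_r, hi_r = 1.0, 2.5 * max(r, ry)
            for _ in range(18):  # bisection on occluder radius
                mid = 0.5 * (lo_r + hi_r)
                occ = _ellipse_coverage(h, w, bx, by, mid, mid * 0.8, phi) >= 0.5
                covered = np.logical_and(occ, mask).sum()
                if covered < target:
                    lo_r = mid
                else:
                    hi_r = mid
            occ = _ellipse_coverage(h, w, bx, by, hi_r, hi_r * 0.8, phi)
            img = img * (1 - occ[..., None]) + foliage * occ[..., None]

    # --- illumination gradient -------------------------------------------
    if spec.illumination_strength > 0:
        ang = np.deg2rad(spec.illumination_angle_deg)
        ux, uy = np.cos(ang), np.sin(ang)
        xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        proj = ux * xx + uy * yy
        lo, hi = proj.min(), proj.max()
        s = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
        img *= (1.0 - spec.illumination_strength * s)[..., None]

    # --- impulse noise ----------------------------------------------------
    if spec.impulse_noise_rate > 0:
        n_noise = int(round(spec.impulse_noise_rate * h * w))
        idx = rng.choice(h * w, size=n_noise, replace=False)
        values = np.where(rng.random(n_noise) < 0.5, 0.0, 255.0)
        flat = img.reshape(-1, 3)
        flat[idx] = values[:, None]
        img = flat.reshape(h, w, 3)

    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Scene(spec=spec, rgb=rgb, depth=depth_map, truth=truth)


def scene_battery(
    n_scenes: int,
    base_spec: SceneSpec,
    seed: int = 0,
    occlusion_levels: tuple[float, ...] = (0.0, 0.1, 0.25),
) -> list[Scene]:
    """Generate a deterministic battery spanning lighting and occlusion.

    Scenes cycle through the four illumination presets (front-lit, backlit,
    side-lit, cloudy analogues) crossed with the given occlusion levels;
    every scene gets its own child seed derived from ``seed``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    presets = list(ILLUMINATION_PRESETS.values())
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    scenes = []
    for i in range(n_scenes):
        angle, strength = presets[i % len(presets)]
        occ = occlusion_levels[(i // len(presets)) % len(occlusion_levels)]
        spec = dataclasses.replace(
            base_spec,
            illumination_angle_deg=angle,
            illumination_strength=strength,
            occlusion_fraction=occ,
            seed=int(scene_seeds[i]),
        )
        scenes.append(generate_scene(spec))
    return scenes
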