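"""Battery evaluation: recall and localization statistics on synthetic scenes.

This is the library behind the ``wolfvision eval`` command and the
reproduction script: it runs a pipeline over a scene battery and scores the
output against the generator's ground truth by greedy nearest-centroid
matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .branch_pipeline import NoRegionError, segment_branch
from .fruit_pipeline import segment_fruits
from .synthetic_scenes import Scene

__all__ = [
    "FruitBatteryResult",
    "BranchBatteryResult",
    "match_centroids",
    "evaluate_fruit_battery",
    "evaluate_branch_battery",
]


def match_centroids(
    detected: list[tuple[float, float]],
    truth: list[tuple[float, float]],
    max_dist: float = 5.0,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of detections to ground-truth centroids.

    Pairs are taken in increasing distance order; each detection and each
    truth point is used at most once, and pairs farther than ``max_dist``
    are discarded.  Returns (detected_idx, truth_idx, distance) triples.
    """
    if not detected or not truth:
        return []
    det = np.asarray(detected, dtype=float)
    tru = np.asarray(truth, dtype=float)
    dists = np.hypot(det[:, None, 0] - tru[None, :, 0], det[:, None, 1] - tru[None, :, 1])
    order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
    used_d, used_t, matches = set(), set(), []
    for di, ti in order:
        d = float(dists[di, ti])
        if d > max_dist:
            break
        if di in used_d or ti in used_t:
            continue
        used_d.add(int(di))
        used_t.add(int(ti))
        matches.append((int(di), int(ti), d))
    return matches


@dataclass
class FruitBatteryResult:
    n_scenes: int
    recall: float
    precision: float
    count_exact_rate: float
    mean_centroid_error: float
    max_centroid_error: float


def evaluate_fruit_battery(
    scenes: list[Scene],
    channel: str = "fused",
    match_dist: float = 5.0,
    **pipeline_kwargs,
) -> FruitBatteryResult:
    """Run the fruit pipeline over a battery and score it."""
    n_truth = n_detected = n_matched = n_count_exact = 0
    errors: list[float] = []
    for scene in scenes:
        result = segment_fruits(scene.rgb, channel=channel, **pipeline_kwargs)
        det = [(d.centroid_x, d.centroid_y) for d in result.detections]
        tru = scene.truth.fruit_centroids
        matches = match_centroids(det, tru, max_dist=match_dist)
        n_truth += len(tru)
        n_detected += len(det)
        n_matched += len(matches)
        if len(det) == len(tru):
            n_count_exact += 1
        errors.extend(m[2] for m in matches)
    return FruitBatteryResult(
        n_scenes=len(scenes),
        recall=n_matched / n_truth if n_truth else float("nan"),
        precision=n_matched / n_detected if n_detected else float("nan"),
        count_exact_rate=n_count_exact / len(scenes),
        mean_centroid_error=float(np.mean(errors)) if errors else float("nan"),
        max_centroid_error=float(np.max(errors)) if errors else float("nan"),
    )


@dataclass
class BranchBatteryResult:
    n_scenes: int
    grip_on_mask_rate: float
    grip_on_truth_rate: float
    inertia_monotone_rate: float
    failed_seeds: list[int]


def evaluate_branch_battery(scenes: list[Scene], **pipeline_kwargs) -> BranchBatteryResult:
    """Run the branch pipeline over a battery and score grip placement.

    ``grip_on_mask_rate`` checks the hard invariant that the grip point is a
    foreground pixel of the final segmented mask; ``grip_on_truth_rate``
    checks it against the generator's branch mask.  Scene seeds of failures
    are collected for reproduction.
    """
    n_on_mask = n_on_truth = n_monotone = 0
    failed: list[int] = []
    for scene in scenes:
        try:
            result = segment_branch(scene.rgb, seed=scene.spec.seed, **pipeline_kwargs)
        except NoRegionError:
            failed.append(scene.spec.seed)
            continue
        grip = result.grip
        if result.region.mask[grip.y, grip.x]:
            n_on_mask += 1
        hist = result.intermediates["cluster_model"].inertia_history
        if all(b <= a + 1e-6 for a, b in zip(hist, hist[1:])):
            n_monotone += 1
        on_truth = (
            scene.truth.branch_mask is not None
            and scene.truth.branch_mask[grip.y, grip.x]
        )
        if on_truth:
            n_on_truth += 1
        else:
            failed.append(scene.spec.seed)
    n = len(scenes)
    return BranchBatteryResult(
        n_scenes=n,
        grip_on_mask_rate=n_on_mask / n,
        grip_on_truth_rate=n_on_truth / n,
        inertia_monotone_rate=n_monotone / n,
        failed_seeds=failed,
    )
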