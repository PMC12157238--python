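# wolfvision

Recognition and localization of wolfberry (goji, *Lycium barbarum*) fruits
and branches for harvesting-robot vision, from RGB images with optional
depth maps.

Wolfberries are small, tender fruits that ripen bright red against green
foliage, and field images come with strong, uncontrolled illumination
(front-lit, backlit, side-lit, overcast) plus occlusion by leaves.
`wolfvision` implements a rule-based segmentation approach that needs no
training data:

- **Fruit segmentation by color-feature fusion.** Two chroma features
  separate red fruit from green background while staying comparatively
  insensitive to lighting: the *a\** axis of an Lab-style representation
  (green ↔ red) and the *I* axis of NTSC YIQ (cyan ↔ orange). Both planes
  are decomposed with a 3-level 2-D wavelet transform and fused pixel-wise
  — detail coefficients by maximum absolute value, approximation planes by
  the weighted average *C_f(p) = α·C_a(p) + β·C_l(p)* with α = β = 0.5 —
  then reconstructed. The fused image has a cleanly bimodal grayscale
  histogram; valley thresholding, a 3×3 morphological opening, and removal
  of connected regions under 100 px yield the fruit masks. Each fruit is
  localized by the first moment of its component,
  *x̄ = Σx/N, ȳ = Σy/N*, and back-projected to camera-frame 3D through the
  pinhole model *Z = d·s, X = (x−c_x)Z/f_x, Y = (y−c_y)Z/f_y*.
- **Branch localization by color clustering.** Branches are chromatically
  close to the background, so pixels are clustered in Lab space with
  K-means (Lloyd's algorithm, K = 8), the clustered image is rendered at K
  gray levels and valley-thresholded, and the component with the tallest
  bounding rectangle — branches are long continuous regions — is kept.
  After a size-3 median filter and a 2×2 opening, the gripping point for a
  robot end-effector is the mask centroid if it lies on the branch,
  otherwise the branch pixel nearest to it.
- **Synthetic scenes with ground truth.** A seeded generator renders
  orchard-like scenes (red elliptical fruits, green foliage, an elongated
  branch, illumination gradients, occlusion patches, impulse noise) with
  per-fruit masks and centroids, a branch mask and midline, and a matching
  depth map, so the whole pipeline is testable end to end.

## Worked example

```python
from wolfvision import (CameraIntrinsics, SceneSpec, generate_scene,
                        segment_branch, segment_fruits)

spec = SceneSpec(width=320, height=240, n_fruits=5,
                 illumination_strength=0.35, illumination_angle_deg=0.0,
                 occlusion_fraction=0.1, impulse_noise_rate=0.005, seed=3)
scene = generate_scene(spec)
intr = CameraIntrinsics(fx=460.0, fy=460.0, cx=160.0, cy=120.0)

result = segment_fruits(scene.rgb, scene.depth, intr)
print(f"threshold={result.threshold.threshold} ({result.threshold.method})")
for det in result.detections:
    p = det.point3d
    print(f"fruit at ({det.centroid_x:6.1f}, {det.centroid_y:6.1f}) px, "
          f"area {det.area:4d} -> ({p.X:+.3f}, {p.Y:+.3f}, {p.Z:.3f}) m")
```

prints

```
threshold=119 (valley)
fruit at ( 263.6,   45.0) px, area 1212 -> (+0.061, -0.044, 0.269) m
fruit at ( 217.2,   78.3) px, area  450 -> (+0.032, -0.024, 0.261) m
fruit at ( 249.4,  106.4) px, area  910 -> (+0.041, -0.006, 0.211) m
fruit at ( 129.5,  115.7) px, area 1034 -> (-0.018, -0.003, 0.276) m
fruit at ( 228.0,  163.6) px, area  714 -> (+0.031, +0.020, 0.210) m
```

The valley threshold at gray level 119 splits the fused image's bimodal
histogram; all five fruits (10 % occluded, under a side-light gradient) are
recovered, and each centroid is back-projected to meters in the camera
frame — the fruits sit at the 0.21–0.28 m working distance encoded in the
synthetic depth map. The branch pipeline works the same way:

```python
bspec = SceneSpec(width=320, height=240, n_fruits=3, branch_present=True,
                  illumination_strength=0.35, seed=11)
bscene = generate_scene(bspec)
grip = segment_branch(bscene.rgb, bscene.depth, intr, seed=11).grip
print(f"grip point ({grip.x}, {grip.y}), depth {grip.depth:.0f} mm")
# -> grip point (188, 118), depth 278 mm
```

## Command line

```bash
wolfvision synth --out scenes/ --n 4 --seed 7         # ground-truthed scenes
wolfvision segment-fruits --image rgb.png --depth depth.png \
    --intrinsics intr.yaml --out detections.json --debug-dir dbg/
wolfvision locate-branch --image rgb.png --out grip.json
wolfvision eval --pipeline fruit --channel i_channel --n 50
```

Exit codes: 0 success, 2 bad input, 3 nothing detected. `--debug-dir`
writes every intermediate stage image plus an annotated overlay.

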