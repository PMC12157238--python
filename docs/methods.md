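# Methods

## Color features

The fruit detector works on two chroma planes extracted per pixel from the
8-bit RGB input.

**Intensity-free Lab variant.** RGB is first chromaticity-normalized,
r = R/(R+G+B) (black pixels map to (0,0,0) so the map is total), then taken
to XYZ with the fixed matrix

    X   [0.433953 0.376219 0.289828] r
    Y = [0.212671 0.715160 0.072169] g
    Z   [0.017758 0.109477 0.872765] b

and compressed with f(t) = t^(1/3) for t > 0.008856, else 7.787·t + 16/116:
L* = 116·f(Y) − 16, a* = 500·(f(X) − f(Y)), b* = 200·(f(Y) − f(Z)).

Two deliberate deviations from textbook CIE Lab: the inputs are
chromaticities rather than linear-light tristimulus values, and f is
applied to X, Y, Z directly with **no reference-white division**. The first
makes every Lab plane invariant to multiplicative illumination changes —
the property the method leans on — and the second follows the formulas as
this variant defines them. A consequence worth knowing: because the X row
of the matrix sums to 1.1 while the Y row sums to 1.0, an achromatic pixel
has a* = 500·(f(1.1/3) − f(1/3)) ≈ 11.19, a constant offset rather than
zero; only differences in a* carry information. The standard sRGB/D65
conversion is available as `rgb_to_lab_d65` for comparison but is not used
by the pipelines.

**YIQ.** The NTSC matrix (Y = 0.2990R + 0.5870G + 0.1140B;
I = 0.5957R − 0.2745G − 0.3213B; Q = 0.2115R − 0.5226G + 0.3111B) is
applied to the **raw 0–255 values**. The I plane therefore scales with
illumination — which is exactly why the fused feature beats it on backlit
scenes — and an achromatic pixel has |I| ≤ 255·0.0001 = 0.0255 (the I row
sums to −0.0001).

## Wavelet fusion

Both planes are min–max rescaled (continuously, no rounding) to a common
[0, 255] range so the approximation average mixes commensurate magnitudes,
then decomposed to 3 levels with the orthogonal Daubechies `db2` wavelet and
symmetric boundary extension (PyWavelets `wavedec2`). Fusion rules:

- detail (high-frequency) coefficients: keep the input of larger absolute
  value, sign preserved; an exact tie goes to the a-channel pyramid;
- approximation (low-frequency) plane: α·A_a + β·A_i with α = β = 0.5.

`db2` was chosen as the shortest Daubechies wavelet beyond Haar: orthogonal
(so the unmodified round trip is the identity to ~1e−13, which the tests
pin at 1e−8) with one extra vanishing moment to keep smooth gradients out
of the detail bands. Wavelet, levels and weights are configurable.
Non-dyadic sizes are handled by PyWavelets' internal symmetric padding;
reconstruction is cropped back to the source shape.

## Fruit segmentation

The fused plane is rescaled to 8-bit (rounded, recorded `display_range`),
histogrammed into 256 bins and thresholded at the histogram valley: the
histogram is smoothed with a width-5 moving average (reflected at the ends
so boundary modes are still detected), the two highest local maxima are
found, and the threshold is the minimum-count raw bin strictly between
them, a tied plateau resolving to its midpoint. If fewer than two peaks
exist — a fruitless or low-contrast image — the method falls back to the
variance-maximizing (Otsu) split and flags `otsu_fallback` in the result
and the run report; the valley of a degenerate single-bin histogram is that
bin itself, so a perfectly uniform image yields an empty mask rather than a
spurious detection.

Foreground is `value > threshold` (fruit is the bright mode of the fused
image; the polarity is a config switch). A 3×3 opening removes impulse
noise; 8-connected components with **fewer than 100 pixels** are removed
(exactly 100 survives). Per-component centroids are the first moment of the
member pixels — x̄ = mean column, ȳ = mean row, 0-based, x = column —
verified in tests against a brute-force double loop. With a depth map and
intrinsics, the depth at the centroid's nearest integer pixel is
back-projected through the pinhole model; zero depth yields a point flagged
invalid instead of an error. No RGB–depth re-registration is attempted.

## Branch localization

Pixels are clustered with a from-scratch Lloyd K-means on the (L, a*, b*)
vectors (a chroma-only (a*, b*) option exists): seeded uniform sampling of
k distinct pixels as initial centers, nearest-center assignment, mean
update, stop when assignments are unchanged, every center moves < 1e−4, or
300 iterations elapse. An empty cluster is re-seeded from the point
currently farthest from its center (each reclaimed point is excluded from
subsequent claims, so even a constant image converges). Inertia is recorded
after every assignment and is non-increasing by construction; the tests
assert it on every battery run. K = 8 by default.

The clustered image is rendered at one gray level per cluster
(luminance = the center's L, mapped [0,100] → [0,255]; distinct centers
whose levels would collide after rounding are deterministically nudged
apart, while genuinely identical centers share a level). Valley
thresholding of this K-spike histogram separates the bright background
group (foliage, sky) from the dark group containing the branch; whole
clusters are kept or dropped, never split. The tallest-bounding-box
component is selected ("longest" = row extent, ties by larger area then
smaller top row — a deliberately literal rule that would mis-rank a purely
horizontal branch), cleaned with a size-3 median filter (symmetric borders;
exactly equal to the brute-force neighborhood-sort oracle) and a 2×2
opening, re-selected, and the grip point computed: the rounded centroid if
it is foreground, else the nearest foreground pixel to the unrounded
centroid (ties: smaller row, then column). The grip point is by
construction a pixel of the final mask.

## Synthetic scenes

The generator emulates the stated acquisition conditions: 640×480 default
frames, a 20–30 cm working distance (fruits and branch at 200–300 depth
units with 1 mm units; background 500–1500), fruits as anti-aliased
ellipses (default radius 12–22 px) at least 6 px apart, an optional curved
branch stroke crossing the frame near-vertically, and four illumination
analogues (front-lit 0.10, backlit 0.50, side-lit 0.35, cloudy 0.05
gradient strength) crossed with occlusion fractions {0, 0.1, 0.25} in
`scene_battery`. Occlusion paints foliage-colored patches over a measured
share of each fruit's pixels (bisected to the requested fraction); impulse
noise replaces a fraction of pixels with salt or pepper. Ground truth
(masks, centroids = exact mask moments, branch midline, depth) is frozen
before occlusion, illumination and noise are applied. Default object
colors — fruit (200, 30, 40), foliage (60, 115, 45), branch (90, 40, 30) —
were picked once to mirror ripe fruit on foliage with a dark branch; a
generation-time assertion enforces the method's precondition
a*(fruit) > a*(foliage).

What the generator does **not** model: specular highlights, maturity
variation (green/orange fruit), leaf-shaped occluders with their own
chromaticity spread, sensor noise correlated across channels, RGB–depth
misalignment, and adhered fruit clusters. Passing batteries therefore
demonstrate the internal consistency and the illumination/occlusion
robustness mechanism of the method, not field-grade accuracy; the
single-channel-versus-fused comparison in particular is a directional
result (the I channel degrades under gradients, the fused feature does
not), not a reproduction of field correctness percentages.

## Battery sizes and determinism

Test and reproduction batteries use 200 scenes of 320×240 px with 5 fruits
(3 plus a branch for the branch battery) and 0.5 % impulse noise — large
enough for stable rates, small enough that the whole suite runs in a few
minutes on one CPU. Every scene seed is derived from the battery seed;
identical seeds give bit-identical scenes and results. The acceptance
script spawns four independent sub-seeds (all < 2³¹) from `--seed` for its
four computations.

## Known limitations

- The valley threshold assumes a bimodal histogram; heavy fruit coverage or
  near-zero fruit coverage shifts it to the Otsu fallback, which is flagged
  but less principled.
- Bounding-box height as the "longest region" criterion fails for
  horizontal branches.
- The branch cluster is selected by dark-side thresholding of the rendered
  luminance levels; a branch brighter than the background (e.g., against
  dark soil) needs the polarity switch flipped.
- Centroid-based grip points can fall off thin, strongly curved branches;
  the nearest-pixel rule then picks a boundary pixel, which is valid but
  not medial.
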