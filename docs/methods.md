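# Methods note

## Model and assumptions

The matcher assumes rectified stereo: correspondences lie on the same image
row, with the right-image match of left pixel `(x, y)` at `(x - d, y)`,
`d >= 0`. Images are RGB in `[0, 1]`. Disparity maps carry an explicit
boolean validity mask; invalid entries hold the sentinel `+inf` (and are
written to PFM as `+inf`). Depth uses the pinhole model `Z = fx * b / d`
with no lens-distortion term — inputs are assumed already undistorted.

Processing per pair:

1. **Cost:** `C = alpha * min(TM, M) + (1 - alpha) * min(TG, G)`.
   `M` sums absolute per-channel RGB differences; `G` is the absolute
   difference of horizontal Sobel responses (3×3 kernel divided by 8,
   replicate border) computed on BT.601 grayscale. Where `x - d` leaves the
   frame the truncation values themselves are used, so out-of-frame costs
   equal the attainable maximum `alpha*TM + (1-alpha)*TG`.
2. **Aggregation:** each disparity slice is smoothed with a guided filter
   (radius `er`, regularizer `eps`) guided by the left image. The color
   variant inverts a per-window 3×3 covariance plus `eps*I` once and reuses
   it across slices. Box means use a count-correct shrinking-window filter
   (separable cumulative sums), so borders are true means, not padded ones.
3. **Selection:** winner-take-all argmin (ties go to the smaller
   disparity), then parabola sub-pixel refinement
   `delta = (C(d-1) - C(d+1)) / (2 (C(d-1) - 2 C(d) + C(d+1)))`, applied
   only where both neighbors are valid and the parabola is convex, clamped
   to ±0.5. A quadratic cost curve is recovered exactly (verified to
   1e-12); general curves are recovered to within the quadratic
   approximation error.
4. **Consistency:** a weighted median with bilateral weights
   `exp(-||p - j||^2 / sigma_g^2) * exp(-||I_p - I_j||^2 / sigma_m^2)`
   (the median is the smallest value whose cumulative weight reaches half
   the total); a left/right check `|d_l(p) - d_r(x - round(d_l(p)), y)| <=
   lr_tolerance`; glare rejection of pixels whose every channel is at or
   above `glare_threshold`; scanline filling with the minimum of the
   nearest valid disparities to the left and right (background preference —
   occlusions belong to the farther surface), with a nearest-valid-row
   column fallback for fully invalid rows; a final weighted median. The
   right-view map needed by the check is produced by mirroring both images
   horizontally, swapping their roles, matching, and mirroring back, which
   reuses the left-view matcher unchanged.
5. **Iteration:** from the previous frame's filled map, four per-pixel
   range masks are built by windowed min/max with stage-specific radii
   (`x1`: (er+br, er+2br), `y1`: (er+br, er+br), `x2`: (er, er+br),
   `y2`: (er, er)), expanded to `floor(min) - d_offset` /
   `ceil(max) + d_offset` and clipped to the global range. Costs are
   computed on the merged envelope of all four stages; entries outside a
   pixel's range are padded with the maximum attainable cost so dense
   slice filtering stays valid; the tightest stage (`y2`) gates final
   validity. With full-range masks this path is bitwise identical to the
   unmasked path (tested). Masks engage after `warmup_frames` and are
   dropped for a frame when the previous frame's inconsistency rate
   exceeds `cut_fallback_rate` (scene-cut fallback).

## Parameters (defaults and rationale)

| name | default | why |
|---|---|---|
| `alpha` | 0.1 | gradient evidence dominates; color is a weak tiebreaker robust to radiometric gain differences |
| `tm`, `tg` | 0.0824, 0.0078 | truncation ceilings on the [0,1] intensity scale; bound outlier influence at occlusions/glare |
| `er` | 7 | guided-filter radius; aggregation support ≈ 15×15 at full resolution |
| `br` | 7 | extra mask-stage radius margin beyond `er` |
| `eps` | 1e-4 | guided-filter regularizer on [0,1] images; small enough to preserve edges, large enough to avoid noise-fitted windows |
| `d_offset` | 2 | tolerated per-frame disparity drift, in levels |
| `sigma_g`, `sigma_m` | 9.0, 0.1 | spatial / range bandwidths of the weighted median (pixels, intensity units) |
| `median_radius` | 9 | weighted-median window radius |
| `glare_threshold` | 250/255 | near-saturated in 8-bit terms |
| `lr_tolerance` | 1.0 | one disparity level of left/right disagreement allowed |
| `warmup_frames` | 5 | unmasked frames before temporal masks engage |
| `d_min_global`, `d_max_global` | 0, 64 | global search range |
| `cut_fallback_rate` | 0.5 | inconsistency rate above which masks are deemed stale |

Tests and the acceptance script use fixture-scale values (`er=3`, `br=3`,
`median_radius=3`, `sigma_g=3.0`, `d_max_global=24`) chosen a priori so
filter windows stay small relative to the 24–56 pixel test images; no
value was tuned against any measured output.

The default camera (`fx=1024.09`, `fy=1023.89`, `cx=601.81`, `cy=508.13`,
baseline 4.35 mm, 1280×1024) is a representative calibrated stereo
endoscope rig; all geometry functions take an explicit `CameraModel`.

## Optics calculators

`rayleigh_resolution` uses the small-angle Rayleigh criterion
`d = Z * 1.22 * lambda / D` (an exact arcsin form is available via
`exact=True`; at endoscopic angles they agree to <1e-6 relative). It
errors when `1.22 lambda / D >= 1` (angle undefined).
`pixel_footprint` is thin-lens back-projection `t = t' * Z / f`.
`sensor_pixel_size` derives pitch from a sensor diagonal, aspect ratio and
column count. With the rounded pitch 3.84 µm the footprint at 5 cm is
41.56 µm; with the full-precision pitch 3.843 µm it is 41.59 µm — the CLI
prints the full-precision value.

## Synthetic generator: scope and limits

Scenes are piecewise or smooth integer disparity fields
(plane, slanted plane, height profile, step pyramid) textured with
band-limited noise, sinusoids, or low-contrast patterns. The right view is
a forward warp with z-buffer visibility: when several left pixels map to
one right pixel the largest disparity wins and the losers are marked
occluded, so the occlusion mask is exact by construction. Holes are filled
from the nearest claimed pixel. Each depth level gets a distinct brightness
gain so depth discontinuities coincide with image edges — the cue the
edge-aware aggregator relies on, and a property real endoscopy shares only
approximately. Glare is modeled as saturated discs painted in both views;
drift shifts the disparity field between frames. Everything is driven by
`numpy.random.default_rng(seed)` and is bitwise reproducible.

What the generator does **not** model: photometric asymmetry between views
beyond an optional gain, non-rigid tissue deformation, motion blur, smoke,
specular highlights with view-dependent position, or calibration error.
Accuracy numbers on these scenes are therefore an upper bound on real
endoscopic performance and validate the machinery, not the clinical claim.

## Numerical choices

- WTA ties break to the smaller disparity (deterministic argmin).
- The weighted median picks the smallest value whose cumulative weight
  reaches half the total weight — stable and deterministic under ties.
- Scanline filling ties (equal left/right candidates) resolve by the `min`
  itself; the fully-empty-row fallback takes the nearest valid row,
  ties toward the smaller row index.
- The box filter divides by the true clipped-window pixel count, so guided
  filtering is correct at borders without reflective padding.
- All arithmetic is float64; no randomness exists outside the generator.

## Verification problem sizes

Oracle equivalence tests run brute-force restatements at 64×64 (box mean),
16×16 (guided filter, tolerance 1e-8), and 32×32 (WTA, weighted median,
scanline fill, mask min/max). End-to-end accuracy uses 40×56 scenes with
24 disparity levels; sequence tests use 5-frame 32×40 clips. On these
sizes the full suite runs in well under a minute.

## Limitations

- The iterative masks assume temporal coherence; motion beyond
  `br + d_offset` per frame between mask construction and use can exclude
  the true disparity until the scene-cut fallback resets the range.
- Sub-pixel accuracy is bounded by the parabola model of the cost curve;
  strongly asymmetric minima bias the estimate within the ±0.5 clamp.
- The left/right check cannot flag symmetric failures (both views wrong in
  the same way), e.g. on large textureless regions.
- Benchmark-protocol numbers in the acceptance output are averages of
  published per-keyframe errors; the package does not ship the benchmark
  imagery itself.
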