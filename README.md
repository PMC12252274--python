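# iterstereo

Iterative dense stereo matching for endoscopic video, with an optics
calculator, a synthetic stereo-scene generator, and evaluation tools.

Given a rectified stereo pair, the matcher estimates a per-pixel disparity
map: for a left pixel at column `x`, its right-image correspondence sits at
`x - d`. Depth follows from the pinhole relation `Z = fx * b / d`. The
pipeline is classical and fully deterministic:

1. **Matching cost.** A truncated blend of color and gradient evidence,
   `C(p, d) = alpha * min(TM, M) + (1 - alpha) * min(TG, G)`, where `M` is the
   summed absolute RGB difference and `G` the absolute difference of
   horizontal Sobel responses on grayscale. Truncation bounds the influence
   of occluded or specular pixels.
2. **Aggregation.** Each disparity slice of the cost volume is smoothed with
   a guided filter steered by the left image, so support weights adapt to
   image edges without an explicit window-weight loop.
3. **Selection.** Winner-take-all over disparities, followed by parabola
   sub-pixel refinement of the cost minimum (clamped to ±0.5 level).
4. **Consistency.** A bilateral-weighted median smooths the map; a
   left/right cross-check invalidates inconsistent pixels; saturated
   (glare) pixels are rejected; invalidated pixels are filled with the
   smaller of the nearest valid disparities along the scanline; a final
   weighted median smooths the seams.
5. **Iteration.** On video, the previous frame's disparity map bounds the
   search range per pixel: windowed min/max envelopes (four stages with
   different window radii) expanded by a small offset `d_offset`. This
   shrinks the cost volume dramatically on temporally coherent footage
   while tolerating bounded frame-to-frame motion.

The package also provides binocular-geometry utilities (depth maps, point
clouds), diffraction/sampling resolution calculators for endoscope optics,
a synthetic scene generator with exact ground truth and occlusion masks,
and MAE/RMSE evaluation with an equal-weight keyframe averaging protocol.

## Tests

```sh
python -m pytest -q tests/
```

## Worked example

A 24×32 step scene (disparity 4 on the left half, 9 on the right) from the
built-in generator, matched with small-image parameters:

```python
import numpy as np
from iterstereo.synthetic import worked_fixture, worked_fixture_params
from iterstereo.pipeline import match_pair
from iterstereo.evaluation import mae, rmse

frame = worked_fixture()
disp, report = match_pair(frame.pair, worked_fixture_params())
visible = ~frame.occluded
print("MAE  (visible px): %.5f" % mae(disp.d, frame.gt_disparity, visible))
print("RMSE (visible px): %.5f" % rmse(disp.d, frame.gt_disparity, visible))
print(np.array2string(disp.d[12, 12:21], precision=3))
```

Output:

```
MAE  (visible px): 0.00815
RMSE (visible px): 0.01120
[4.021 4.021 4.021 4.021 9.007 9.    8.995 8.998 9.001]
```

The corresponding ground-truth row is `[4 4 4 4 9 9 9 9 9]`: the step edge
is recovered at the right column and the sub-pixel estimates sit within a
few hundredths of a level of truth.

The same pipeline is available from the command line:

```sh
iterstereo synth --out-dir data --height 48 --width 64 --n-frames 5 --seed 1
iterstereo run data --out-dir out          # per-frame PFM maps + metrics.csv
iterstereo eval out data                   # MAE / RMSE against ground truth
iterstereo optics                          # resolution limits of the default rig
```

`iterstereo optics` with its defaults (650 nm, 4.5 mm aperture, 5 cm
working distance, 3.843 µm pixel, 4.62 mm focal length) prints:

```
Rayleigh spatial resolution: 8.81 um
Pixel footprint:             41.59 um
System limit (max of both):  41.59 um
```

so the spatial resolution of this rig is sampling-limited, not
diffraction-limited.

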