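"""Error metrics and the per-keyframe averaging protocol.

MAE and RMSE are computed over an explicit validity mask (ground-truth
pixels that are finite, inside the stereo overlap, and not occluded).
The keyframe protocol first averages the error within each keyframe and
then averages those keyframe means with equal weight — which biases the
result toward keyframes with fewer frames, but matches how endoscopic
stereo benchmarks aggregate their scores.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np


def _masked_errors(est: np.ndarray, gt: np.ndarray, valid: np.ndarray) -> np.ndarray:
    est = np.asarray(est, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool)
    if est.shape != gt.shape or est.shape != valid.shape:
        raise ValueError("est, gt and valid must share a shape")
    if not valid.any():
        raise ValueError("no valid pixels to evaluate")
    return est[valid] - gt[valid]


def mae(est: np.ndarray, gt: np.ndarray, valid: np.ndarray) -> float:
    """Mean absolute error over valid pixels."""
    return float(np.mean(np.abs(_masked_errors(est, gt, valid))))


def rmse(est: np.ndarray, gt: np.ndarray, valid: np.ndarray) -> float:
    """Root-mean-square error over valid pixels (always >= MAE)."""
    return float(np.sqrt(np.mean(_masked_errors(est, gt, valid) ** 2)))


def evaluation_mask(
    gt: np.ndarray, occluded: np.ndarray | None = None
) -> np.ndarray:
    """Pixels usable for scoring: finite ground truth, not occluded."""
    valid = np.isfinite(np.asarray(gt, dtype=np.float64))
    if occluded is not None:
        valid &= ~np.asarray(occluded, dtype=bool)
    return valid


def keyframe_average(per_frame_maes: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> float:
    """Equal-weight mean over keyframes of each keyframe's mean error.

    ``per_frame_maes`` groups per-frame errors by keyframe (mapping or
    sequence of sequences).  Keyframes contribute equally regardless of
    how many frames they contain, so the result equals the pooled mean
    only when all groups have the same size.
    """
    groups = (
        list(per_frame_maes.values())
        if isinstance(per_frame_maes, Mapping)
        else list(per_frame_maes)
    )
    if not groups:
        raise ValueError("at least one keyframe group is required")
    means = []
    for g in groups:
        g = np.asarray(list(g), dtype=np.float64)
        if g.size == 0:
            raise ValueError("every keyframe must contain at least one frame")
        means.append(g.mean())
    return float(np.mean(means))


def render_error_map(est: np.ndarray, gt: np.ndarray, valid: np.ndarray, path, vmax: float | None = None) -> None:
    """Save a |est - gt| heat map (viridis colormap) as PNG; pixels
    outside the validity mask render black."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import cm

    err = np.where(valid, np.abs(np.asarray(est) - np.asarray(gt)), np.nan)
    top = vmax if vmax is not None else (np.nanmax(err) or 1.0)
    top = max(top, 1e-12)
    rgba = cm.viridis(np.clip(err / top, 0.0, 1.0))
    rgba[~np.asarray(valid, dtype=bool)] = (0.0, 0.0, 0.0, 1.0)
    from . import io as iio

    iio.write_image(rgba[:, :, :3], path)
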