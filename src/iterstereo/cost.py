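"""Initial matching cost: truncated color + gradient dissimilarity.

For a left pixel p = (x, y) and candidate disparity d, the color term is
the summed absolute RGB difference against right pixel (x - d, y) and the
gradient term is the absolute difference of horizontal Sobel responses of
the grayscale images.  Both terms are truncated (at ``tm`` and ``tg``)
and blended with the balance factor alpha:

    C(p, d) = alpha * min(tm, M(p, d)) + (1 - alpha) * min(tg, G(p, d))

Out-of-frame right-image lookups (x - d < 0) receive the truncated
maxima rather than clamped-pixel costs; those pixels are resolved later
by the left-right consistency fill.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .params import MatchParams
from .types import CostVolume, DisparityRangeMask, StereoPair

#: ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])

#: 3x3 horizontal Sobel kernel; rows are y, columns are x.
_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luminance of an RGB image in [0, 1] (BT.601 weights)."""
    return np.asarray(rgb, dtype=np.float64) @ _LUMA


def sobel_x(gray: np.ndarray) -> np.ndarray:
    """Horizontal Sobel gradient with replicate border padding.

    Scaled by 1/8 (the positive tap weight) so the response to a ramp of
    unit slope in x is the slope itself; this keeps the gradient and the
    truncation threshold ``tg`` on the [0, 1] intensity scale.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError(f"image must be at least 3 x 3, got shape {gray.shape}")
    return ndimage.correlate(gray, _SOBEL_X, mode="nearest") / 8.0


def _shifted_abs_diff(left: np.ndarray, right: np.ndarray, d: int, fill: float) -> np.ndarray:
    """|left(x, y) - right(x - d, y)| summed over trailing channels.

    Columns x < d have no right-image correspondence and take ``fill``.
    """
    h, w = left.shape[:2]
    diff = np.abs(left[:, d:] - right[:, : w - d]) if d < w else np.zeros_like(left[:, :0])
    if diff.ndim == 3:
        diff = diff.sum(axis=2)
    out = np.full((h, w), fill, dtype=np.float64)
    out[:, d:] = diff
    return out


def color_cost(pair: StereoPair, d: int, tm: float = np.inf) -> np.ndarray:
    """Summed absolute RGB difference M(p, d); out-of-frame -> ``tm``."""
    if d < 0:
        raise ValueError(f"disparity must be >= 0, got {d}")
    return _shifted_abs_diff(pair.left, pair.right, d, fill=tm)


def gradient_cost(pair: StereoPair, d: int, tg: float = np.inf) -> np.ndarray:
    """Absolute x-Sobel difference G(p, d); out-of-frame -> ``tg``."""
    if d < 0:
        raise ValueError(f"disparity must be >= 0, got {d}")
    gl = sobel_x(to_grayscale(pair.left))
    gr = sobel_x(to_grayscale(pair.right))
    return _shifted_abs_diff(gl, gr, d, fill=tg)


def combined_cost(
    pair: StereoPair,
    params: MatchParams,
    d_range: tuple[int, int] | None = None,
    mask: DisparityRangeMask | None = None,
) -> CostVolume:
    """Truncated color+gradient cost volume over an inclusive d range.

    With a :class:`DisparityRangeMask`, only entries with
    ``lo(p) <= d <= hi(p)`` are marked valid; the remaining entries hold
    the maximum attainable cost and must not be consulted downstream.
    """
    d_min, d_max = d_range if d_range is not None else (params.d_min_global, params.d_max_global)
    if d_min > d_max:
        raise ValueError("empty disparity range")
    if not (params.d_min_global <= d_min and d_max <= params.d_max_global):
        raise ValueError(
            f"range [{d_min}, {d_max}] outside global bounds "
            f"[{params.d_min_global}, {params.d_max_global}]"
        )
    h, w = pair.shape
    n = d_max - d_min + 1
    gl = sobel_x(to_grayscale(pair.left))
    gr = sobel_x(to_grayscale(pair.right))

    costs = np.full((h, w, n), params.max_cost, dtype=np.float64)
    if mask is not None:
        if mask.shape != (h, w):
            raise ValueError("mask shape does not match the image")
        valid = np.zeros((h, w, n), dtype=bool)
    else:
        valid = np.ones((h, w, n), dtype=bool)

    for i, d in enumerate(range(d_min, d_max + 1)):
        if mask is not None:
            sel = mask.covers(d)
            if not sel.any():
                continue
        m = _shifted_abs_diff(pair.left, pair.right, d, fill=params.tm)
        g = _shifted_abs_diff(gl, gr, d, fill=params.tg)
        plane = params.alpha * np.minimum(params.tm, m) + (1.0 - params.alpha) * np.minimum(
            params.tg, g
        )
        if mask is not None:
            costs[sel, i] = plane[sel]
            valid[:, :, i] = sel
        else:
            costs[:, :, i] = plane
    return CostVolume(costs, d_min, d_max, valid)
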