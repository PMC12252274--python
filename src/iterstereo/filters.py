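"""O(n) box filtering and the guided filter, used as the adaptive
support-weight aggregator.

The guided filter output is a local affine function of a guidance image:
within each window the filtered value is ``a * I + b`` with ``a, b``
chosen by ridge regression of the input onto the guide (regularizer
``eps``).  Applied per disparity slice with the matched view's RGB image
as guide, this smooths the cost volume while preserving depth edges that
coincide with image edges.

Box means are computed as two separable cumulative-sum passes (rows then
columns); borders use shrinking windows normalized by the true in-bounds
count, which keeps constants exactly invariant.
"""

from __future__ import annotations

import numpy as np

from .params import MatchParams
from .types import CostVolume, DisparityRangeMask


def _box_sum_axis(arr: np.ndarray, r: int, axis: int) -> np.ndarray:
    """Inclusive windowed sum of half-width r along one axis (clipped)."""
    c = np.cumsum(arr, axis=axis)
    n = arr.shape[axis]
    idx = np.arange(n)
    hi = np.take(c, np.minimum(idx + r, n - 1), axis=axis)
    lo_idx = idx - r - 1
    lo = np.take(c, np.clip(lo_idx, 0, n - 1), axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = n
    lo = np.where((lo_idx >= 0).reshape(shape), lo, 0.0)
    return hi - lo


def _window_counts(h: int, w: int, r: int) -> np.ndarray:
    ny = np.minimum(np.arange(h) + r, h - 1) - np.maximum(np.arange(h) - r, 0) + 1
    nx = np.minimum(np.arange(w) + r, w - 1) - np.maximum(np.arange(w) - r, 0) + 1
    return ny[:, None].astype(np.float64) * nx[None, :]


def box_filter(img: np.ndarray, r: int) -> np.ndarray:
    """Mean over the (2r+1)^2 window, count-correct at borders.

    Accepts H x W or H x W x C input (channels filtered independently).
    """
    img = np.asarray(img, dtype=np.float64)
    if r < 1:
        raise ValueError(f"radius must be >= 1, got {r}")
    h, w = img.shape[:2]
    if r > h or r > w:
        raise ValueError(f"radius {r} larger than image dimensions {h} x {w}")
    sums = _box_sum_axis(_box_sum_axis(img, r, 0), r, 1)
    counts = _window_counts(h, w, r)
    if img.ndim == 3:
        counts = counts[:, :, None]
    return sums / counts


def guided_filter_gray(guide: np.ndarray, input: np.ndarray, r: int, eps: float) -> np.ndarray:
    """Scalar-guide guided filter (the classic pseudo-code, verbatim)."""
    guide = np.asarray(guide, dtype=np.float64)
    input = np.asarray(input, dtype=np.float64)
    if guide.shape != input.shape or guide.ndim != 2:
        raise ValueError("guide and input must be identically shaped H x W maps")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    mean_i = box_filter(guide, r)
    corr_i = box_filter(guide * guide, r)
    var_i = corr_i - mean_i * mean_i
    mean_p = box_filter(input, r)
    corr_ip = box_filter(guide * input, r)
    cov_ip = corr_ip - mean_i * mean_p
    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    return box_filter(a, r) * guide + box_filter(b, r)


class ColorGuideStats:
    """Precomputed per-window statistics of an RGB guide.

    The expensive part of the color guided filter — the regularized 3x3
    window covariance and its inverse — depends only on the guide, so it
    is computed once and shared across all disparity slices.
    """

    def __init__(self, guide: np.ndarray, r: int, eps: float):
        guide = np.asarray(guide, dtype=np.float64)
        if guide.ndim != 3 or guide.shape[2] != 3:
            raise ValueError("color guide must be H x W x 3")
        if eps <= 0:
            raise ValueError("eps must be > 0")
        if not np.isfinite(guide).all():
            raise ValueError("guide contains non-finite values")
        self.guide = guide
        self.r = r
        self.mean_i = box_filter(guide, r)  # (H, W, 3)
        h, w, _ = guide.shape
        corr = np.empty((h, w, 3, 3))
        for i in range(3):
            for j in range(i, 3):
                corr[:, :, i, j] = corr[:, :, j, i] = box_filter(
                    guide[:, :, i] * guide[:, :, j], r
                )
        cov = corr - self.mean_i[:, :, :, None] * self.mean_i[:, :, None, :]
        cov[:, :, np.arange(3), np.arange(3)] += eps
        self.inv_sigma = np.linalg.inv(cov)  # (H, W, 3, 3)

    def filter(self, input: np.ndarray) -> np.ndarray:
        input = np.asarray(input, dtype=np.float64)
        if input.shape != self.guide.shape[:2]:
            raise ValueError("input shape does not match the guide")
        if not np.isfinite(input).all():
            raise ValueError("input contains non-finite values")
        mean_p = box_filter(input, self.r)
        corr_ip = box_filter(self.guide * input[:, :, None], self.r)
        cov_ip = corr_ip - self.mean_i * mean_p[:, :, None]
        a = np.einsum("hwij,hwj->hwi", self.inv_sigma, cov_ip)
        b = mean_p - np.einsum("hwi,hwi->hw", a, self.mean_i)
        mean_a = box_filter(a, self.r)
        mean_b = box_filter(b, self.r)
        return np.einsum("hwi,hwi->hw", mean_a, self.guide) + mean_b


def guided_filter_color(guide: np.ndarray, input: np.ndarray, r: int, eps: float) -> np.ndarray:
    """RGB-guide guided filter: per-window 3x3 covariance, diagonal
    eps regularization, per-pixel coefficient vector a and offset b."""
    return ColorGuideStats(guide, r, eps).filter(input)


def smooth_cost_volume(
    vol: CostVolume,
    guide: np.ndarray,
    params: MatchParams,
    stage_mask: DisparityRangeMask | None = None,
) -> CostVolume:
    """Guided-filter every disparity slice with the view image as guide.

    Entries that were never computed (``valid=False``) are padded with
    the maximum attainable truncated cost before filtering so they repel,
    never attract, the winner-takes-all step.  In mask-aware mode the
    output validity is gated by ``stage_mask`` (pixels whose range does
    not cover d stay invalid).
    """
    guide = np.asarray(guide, dtype=np.float64)
    if guide.shape[:2] != vol.costs.shape[:2]:
        raise ValueError("guide does not match the cost volume extent")
    stats = ColorGuideStats(guide, params.er, params.eps)
    out = np.empty_like(vol.costs)
    out_valid = vol.valid.copy()
    for i, d in enumerate(vol.disparities):
        slc = vol.costs[:, :, i]
        if not vol.valid[:, :, i].all():
            slc = np.where(vol.valid[:, :, i], slc, params.max_cost)
        out[:, :, i] = stats.filter(slc)
        if stage_mask is not None:
            out_valid[:, :, i] &= stage_mask.covers(d)
    return CostVolume(out, vol.d_min, vol.d_max, out_valid)
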