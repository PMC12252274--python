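"""Single-pair disparity estimation and consistency postprocessing.

Stage order: truncated cost volume for both views -> guided-filter
aggregation -> winner-takes-all with parabola sub-pixel refinement ->
weighted median of the right map -> left-right consistency check ->
glare invalidation -> scanline fill -> final weighted median over the
whole map.  Everything is deterministic: identical inputs and parameters
produce bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost import combined_cost
from .filters import smooth_cost_volume
from .params import MatchParams
from .types import (
    INVALID,
    ConsistencyReport,
    CostVolume,
    DisparityMap,
    DisparityRangeMask,
    StageMasks,
    StereoPair,
)


def wta(vol: CostVolume) -> DisparityMap:
    """Winner-takes-all: per-pixel argmin over valid disparities.

    Ties break toward the smaller disparity.  A pixel with no valid
    entry indicates a broken range mask upstream and raises.
    """
    if not vol.valid.any(axis=2).all():
        raise ValueError("cost volume has pixels with zero valid entries")
    masked = np.where(vol.valid, vol.costs, np.inf)
    idx = np.argmin(masked, axis=2)
    return DisparityMap((vol.d_min + idx).astype(np.float64), np.ones(idx.shape, dtype=bool), "left")


def subpixel_refine(vol: CostVolume, disp: DisparityMap) -> DisparityMap:
    """Parabola refinement of integer winners.

    Where both neighboring levels are valid and the three costs form a
    convex parabola, the refined disparity is the parabola vertex

        d* = d + (C(d-1) - C(d+1)) / (2 (C(d-1) - 2 C(d) + C(d+1)))

    which never moves the winner by more than half a level; otherwise
    the integer disparity is kept.
    """
    h, w = disp.shape
    idx = np.round(disp.d - vol.d_min).astype(np.int64)
    refined = disp.d.copy()
    inner = disp.valid & (idx > 0) & (idx < vol.n_levels - 1)
    if inner.any():
        ys, xs = np.nonzero(inner)
        ii = idx[inner]
        ok = vol.valid[ys, xs, ii - 1] & vol.valid[ys, xs, ii + 1]
        ys, xs, ii = ys[ok], xs[ok], ii[ok]
        c0 = vol.costs[ys, xs, ii - 1]
        c1 = vol.costs[ys, xs, ii]
        c2 = vol.costs[ys, xs, ii + 1]
        denom = c0 - 2.0 * c1 + c2
        convex = denom > 0
        delta = np.zeros_like(c1)
        delta[convex] = (c0[convex] - c2[convex]) / (2.0 * denom[convex])
        np.clip(delta, -0.5, 0.5, out=delta)
        refined[ys, xs] = refined[ys, xs] + delta
    return DisparityMap(refined, disp.valid.copy(), disp.view)


def weighted_median(
    disp: DisparityMap,
    guide: np.ndarray,
    radius: int,
    sigma_g: float,
    sigma_m: float,
) -> DisparityMap:
    """Bilateral-weighted median over a (2*radius+1)^2 window.

    Neighbor j of pixel p gets weight
    ``exp(-||p-j||^2 / sigma_g^2) * exp(-||I_p - I_j||^2 / sigma_m^2)``;
    the output is the smallest neighbor disparity whose cumulative weight
    reaches half the window total.  Invalid neighbors are excluded; a
    window with no valid neighbor leaves the pixel invalid.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    guide = np.asarray(guide, dtype=np.float64)
    h, w = disp.shape
    k = (2 * radius + 1) ** 2
    vals = np.full((k, h, w), np.nan)
    wts = np.zeros((k, h, w))
    n = 0
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            py0, py1 = max(0, -dy), h - max(0, dy)
            px0, px1 = max(0, -dx), w - max(0, dx)
            if py0 >= py1 or px0 >= px1:
                n += 1
                continue
            p_sl = (slice(py0, py1), slice(px0, px1))
            j_sl = (slice(py0 + dy, py1 + dy), slice(px0 + dx, px1 + dx))
            nb_valid = disp.valid[j_sl]
            cdiff = guide[p_sl] - guide[j_sl]
            wgt = np.exp(-(dy * dy + dx * dx) / (sigma_g * sigma_g)) * np.exp(
                -np.sum(cdiff * cdiff, axis=2) / (sigma_m * sigma_m)
            )
            vals[n][p_sl] = np.where(nb_valid, disp.d[j_sl], np.nan)
            wts[n][p_sl] = np.where(nb_valid, wgt, 0.0)
            n += 1
    order = np.argsort(vals, axis=0)  # NaNs sort last
    s_vals = np.take_along_axis(vals, order, axis=0)
    s_wts = np.take_along_axis(wts, order, axis=0)
    cum = np.cumsum(s_wts, axis=0)
    total = cum[-1]
    any_valid = total > 0
    half = 0.5 * total
    pick = np.argmax(cum >= half[None], axis=0)
    out = np.take_along_axis(s_vals, pick[None], axis=0)[0]
    out = np.where(any_valid, out, INVALID)
    return DisparityMap(out, any_valid, disp.view)


def lr_check(d_left: DisparityMap, d_right: DisparityMap, tol: float) -> np.ndarray:
    """Left-right consistency: pixel p = (x, y) passes iff the right-view
    disparity at (x - round(d_left(p)), y) agrees within ``tol`` and the
    lookup stays in frame."""
    if d_left.shape != d_right.shape:
        raise ValueError("left and right maps must share a shape")
    h, w = d_left.shape
    xs = np.arange(w)[None, :]
    dl = np.where(d_left.valid, d_left.d, 0.0)
    xr = xs - np.round(dl).astype(np.int64)
    inb = d_left.valid & (xr >= 0) & (xr < w)
    xr_c = np.clip(xr, 0, w - 1)
    rows = np.arange(h)[:, None]
    right_d = d_right.d[rows, xr_c]
    right_ok = d_right.valid[rows, xr_c]
    return inb & right_ok & (np.abs(d_left.d - right_d) <= tol)


def fill_invalid(disp: DisparityMap) -> tuple[DisparityMap, int]:
    """Fill invalid pixels from the nearest consistent neighbors.

    Per scanline each invalid pixel takes the smaller of the nearest
    valid disparities to its left and right (occluded regions belong to
    the farther, lower-disparity surface); one-sided when only one side
    exists.  A fully invalid row falls back to the nearest valid row in
    the column direction (ties take the smaller value).  Returns the
    filled map and the number of filled pixels.
    """
    valid = disp.valid
    if not valid.any():
        raise ValueError("cannot fill a fully invalid disparity map")
    h, w = disp.shape
    d = np.where(valid, disp.d, np.nan)
    cols = np.arange(w)[None, :].repeat(h, axis=0)

    left_idx = np.maximum.accumulate(np.where(valid, cols, -1), axis=1)
    right_idx = np.minimum.accumulate(np.where(valid, cols, w)[:, ::-1], axis=1)[:, ::-1]
    rows = np.arange(h)[:, None]
    left_val = np.where(left_idx >= 0, d[rows, np.clip(left_idx, 0, w - 1)], np.inf)
    right_val = np.where(right_idx < w, d[rows, np.clip(right_idx, 0, w - 1)], np.inf)
    filled = np.where(valid, disp.d, np.minimum(left_val, right_val))

    empty_rows = ~valid.any(axis=1)
    if empty_rows.any():
        ridx = np.arange(h)
        row_ok = ~empty_rows
        up = np.maximum.accumulate(np.where(row_ok, ridx, -1))
        down = np.minimum.accumulate(np.where(row_ok, ridx, h)[::-1])[::-1]
        for y in np.nonzero(empty_rows)[0]:
            cand = []
            if up[y] >= 0:
                cand.append((y - up[y], filled[up[y]]))
            if down[y] < h:
                cand.append((down[y] - y, filled[down[y]]))
            dist_min = min(c[0] for c in cand)
            vals = [c[1] for c in cand if c[0] == dist_min]
            filled[y] = np.minimum.reduce(vals) if len(vals) > 1 else vals[0]

    n_filled = int((~valid).sum())
    return DisparityMap(filled, np.ones((h, w), dtype=bool), disp.view), n_filled


def glare_mask(img: np.ndarray, threshold: float) -> np.ndarray:
    """True where every channel is saturated (>= threshold)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    img = np.asarray(img, dtype=np.float64)
    return img.min(axis=2) >= threshold


@dataclass
class MatchResult:
    """Full output of one matched pair, kept for the sequence driver."""

    disparity: DisparityMap  # final left-view map, fully valid
    report: ConsistencyReport
    right_disparity: DisparityMap  # median-filtered right-view map
    inconsistency_rate: float


def _flip_mask(mask: DisparityRangeMask | None) -> DisparityRangeMask | None:
    if mask is None:
        return None
    return DisparityRangeMask(mask.lo[:, ::-1], mask.hi[:, ::-1], mask.stage)


def _match_one_view(
    pair: StereoPair,
    params: MatchParams,
    guide: np.ndarray,
    envelope: DisparityRangeMask | None,
    y2_mask: DisparityRangeMask | None,
) -> DisparityMap:
    vol = combined_cost(pair, params, mask=envelope)
    vol = smooth_cost_volume(vol, guide, params, stage_mask=y2_mask)
    return subpixel_refine(vol, wta(vol))


def match_pair_detailed(
    pair: StereoPair,
    params: MatchParams,
    masks: StageMasks | None = None,
    right_masks: StageMasks | None = None,
) -> MatchResult:
    """Run the full pipeline on one rectified pair.

    ``masks``/``right_masks`` are the per-stage disparity-range masks
    for the left and right views (or None for the full global range).
    The right view is matched by mirroring both images horizontally and
    swapping their roles, which reduces it to the left-view matcher.
    """
    from .iterative import merge_masks  # local import; no cycle at call time

    env_l = merge_masks([masks[s] for s in ("x1", "y1", "x2", "y2")]) if masks else None
    y2_l = masks["y2"] if masks else None
    d_left = _match_one_view(pair, params, pair.left, env_l, y2_l)

    flipped = StereoPair(pair.right[:, ::-1], pair.left[:, ::-1], pair.frame_index)
    env_r = (
        merge_masks([right_masks[s] for s in ("x1", "y1", "x2", "y2")]) if right_masks else None
    )
    y2_r = right_masks["y2"] if right_masks else None
    d_right_f = _match_one_view(
        flipped, params, flipped.left, _flip_mask(env_r), _flip_mask(y2_r)
    )
    d_right = DisparityMap(d_right_f.d[:, ::-1].copy(), d_right_f.valid[:, ::-1].copy(), "right")

    # postprocessing chain
    d_right_med = weighted_median(
        d_right, pair.right, params.median_radius, params.sigma_g, params.sigma_m
    )
    lr_ok = lr_check(d_left, d_right_med, params.lr_tolerance)
    glare = glare_mask(pair.left, params.glare_threshold)
    n_inconsistent = int((~lr_ok).sum())
    n_glare = int((glare & lr_ok).sum())
    keep = lr_ok & ~glare
    invalidated = DisparityMap(np.where(keep, d_left.d, INVALID), keep, "left")
    filled, n_filled = fill_invalid(invalidated)
    final = weighted_median(
        filled, pair.left, params.median_radius, params.sigma_g, params.sigma_m
    )
    final = DisparityMap(
        np.clip(final.d, params.d_min_global, params.d_max_global), final.valid, "left"
    )
    report = ConsistencyReport(n_inconsistent, n_glare, n_filled)
    h, w = pair.shape
    return MatchResult(final, report, d_right_med, n_inconsistent / float(h * w))


def match_pair(
    pair: StereoPair,
    params: MatchParams | None = None,
    masks: StageMasks | None = None,
    right_masks: StageMasks | None = None,
) -> tuple[DisparityMap, ConsistencyReport]:
    """Convenience wrapper returning just the left map and its report."""
    result = match_pair_detailed(pair, params or MatchParams(), masks, right_masks)
    return result.disparity, result.report
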