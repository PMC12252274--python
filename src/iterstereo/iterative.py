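"""Temporal disparity-range refinement for video.

The previous frame's postprocessed disparity map bounds the current
frame's per-pixel search range: each pixel's range is the local min/max
of the previous map over a stage-dependent rectangular window, widened
by ``d_offset`` levels.  The four stages correspond to the separable
x/y passes of the guided filter's two box-filter sweeps, whose effective
support shrinks from the first pass to the last:

    x1 -> (er + br, er + 2 br)      y1 -> (er + br, er + br)
    x2 -> (er,      er + br)        y2 -> (er,      er)

(radii given as (rx, ry); er = guided-filter edge radius, br = box
radius).  The merged per-pixel envelope of the four masks governs which
cost entries are computed at all.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
from scipy import ndimage

from .params import MatchParams
from .pipeline import MatchResult, match_pair_detailed
from .types import (
    ConsistencyReport,
    DisparityMap,
    DisparityRangeMask,
    StageMasks,
    StereoPair,
    STAGES,
)


def stage_radii(er: int, br: int, stage: str) -> tuple[int, int]:
    """Window radii (rx, ry) for one separable-convolution stage."""
    if er < 1 or br < 1:
        raise ValueError("er and br must be >= 1")
    table = {
        "x1": (er + br, er + 2 * br),
        "y1": (er + br, er + br),
        "x2": (er, er + br),
        "y2": (er, er),
    }
    if stage not in table:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return table[stage]


def build_mask(prev: DisparityMap, stage: str, params: MatchParams) -> DisparityRangeMask:
    """Per-pixel [lo, hi] bounds from the previous frame's map.

    ``lo = floor(window min) - d_offset`` and ``hi = ceil(window max) +
    d_offset`` over the stage's rectangular window (clipped at borders),
    clamped to the global range.  The previous map must be fully valid
    (it is the postprocessed, filled map by construction).
    """
    if not prev.valid.all():
        raise ValueError("build_mask requires a fully valid (filled) previous map")
    rx, ry = stage_radii(params.er, params.br, stage)
    size = (2 * ry + 1, 2 * rx + 1)
    # replicate padding reproduces the clipped-window min/max exactly
    wmin = ndimage.minimum_filter(prev.d, size=size, mode="nearest")
    wmax = ndimage.maximum_filter(prev.d, size=size, mode="nearest")
    lo = np.floor(wmin).astype(np.int64) - params.d_offset
    hi = np.ceil(wmax).astype(np.int64) + params.d_offset
    lo = np.clip(lo, params.d_min_global, params.d_max_global)
    hi = np.clip(hi, params.d_min_global, params.d_max_global)
    return DisparityRangeMask(lo, hi, stage)


def build_stage_masks(prev: DisparityMap, params: MatchParams) -> StageMasks:
    """All four per-stage masks for one view."""
    return StageMasks({s: build_mask(prev, s, params) for s in STAGES})


def merge_masks(masks: Iterable[DisparityRangeMask]) -> DisparityRangeMask:
    """Per-pixel envelope: lo = min of the lo's, hi = max of the hi's.

    The envelope decides which cost-volume entries must exist before any
    filtering stage consumes them; it is labeled with the outermost
    stage (x1), whose window dominates the union in practice.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("merge_masks needs at least one mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("masks must share a shape")
    lo = np.minimum.reduce([m.lo for m in masks])
    hi = np.maximum.reduce([m.hi for m in masks])
    return DisparityRangeMask(lo, hi, "x1")


def valid_entry_count(masks: Iterable[DisparityRangeMask]) -> int:
    """Total cost-volume entries inside the merged envelope."""
    env = merge_masks(masks)
    return int(np.sum(env.hi - env.lo + 1))


def run_sequence_detailed(
    frames: Iterable[StereoPair], params: MatchParams | None = None
) -> Iterator[MatchResult]:
    """Match a stereo sequence with temporal range refinement.

    Frames with index below ``warmup_frames`` (and frame 0 always) use
    the full global range; afterwards each frame's masks derive from the
    previous frame's postprocessed left and right maps.  If a frame's
    left-right inconsistency rate exceeds ``cut_fallback_rate`` (scene
    cut, tracking loss), the next frame falls back to the full range.
    """
    params = params or MatchParams()
    prev: MatchResult | None = None
    for index, pair in enumerate(frames):
        use_masks = (
            prev is not None
            and index >= max(1, params.warmup_frames)
            and prev.inconsistency_rate <= params.cut_fallback_rate
        )
        if use_masks:
            left_masks = build_stage_masks(prev.disparity, params)
            # the right map is median-filtered but may retain invalid
            # pixels in degenerate windows; fill before building masks
            right_prev = prev.right_disparity
            if not right_prev.valid.all():
                from .pipeline import fill_invalid

                right_prev, _ = fill_invalid(right_prev)
            right_masks = build_stage_masks(right_prev, params)
        else:
            left_masks = right_masks = None
        prev = match_pair_detailed(pair, params, left_masks, right_masks)
        yield prev


def run_sequence(
    frames: Iterable[StereoPair], params: MatchParams | None = None
) -> Iterator[tuple[DisparityMap, ConsistencyReport]]:
    """Like :func:`run_sequence_detailed` but yields (map, report)."""
    for result in run_sequence_detailed(frames, params):
        yield result.disparity, result.report


def refine_single_pair(
    pair: StereoPair, params: MatchParams | None = None, iterations: int = 1
) -> MatchResult:
    """Single-pair refinement: iterate the temporal update on one pair.

    A first full-range pass seeds the masks; each further iteration
    re-matches the same pair restricted to masks built from the previous
    result, trimming outliers the way the video mode does.
    """
    params = params or MatchParams()
    result = match_pair_detailed(pair, params)
    for _ in range(iterations):
        left_masks = build_stage_masks(result.disparity, params)
        right_prev = result.right_disparity
        if not right_prev.valid.all():
            from .pipeline import fill_invalid

            right_prev, _ = fill_invalid(right_prev)
        right_masks = build_stage_masks(right_prev, params)
        result = match_pair_detailed(pair, params, left_masks, right_masks)
    return result
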