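"""Shared domain types for the stereo-matching pipeline.

All images are ``float64`` arrays normalized to [0, 1], indexed
``(row, column)`` = ``(y, x)`` with 0-based coordinates.  Disparity ``d``
means the right-image match of left pixel ``(x, y)`` is ``(x - d, y)``,
with ``d >= 0``; pairs are assumed rectified, so correspondences lie on
the same row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel stored at invalid disparity-map entries.  Consumers must branch
#: on the validity mask, never on this numeric value.
INVALID = np.inf

STAGES = ("x1", "y1", "x2", "y2")


def _as_float_image(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must be an H x W x 3 RGB array, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return arr


@dataclass
class StereoPair:
    """A rectified stereo frame: left/right RGB images in [0, 1]."""

    left: np.ndarray
    right: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.left = _as_float_image(self.left, "left")
        self.right = _as_float_image(self.right, "right")
        if self.left.shape != self.right.shape:
            raise ValueError(
                f"left/right shapes differ: {self.left.shape} vs {self.right.shape}"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape[:2]


@dataclass
class CostVolume:
    """Per-pixel, per-disparity matching cost.

    ``costs[y, x, i]`` is the cost of assigning disparity ``d_min + i`` to
    pixel ``(x, y)``.  Entries with ``valid=False`` were never computed
    (mask-aware mode) and must not be consulted by winner-takes-all.
    """

    costs: np.ndarray  # (H, W, D)
    d_min: int
    d_max: int
    valid: np.ndarray  # (H, W, D) bool

    def __post_init__(self) -> None:
        if self.d_min > self.d_max:
            raise ValueError("d_min must be <= d_max")
        D = self.d_max - self.d_min + 1
        if self.costs.shape != self.valid.shape or self.costs.shape[2] != D:
            raise ValueError("costs/valid shape mismatch with disparity range")

    @property
    def disparities(self) -> np.ndarray:
        return np.arange(self.d_min, self.d_max + 1)

    @property
    def n_levels(self) -> int:
        return self.d_max - self.d_min + 1


@dataclass
class DisparityMap:
    """Float disparity map with an explicit validity mask.

    Invalid entries hold the :data:`INVALID` sentinel; the ``valid`` mask is
    the single source of truth.
    """

    d: np.ndarray  # (H, W) float
    valid: np.ndarray  # (H, W) bool
    view: str = "left"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.d.shape != self.valid.shape:
            raise ValueError("d and valid must share a shape")
        if self.view not in ("left", "right"):
            raise ValueError(f"view must be 'left' or 'right', got {self.view!r}")
        # enforce valid=False <=> d == INVALID
        self.d = np.where(self.valid, self.d, INVALID)
        if np.any(self.d[self.valid] < 0) or not np.isfinite(self.d[self.valid]).all():
            raise ValueError("valid disparities must be finite and >= 0")

    def copy(self) -> "DisparityMap":
        return DisparityMap(self.d.copy(), self.valid.copy(), self.view)

    @property
    def shape(self) -> tuple[int, int]:
        return self.d.shape


@dataclass
class DisparityRangeMask:
    """Per-pixel inclusive [lo, hi] disparity search bounds for one
    separable-convolution stage of the guided filter."""

    lo: np.ndarray  # (H, W) int
    hi: np.ndarray  # (H, W) int
    stage: str = "y2"

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=np.int64)
        self.hi = np.asarray(self.hi, dtype=np.int64)
        if self.lo.shape != self.hi.shape:
            raise ValueError("lo and hi must share a shape")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if np.any(self.lo > self.hi):
            raise ValueError("mask invariant violated: lo > hi at some pixel")

    def covers(self, d: int) -> np.ndarray:
        """Boolean map of pixels whose range includes disparity ``d``."""
        return (self.lo <= d) & (d <= self.hi)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lo.shape


@dataclass
class ConsistencyReport:
    """Bookkeeping from the postprocessing chain.

    Conservation: every invalidated pixel (LR-inconsistent or glare) is
    subsequently filled, so ``n_filled == n_inconsistent + n_glare``.
    """

    n_inconsistent: int = 0
    n_glare: int = 0
    n_filled: int = 0

    def __post_init__(self) -> None:
        if self.n_filled != self.n_inconsistent + self.n_glare:
            raise ValueError("report conservation violated: n_filled != n_inconsistent + n_glare")


@dataclass
class StageMasks:
    """The four per-stage masks for one view, keyed by stage name."""

    masks: dict = field(default_factory=dict)

    def __getitem__(self, stage: str) -> DisparityRangeMask:
        return self.masks[stage]

    def __contains__(self, stage: str) -> bool:
        return stage in self.masks
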