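"""Deterministic synthetic rectified stereo scenes with ground truth.

The generator emulates the structure of endoscope-like desk scenes:
textured height-field surfaces seen by a rectified rig, so disparity is
horizontal only, depth steps create occlusion bands on their far side,
and optional saturated glare discs mimic specular LED reflections.  The
right image is synthesized from the left by forward warping with
visibility reasoning (a right pixel claimed by several left pixels keeps
the largest disparity; the losers are occluded), which makes integer-
disparity scenes exactly self-consistent and hence exactly testable.

Each depth level receives a small brightness modulation on top of the
texture, standing in for the illumination differences between faces of
a real machined body; without it a depth edge would be invisible to any
edge-aware aggregator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io as iio
from .params import MatchParams
from .types import StereoPair

_SURFACES = ("plane", "slanted_plane", "height_profile", "step_pyramid")
_TEXTURES = ("noise", "sinusoid", "low_contrast")


@dataclass
class SceneSpec:
    """Parameters of a generated scene / sequence.

    ``d_base`` is the central disparity (levels), ``d_amplitude`` the
    surface relief around it; ``drift_per_frame`` shifts the whole
    surface in disparity between frames (object moving in depth).
    """

    height: int = 48
    width: int = 64
    surface: str = "plane"
    d_base: int = 8
    d_amplitude: int = 4
    texture: str = "noise"
    texture_contrast: float = 0.8
    glare_spots: int = 0
    drift_per_frame: float = 0.0
    n_frames: int = 1
    seed: int = 0
    d_min_global: int = 0
    d_max_global: int = 24
    quantize_disparity: bool = True
    per_view_gain: float = 1.0  # optional right-view photometric gain

    def __post_init__(self) -> None:
        if self.surface not in _SURFACES:
            raise ValueError(f"surface must be one of {_SURFACES}, got {self.surface!r}")
        if self.texture not in _TEXTURES:
            raise ValueError(f"texture must be one of {_TEXTURES}, got {self.texture!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.texture_contrast <= 1.0:
            raise ValueError("texture_contrast must lie in [0, 1]")
        total_drift = self.drift_per_frame * (self.n_frames - 1)
        lo = self.d_base - self.d_amplitude + min(0.0, total_drift)
        hi = self.d_base + self.d_amplitude + max(0.0, total_drift)
        if lo < self.d_min_global or hi > self.d_max_global:
            raise ValueError(
                f"disparity span [{lo}, {hi}] violates global bounds "
                f"[{self.d_min_global}, {self.d_max_global}]"
            )


@dataclass
class SyntheticFrame:
    """One generated frame with its exact ground truth."""

    pair: StereoPair
    gt_disparity: np.ndarray  # (H, W) float
    occluded: np.ndarray  # (H, W) bool: no right-image correspondence
    glare: np.ndarray  # (H, W) bool: painted saturated discs (left view)


# --------------------------------------------------------------------------
# surface and texture primitives
# --------------------------------------------------------------------------

def _surface_field(spec: SceneSpec, d_base: float) -> np.ndarray:
    h, w = spec.height, spec.width
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    if spec.surface == "plane":
        d = np.full((h, w), d_base)
    elif spec.surface == "slanted_plane":
        d = d_base + spec.d_amplitude * (2.0 * xs / max(w - 1, 1) - 1.0)
    elif spec.surface == "height_profile":
        d = d_base + spec.d_amplitude * np.sin(2.0 * np.pi * xs / w) * np.sin(
            np.pi * ys / max(h - 1, 1)
        )
    else:  # step_pyramid: concentric rectangular terraces
        border = np.minimum.reduce([ys, xs, h - 1 - ys, w - 1 - xs])
        level = np.minimum((border // (min(h, w) // 6 + 1)).astype(np.int64), 2)
        d = d_base + spec.d_amplitude * (level - 1).astype(np.float64)
    if spec.quantize_disparity:
        d = np.round(d)
    return d


def _texture(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    contrast = spec.texture_contrast
    if spec.texture == "sinusoid":
        ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
        tex = np.empty((h, w, 3))
        for c, phase in enumerate((0.0, 1.1, 2.3)):
            tex[:, :, c] = 0.5 + 0.5 * contrast * np.sin(
                2.0 * np.pi * xs / 5.5 + phase
            ) * np.cos(2.0 * np.pi * ys / 7.0 + 0.5 * phase)
        return np.clip(tex, 0.0, 1.0)
    if spec.texture == "low_contrast":
        contrast = 0.2 * contrast
    # band-limited noise: white noise low-passed below Nyquist
    raw = rng.standard_normal((h, w, 3))
    smooth = ndimage.gaussian_filter(raw, sigma=(1.0, 1.0, 0.0))
    span = max(np.abs(smooth).max(), 1e-12)
    return np.clip(0.5 + 0.5 * contrast * smooth / span, 0.0, 1.0)


def _shade_by_level(tex: np.ndarray, d: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Brightness modulation per depth level (illumination cue)."""
    span = max(spec.d_amplitude, 1)
    rel = (d - spec.d_base) / span  # roughly [-1, 1]
    gain = 0.75 + 0.25 * rel
    return np.clip(tex * gain[:, :, None], 0.0, 1.0)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_frame(
    left: np.ndarray,
    d: np.ndarray,
    glare_centers: list[tuple[int, int, int]] | None = None,
    frame_index: int = 0,
    per_view_gain: float = 1.0,
) -> SyntheticFrame:
    """Forward-warp a left image by a disparity field into a right image.

    Visibility: each right pixel keeps the claimant with the largest
    disparity (nearest surface); losing left pixels and those mapping
    out of frame are occluded.  Unclaimed right pixels (background
    revealed only to the right camera) are filled from the nearest
    claimed pixel in the row.  ``glare_centers`` are (y, x, radius)
    discs painted saturated in both views at matching positions.
    """
    h, w = d.shape
    left = left.copy()
    right = np.zeros_like(left)
    claimed = np.full((h, w), -np.inf)
    src = np.full((h, w), -1, dtype=np.int64)
    d_round = np.round(d).astype(np.int64)
    occluded = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            xr = x - d_round[y, x]
            if xr < 0 or xr >= w:
                occluded[y, x] = True
                continue
            if d[y, x] > claimed[y, xr]:
                claimed[y, xr] = d[y, x]
                src[y, xr] = x
    for y in range(h):
        for x in range(w):
            xr = x - d_round[y, x]
            if 0 <= xr < w and src[y, xr] != x:
                occluded[y, x] = True
    integer_scene = np.array_equal(d, d_round)
    for y in range(h):
        for xr in range(w):
            xl = src[y, xr]
            if xl >= 0:
                if integer_scene:
                    right[y, xr] = left[y, xl]
                else:
                    xf = xr + d[y, xl]  # sub-pixel source position
                    x0 = int(np.clip(np.floor(xf), 0, w - 1))
                    x1 = min(x0 + 1, w - 1)
                    t = np.clip(xf - x0, 0.0, 1.0)
                    right[y, xr] = (1.0 - t) * left[y, x0] + t * left[y, x1]
    # fill revealed-background holes from the nearest claimed row pixel
    for y in range(h):
        holes = np.nonzero(src[y] < 0)[0]
        if holes.size and holes.size < w:
            good = np.nonzero(src[y] >= 0)[0]
            nearest = good[np.argmin(np.abs(holes[:, None] - good[None, :]), axis=1)]
            right[y, holes] = right[y, nearest]
    if per_view_gain != 1.0:
        right = np.clip(right * per_view_gain, 0.0, 1.0)

    glare = np.zeros((h, w), dtype=bool)
    if glare_centers:
        ys, xs = np.mgrid[0:h, 0:w]
        for gy, gx, gr in glare_centers:
            disc = (ys - gy) ** 2 + (xs - gx) ** 2 <= gr * gr
            glare |= disc
            left[disc] = 1.0
            for y, x in zip(*np.nonzero(disc)):
                xr = x - d_round[y, x]
                if 0 <= xr < w:
                    right[y, xr] = 1.0
    return SyntheticFrame(
        StereoPair(left, right, frame_index), d.astype(np.float64), occluded, glare
    )


def generate(spec: SceneSpec) -> list[SyntheticFrame]:
    """Generate the full sequence described by ``spec`` (reproducible)."""
    rng = np.random.default_rng(spec.seed)
    tex = _texture(spec, rng)
    glare_centers = [
        (
            int(rng.integers(3, max(4, spec.height - 3))),
            int(rng.integers(3, max(4, spec.width - 3))),
            int(rng.integers(1, 3)),
        )
        for _ in range(spec.glare_spots)
    ]
    frames = []
    for f in range(spec.n_frames):
        d = _surface_field(spec, spec.d_base + f * spec.drift_per_frame)
        left = _shade_by_level(tex, d, spec)
        frames.append(
            render_frame(left, d, glare_centers, frame_index=f, per_view_gain=spec.per_view_gain)
        )
    return frames


# --------------------------------------------------------------------------
# worked regression fixture
# --------------------------------------------------------------------------

_FIXTURE_CSV = Path(__file__).parent / "data" / "step_fixture_expected.csv"


def worked_fixture_params() -> MatchParams:
    """Matcher parameters scaled to the 32 x 24 fixture (windows must
    stay well below the image extent)."""
    return MatchParams(
        er=3, br=3, median_radius=3, sigma_g=3.0, d_min_global=0, d_max_global=14
    )


def worked_fixture() -> SyntheticFrame:
    """Fixed 32 x 24 two-level step scene at disparities {4, 9}.

    Sinusoid texture, seed 0; the left half of the image sits on the far
    level (d = 4), the right half on the near level (d = 9), so a
    five-column occlusion band forms left of the step.
    """
    spec = SceneSpec(
        height=24,
        width=32,
        surface="plane",
        d_base=6,
        d_amplitude=3,
        texture="sinusoid",
        seed=0,
        d_max_global=14,
    )
    rng = np.random.default_rng(spec.seed)
    tex = _texture(spec, rng)
    d = np.where(np.tile(np.arange(32) < 16, (24, 1)), 4.0, 9.0)
    left = _shade_by_level(tex, d, spec)
    return render_frame(left, d, frame_index=0)


def worked_fixture_expected() -> np.ndarray:
    """The frozen final disparity map for :func:`worked_fixture` under
    :func:`worked_fixture_params` (regression oracle)."""
    if not _FIXTURE_CSV.exists():
        raise FileNotFoundError(f"frozen fixture map missing: {_FIXTURE_CSV}")
    return np.loadtxt(_FIXTURE_CSV, delimiter=",")


# --------------------------------------------------------------------------
# dataset export
# --------------------------------------------------------------------------

def write_dataset(spec: SceneSpec, out_dir) -> list[Path]:
    """Write a generated sequence as PNG pairs + PFM ground truth + a
    JSON sidecar of the scene spec; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for f, frame in enumerate(generate(spec)):
        for name, img in (("left", frame.pair.left), ("right", frame.pair.right)):
            p = out / f"frame{f:04d}_{name}.png"
            iio.write_image(img, p)
            written.append(p)
        gt = np.where(frame.occluded, np.inf, frame.gt_disparity)
        p = out / f"frame{f:04d}_gt.pfm"
        iio.write_pfm(gt, p)
        written.append(p)
    sidecar = out / "scene.json"
    sidecar.write_text(json.dumps(asdict(spec), indent=2))
    written.append(sidecar)
    return written
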