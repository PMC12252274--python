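"""Algorithm parameters and camera model, with config-file loading.

All intensity-scale thresholds (``tm``, ``tg``, ``sigma_m``,
``glare_threshold``) live on the internal [0, 1] image scale so they are
independent of the input bit depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml


@dataclass
class MatchParams:
    """Tunable parameters of the matcher.

    alpha
        Balance between the color term and the gradient term of the
        truncated matching cost; 0.1 favors the gradient modality.
    tm, tg
        Truncation thresholds for the color and gradient dissimilarities,
        on the [0, 1] intensity scale.
    er, br
        Edge radius of the guided filter window and internal box-filter
        radius, in pixels; they also parameterize the stage-dependent
        window radii of the iterative disparity-range masks.
    eps
        Guided-filter regularization on the [0, 1] intensity scale.
    d_offset
        Disparity margin added around the previous frame's local min/max
        when building range masks.
    sigma_g, sigma_m
        Spatial and color scales of the bilateral weights used by the
        weighted median postprocessing filter.
    median_radius
        Half-width of the weighted median window.
    glare_threshold
        A pixel is glare when every channel is >= this value.
    lr_tolerance
        Maximum left/right disparity disagreement (levels) accepted by
        the consistency check.
    warmup_frames
        Number of initial frames matched at the full disparity range
        before the iterative masks take over.
    d_min_global, d_max_global
        Global disparity search bounds (integer levels).
    cut_fallback_rate
        If the fraction of LR-inconsistent pixels in a frame exceeds this,
        the next frame falls back to the full range (scene-cut recovery).
    """

    alpha: float = 0.1
    tm: float = 0.0824
    tg: float = 0.0078
    er: int = 7
    br: int = 7
    eps: float = 1e-4
    d_offset: int = 2
    sigma_g: float = 9.0
    sigma_m: float = 0.1
    median_radius: int = 9
    glare_threshold: float = 250.0 / 255.0
    lr_tolerance: float = 1.0
    warmup_frames: int = 5
    d_min_global: int = 0
    d_max_global: int = 64
    cut_fallback_rate: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        for name in ("tm", "tg", "eps", "sigma_g", "sigma_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("er", "br", "median_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.d_offset < 0:
            raise ValueError(f"d_offset must be >= 0, got {self.d_offset}")
        if not 0.0 < self.glare_threshold <= 1.0:
            raise ValueError(f"glare_threshold must lie in (0, 1], got {self.glare_threshold}")
        if self.lr_tolerance < 0:
            raise ValueError(f"lr_tolerance must be >= 0, got {self.lr_tolerance}")
        if self.warmup_frames < 0:
            raise ValueError(f"warmup_frames must be >= 0, got {self.warmup_frames}")
        if self.d_min_global > self.d_max_global:
            raise ValueError("d_min_global must be <= d_max_global")
        if not 0.0 < self.cut_fallback_rate <= 1.0:
            raise ValueError("cut_fallback_rate must lie in (0, 1]")

    @property
    def max_cost(self) -> float:
        """Largest attainable truncated combined cost."""
        return self.alpha * self.tm + (1.0 - self.alpha) * self.tg


@dataclass
class CameraModel:
    """Rectified pinhole stereo rig: intrinsics plus baseline in mm."""

    fx: float = 1024.09
    fy: float = 1023.89
    cx: float = 601.81
    cy: float = 508.13
    baseline: float = 4.35
    width: int = 1280
    height: int = 1024

    def __post_init__(self) -> None:
        for name in ("fx", "fy", "baseline"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 <= self.cx < self.width:
            raise ValueError(f"cx must lie in [0, width), got {self.cx}")
        if not 0 <= self.cy < self.height:
            raise ValueError(f"cy must lie in [0, height), got {self.cy}")


def _build(cls, section: dict, section_name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in '{section_name}' section: {sorted(unknown)}; "
            f"valid keys: {sorted(known)}"
        )
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid '{section_name}' configuration: {exc}") from exc


def load_params(path) -> tuple[MatchParams, CameraModel]:
    """Load ``(MatchParams, CameraModel)`` from a YAML or JSON config.

    The file holds two optional mappings, ``params`` and ``camera``;
    omitted keys take the documented defaults and unknown keys are an
    error (typo safety).  An empty file yields the full default set.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"params", "camera"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    params = _build(MatchParams, data.get("params") or {}, "params")
    camera = _build(CameraModel, data.get("camera") or {}, "camera")
    return params, camera


def save_params(params: MatchParams, camera: CameraModel, path) -> None:
    """Write a round-trippable YAML config."""
    Path(path).write_text(
        yaml.safe_dump({"params": asdict(params), "camera": asdict(camera)}, sort_keys=True)
    )
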