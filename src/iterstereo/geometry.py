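"""Disparity-to-depth conversion, point-cloud reprojection, and the
optical-resolution calculators for a stereo endoscope.

For a rectified rig with horizontal focal length ``fx`` (pixels) and
baseline ``b`` (mm), depth is ``Z = fx * b / d``.  The optics helpers
work in SI units internally: the diffraction (Rayleigh) limit of a
circular aperture, the object-space footprint of one sensor pixel, and
the pixel pitch implied by a sensor diagonal and aspect ratio.
"""

from __future__ import annotations

import math

import numpy as np

from .params import CameraModel
from .types import DisparityMap


def disparity_to_depth(disp: DisparityMap, cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Depth map in mm: Z = fx * baseline / d.

    Returns ``(depth, valid)``; pixels with invalid or zero disparity
    have no depth (NaN, valid=False).
    """
    ok = disp.valid & (disp.d > 0)
    depth = np.full(disp.shape, np.nan)
    depth[ok] = cam.fx * cam.baseline / disp.d[ok]
    return depth, ok


def depth_to_disparity(depth: np.ndarray, cam: CameraModel, view: str = "left") -> DisparityMap:
    """Inverse of :func:`disparity_to_depth` on finite positive depths."""
    depth = np.asarray(depth, dtype=np.float64)
    ok = np.isfinite(depth) & (depth > 0)
    d = np.full(depth.shape, np.inf)
    d[ok] = cam.fx * cam.baseline / depth[ok]
    return DisparityMap(d, ok, view)


def disparity_to_pointcloud(
    disp: DisparityMap, img: np.ndarray, cam: CameraModel
) -> tuple[np.ndarray, np.ndarray]:
    """Reproject valid pixels to camera-frame points (mm) with colors.

    X = (x - cx) Z / fx, Y = (y - cy) Z / fy; invalid pixels are skipped.
    """
    depth, ok = disparity_to_depth(disp, cam)
    ys, xs = np.nonzero(ok)
    z = depth[ys, xs]
    x3 = (xs - cam.cx) * z / cam.fx
    y3 = (ys - cam.cy) * z / cam.fy
    points = np.column_stack([x3, y3, z])
    colors = np.asarray(img, dtype=np.float64)[ys, xs]
    return points, colors


def rayleigh_resolution(
    wavelength: float, aperture: float, depth: float, exact: bool = False
) -> float:
    """Diffraction-limited spatial resolution at depth Z, in meters.

    Small-angle form ``Z * 1.22 * lambda / D`` by default; with
    ``exact=True`` returns ``Z * tan(asin(1.22 * lambda / D))``.
    """
    if wavelength <= 0 or aperture <= 0 or depth <= 0:
        raise ValueError("wavelength, aperture and depth must all be > 0")
    s = 1.22 * wavelength / aperture
    if s >= 1.0:
        raise ValueError(f"1.22*lambda/D = {s:.3g} >= 1: diffraction angle undefined")
    if exact:
        return depth * math.tan(math.asin(s))
    return depth * s


def pixel_footprint(pixel_size: float, depth: float, focal_length: float) -> float:
    """Object-space size of one sensor pixel: t = t' * Z / f (meters)."""
    if pixel_size <= 0 or depth <= 0 or focal_length <= 0:
        raise ValueError("pixel_size, depth and focal_length must all be > 0")
    return pixel_size * depth / focal_length


def sensor_pixel_size(
    diagonal: float, aspect_w: int, aspect_h: int, horizontal_pixels: int
) -> float:
    """Square pixel pitch from sensor diagonal, aspect ratio and column
    count (meters)."""
    if diagonal <= 0 or aspect_w <= 0 or aspect_h <= 0 or horizontal_pixels <= 0:
        raise ValueError("all sensor parameters must be > 0")
    width = diagonal * aspect_w / math.hypot(aspect_w, aspect_h)
    return width / horizontal_pixels
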