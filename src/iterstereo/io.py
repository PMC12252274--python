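"""Readers and writers: PNG/PPM images, PFM float maps, PLY point clouds.

Images come back as float64 RGB in [0, 1].  PFM follows the portable
float map convention (``Pf`` header, bottom-up rows, scale sign encoding
endianness); invalid disparities are stored as ``+inf`` and restored as
the :data:`~iterstereo.types.INVALID` sentinel.  The PLY writer supports
``ascii`` and ``binary_little_endian`` with x/y/z/red/green/blue vertex
properties.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .types import INVALID, DisparityMap

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit PNG/PPM as H x W x 3 float64 in [0, 1].

    Grayscale inputs are replicated to three channels; an alpha channel,
    if present, is dropped.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    elif raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    else:
        raise IOError(f"unsupported image dtype {raw.dtype} in {path}")
    return raw.astype(np.float64) / scale


def write_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 8-bit PNG/PPM."""
    img = np.asarray(img, dtype=np.float64)
    quant = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), quant)


# --------------------------------------------------------------------------
# PFM
# --------------------------------------------------------------------------

def write_pfm(data: np.ndarray, path, scale: float = 1.0) -> None:
    """Write a single-channel float map as little-endian PFM.

    Non-finite entries pass through unchanged (``+inf`` is the on-disk
    encoding of invalid disparities).
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError(f"PFM writer expects an H x W map, got shape {data.shape}")
    h, w = data.shape
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{w} {h}\n".encode("ascii"))
        fh.write(f"{-abs(scale)}\n".encode("ascii"))  # negative => little-endian
        fh.write(data[::-1].astype("<f4").tobytes())  # bottom-up row order


def _read_token(fh) -> bytes:
    """Read one whitespace-delimited header token."""
    tok = b""
    while True:
        c = fh.read(1)
        if not c:
            raise ValueError("PFM header truncated")
        if c.isspace():
            if tok:
                return tok
            continue
        tok += c


def read_pfm(path) -> np.ndarray:
    """Read a grayscale PFM into an H x W float64 map (top-down rows)."""
    with open(path, "rb") as fh:
        magic = _read_token(fh)
        if magic != b"Pf":
            raise ValueError(f"not a grayscale PFM file (header {magic!r}): {path}")
        try:
            w = int(_read_token(fh))
            h = int(_read_token(fh))
            scale = float(_read_token(fh))
        except ValueError as exc:
            raise ValueError(f"malformed PFM header in {path}: {exc}") from exc
        endian = "<" if scale < 0 else ">"
        buf = fh.read(4 * w * h)
        if len(buf) < 4 * w * h:
            raise ValueError(f"PFM payload truncated in {path}")
        data = np.frombuffer(buf, dtype=f"{endian}f4").reshape(h, w)
    return data[::-1].astype(np.float64)


def write_disparity(disp: DisparityMap, path) -> None:
    """Write a disparity map to PFM, encoding invalid pixels as +inf."""
    out = np.where(disp.valid, disp.d, np.inf)
    write_pfm(out, path)


def read_disparity(path, view: str = "left") -> DisparityMap:
    """Read a PFM disparity map; non-finite entries become INVALID."""
    data = read_pfm(path)
    valid = np.isfinite(data)
    return DisparityMap(np.where(valid, data, INVALID), valid, view)


# --------------------------------------------------------------------------
# PLY
# --------------------------------------------------------------------------

def write_ply(points: np.ndarray, colors: np.ndarray, path, binary: bool = True) -> None:
    """Write an N x 3 point cloud (mm) with [0, 1] RGB colors to PLY.

    Raises on non-finite coordinates; an empty cloud produces a valid
    zero-vertex file with a logged warning.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    colors = np.asarray(colors, dtype=np.float64).reshape(-1, 3)
    if points.shape != colors.shape:
        raise ValueError("points and colors must both be N x 3")
    if points.size and not np.isfinite(points).all():
        raise ValueError("point cloud contains non-finite coordinates")
    if points.shape[0] == 0:
        log.warning("writing empty point cloud to %s", path)
    rgb = np.clip(np.round(colors * 255.0), 0, 255).astype(np.uint8)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        f"ply\nformat {fmt} 1.0\nelement vertex {points.shape[0]}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            for p, c in zip(points.astype(np.float32), rgb):
                fh.write(struct.pack("<fffBBB", p[0], p[1], p[2], c[0], c[1], c[2]))
        else:
            for p, c in zip(points, rgb):
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c[0]} {c[1]} {c[2]}\n".encode())


def read_ply(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PLY written by :func:`write_ply`; returns (points, colors01)."""
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ValueError(f"not a PLY file: {path}")
        fmt = None
        n = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("PLY header truncated")
            parts = line.split()
            if parts[0] == b"format":
                fmt = parts[1].decode()
            elif parts[0] == b"element" and parts[1] == b"vertex":
                n = int(parts[2])
            elif parts[0] == b"end_header":
                break
        if fmt not in ("ascii", "binary_little_endian") or n is None:
            raise ValueError(f"unsupported PLY layout in {path}")
        points = np.empty((n, 3), dtype=np.float64)
        colors = np.empty((n, 3), dtype=np.float64)
        if fmt == "binary_little_endian":
            rec = struct.Struct("<fffBBB")
            for i in range(n):
                x, y, z, r, g, b = rec.unpack(fh.read(rec.size))
                points[i] = (x, y, z)
                colors[i] = (r, g, b)
        else:
            for i in range(n):
                vals = fh.readline().split()
                points[i] = [float(v) for v in vals[:3]]
                colors[i] = [float(v) for v in vals[3:6]]
    return points, colors / 255.0
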