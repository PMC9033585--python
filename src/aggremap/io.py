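"""Calibrated multi-channel images: container, TIFF round-trip, projection, crops.

Conventions used throughout the package:

* coordinates are 0-based with ``x`` = column and ``y`` = row, pixel-center;
* all distances are Euclidean in pixel units;
* every channel is stored as a ``(Z, Y, X)`` stack, with ``Z = 1`` for plain
  2-D images, so downstream code never branches on dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile


@dataclass
class ImageField:
    """One calibrated multi-channel field of view.

    ``channels`` maps channel name to a ``(Z, Y, X)`` float array; 2-D input
    arrays are promoted to a single-plane stack. All channels must share one
    raster shape, intensities must be finite and non-negative, and
    ``pixel_size_um`` must be positive.
    """

    channels: dict
    pixel_size_um: float
    field_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        norm = {}
        shape = None
        for name, arr in self.channels.items():
            a = np.asarray(arr)
            if a.ndim == 2:
                a = a[None, :, :]
            if a.ndim != 3:
                raise ValueError(f"channel {name!r} must be 2-D or 3-D")
            if not np.issubdtype(a.dtype, np.number):
                raise ValueError(f"channel {name!r} is non-numeric")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {name!r} has non-finite values")
            if a.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError("channels have mismatched raster shapes")
            norm[name] = a
        self.channels = norm

    # -- basic accessors --------------------------------------------------
    @property
    def channel_names(self) -> list:
        return list(self.channels)

    @property
    def n_planes(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> tuple:
        """(Y, X) raster shape."""
        return next(iter(self.channels.values())).shape[1:]

    def plane(self, channel: str, z: int) -> np.ndarray:
        return self._get(channel)[z]

    def projection(self, channel: str) -> np.ndarray:
        """Per-pixel maximum over z; identity for single-plane channels."""
        return self._get(channel).max(axis=0)

    def _get(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel]
        except KeyError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def subset(self, names: Iterable[str]) -> "ImageField":
        return ImageField({n: self._get(n) for n in names},
                          self.pixel_size_um, self.field_id, self.condition)


def read_image(path: str | Path, calibration: float,
               channel_names: Sequence[str], *,
               field_id: str = "", condition: str = "") -> ImageField:
    """Read a multi-channel TIFF written as ``(C, Y, X)`` or ``(C, Z, Y, X)``.

    ``calibration`` is the pixel size in µm/pixel; the TIFF carries no
    calibration of its own. ``channel_names`` must match the leading axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim not in (3, 4):
        raise ValueError(f"expected (C[,Z],Y,X) TIFF, got shape {data.shape}")
    if data.shape[0] != len(channel_names):
        raise ValueError(
            f"channel-count mismatch: file has {data.shape[0]} channels, "
            f"{len(channel_names)} names given")
    channels = {name: data[i] for i, name in enumerate(channel_names)}
    return ImageField(channels, calibration, field_id=field_id or path.stem,
                      condition=condition)


def write_image(field: ImageField, path: str | Path) -> None:
    """Write all channels to one TIFF, ``(C, Y, X)`` or ``(C, Z, Y, X)``."""
    stacks = [field.channels[n] for n in field.channel_names]
    data = np.stack(stacks, axis=0)
    if field.n_planes == 1:
        data = data[:, 0]
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def max_project(field: ImageField) -> ImageField:
    """Maximum-intensity projection over z for every channel."""
    if field.n_planes == 1:
        return field
    return ImageField({n: field.projection(n) for n in field.channel_names},
                      field.pixel_size_um, field.field_id, field.condition)


def crop_centered(field: ImageField, center: tuple, size_um: float) -> ImageField:
    """Square crop of side ``round(size_um / pixel_size_um)`` px around a point.

    ``center`` is ``(x, y)`` in pixels and must lie inside the raster.
    Portions of the window outside the raster are zero-padded so every crop
    has the same shape regardless of position. Calibration is preserved.
    """
    side = int(round(size_um / field.pixel_size_um))
    if side < 1:
        raise ValueError("crop smaller than one pixel")
    ny, nx = field.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError(f"crop center {center} outside raster {nx}x{ny}")
    x0 = cx - side // 2
    y0 = cy - side // 2
    out = {}
    for name in field.channel_names:
        stack = field.channels[name]
        dst = np.zeros((stack.shape[0], side, side), dtype=float)
        sy0, sy1 = max(y0, 0), min(y0 + side, ny)
        sx0, sx1 = max(x0, 0), min(x0 + side, nx)
        dst[:, sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = stack[:, sy0:sy1, sx0:sx1]
        out[name] = dst
    return ImageField(out, field.pixel_size_um, field.field_id, field.condition)
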