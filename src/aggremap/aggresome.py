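"""Aggresome segmentation and morphometry.

The aggresome is segmented by expanding outward from each centrosome seed on
the aggresome-marker channel (pHSP27) with a seeded watershed. The channel is
first background-subtracted at its lower quartile; expansion is bounded by an
Otsu foreground mask of the subtracted channel so that every region has a
well-defined area. The readouts are the region area (px² and µm²) and the
background-corrected total intensity, plus a configurable aggresome-positive
call on area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .foci import FociSet
from .io import ImageField


@dataclass
class AggresomeMeasurement:
    seed: tuple                   # (x, y) px
    label_mask: np.ndarray        # boolean raster
    area_px: int
    area_um2: float
    total_intensity: float        # background-corrected
    field_id: str = ""
    condition: str = ""


def subtract_background_lq(raster: np.ndarray) -> np.ndarray:
    """Subtract the image's lower quartile, clamping at zero.

    The 25th percentile (linear-interpolation quantile over all pixels) is
    the background estimate; output = max(0, value - Q1).
    """
    raster = np.asarray(raster, dtype=float)
    if raster.size == 0:
        raise ValueError("empty raster")
    q1 = np.percentile(raster, 25)
    return np.clip(raster - q1, 0.0, None)


def _otsu_foreground(img: np.ndarray) -> np.ndarray:
    """Otsu foreground of a background-subtracted raster; empty if flat."""
    if np.allclose(img, img.flat[0]):
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img)


def segment_aggresomes(field: ImageField, seeds: FociSet, channel: str,
                       ) -> list:
    """Watershed each seed's aggresome territory on the marker channel.

    Foreground is the Otsu mask of the lower-quartile-subtracted projection;
    the watershed floods inverted intensity from the seed markers and
    partitions the foreground among them. A seed outside the foreground gets
    area 0. Returns one :class:`AggresomeMeasurement` per seed, in seed order.
    """
    if len(seeds) == 0:
        raise ValueError("need at least one seed")
    img = subtract_background_lq(field.projection(channel))
    fg = _otsu_foreground(img)
    ny, nx = img.shape
    markers = np.zeros(img.shape, dtype=np.int32)
    seed_px = []
    for i, (x, y, _w) in enumerate(seeds.foci, start=1):
        r, c = int(np.round(y)), int(np.round(x))
        r, c = np.clip(r, 0, ny - 1), np.clip(c, 0, nx - 1)
        seed_px.append((r, c))
        markers[r, c] = i
    mask = fg | (markers > 0)          # a seed always belongs to its region
    labels = watershed(-img, markers, mask=mask)
    px_area = field.pixel_size_um ** 2
    out = []
    for i, (x, y, _w) in enumerate(seeds.foci, start=1):
        region = labels == i
        # keep only the connected territory containing the seed
        if region.any():
            comp, _ = ndimage.label(region)
            keep = comp[seed_px[i - 1]]
            region = comp == keep if keep > 0 else np.zeros_like(region)
        area = int(region.sum())
        if area <= 1 and not fg[seed_px[i - 1]]:
            region = np.zeros_like(region)   # bare seed pixel, no foreground
            area = 0
        out.append(AggresomeMeasurement(
            seed=(float(x), float(y)), label_mask=region, area_px=area,
            area_um2=area * px_area,
            total_intensity=float(img[region].sum()),
            field_id=field.field_id, condition=field.condition))
    return out


def classify_positive(measurement: AggresomeMeasurement,
                      min_area_um2: float) -> bool:
    """Aggresome-positive call: area_um2 >= min_area_um2 (inclusive)."""
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    return bool(measurement.area_um2 >= min_area_um2)
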