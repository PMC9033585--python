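"""Pearson colocalization on aggresome-centred crops, per z-plane.

Each field is cropped to a 7.5 × 7.5 µm square centred on the aggresome seed
(the merged centrosome focus), and the Pearson correlation coefficient of
every requested channel pair is computed on each z-plane of the crop.
Planes on which either channel is constant carry no correlation information
and are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ImageField, crop_centered

logger = logging.getLogger(__name__)

MIN_IMAGES_PER_PAIR = 10


class ZeroVarianceError(ValueError):
    """Raised when a channel is constant over the region of interest."""


@dataclass
class ColocResult:
    channel_pair: tuple
    per_plane_r: list
    field_id: str = ""


def pearson_coloc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shape rasters.

    r = Σ(aᵢ−ā)(bᵢ−b̄) / sqrt(Σ(aᵢ−ā)² · Σ(bᵢ−b̄)²), in [−1, 1].
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("rasters must have identical shapes")
    da, db = a - a.mean(), b - b.mean()
    va, vb = (da * da).sum(), (db * db).sum()
    if va == 0 or vb == 0:
        raise ZeroVarianceError("constant channel: correlation undefined")
    r = float((da * db).sum() / np.sqrt(va * vb))
    return float(np.clip(r, -1.0, 1.0))


def coloc_pipeline(field: ImageField, center: tuple, pairs: list,
                   crop_size_um: float = 7.5) -> list:
    """Crop around ``center`` and correlate each channel pair per z-plane.

    Planes failing the nonzero-variance precondition are skipped and logged;
    the result for a pair holds one coefficient per retained plane.
    """
    crop = crop_centered(field, center, crop_size_um)
    out = []
    for pair in pairs:
        ca, cb = pair
        rs = []
        for z in range(crop.n_planes):
            try:
                rs.append(pearson_coloc(crop.plane(ca, z), crop.plane(cb, z)))
            except ZeroVarianceError:
                logger.info("skipping zero-variance plane %d of %s/%s in %s",
                            z, ca, cb, field.field_id)
        out.append(ColocResult((ca, cb), rs, field.field_id))
    return out
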