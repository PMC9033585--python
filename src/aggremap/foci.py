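"""Centrosome seed detection from the centriole-marker channel.

The centriole marker (CEP135 by default) shows as diffraction-limited spots.
Spots are found with Laplacian-of-Gaussian blob detection, near-duplicates —
the two centrioles of one centrosome, or split detections — are merged when
strictly closer than the merge distance (8 px by default), and each merged
focus is finally shrunk to a single integer pixel so it can seed the
watershed and the region masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from skimage.feature import blob_log

from .io import ImageField


@dataclass
class FociSet:
    """Detected foci: ``(x, y, total_intensity)`` triples plus their source."""

    foci: list                      # of (x, y, intensity)
    source_channel: str = ""

    def __len__(self) -> int:
        return len(self.foci)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions; empty-safe."""
        if not self.foci:
            return np.empty((0, 2))
        return np.array([(f[0], f[1]) for f in self.foci], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([f[2] for f in self.foci], dtype=float)


def detect_foci(field: ImageField, channel: str, *, min_sigma: float = 1.0,
                max_sigma: float = 3.0, threshold: float = 0.1) -> FociSet:
    """LoG spot detection on the max projection of ``channel``.

    ``threshold`` is relative to the channel maximum (an all-zero channel
    yields an empty set). Each focus's intensity is the raster sum inside a
    disc of radius ``2·sigma`` around the detection.
    """
    if not 0 < min_sigma <= max_sigma:
        raise ValueError("need 0 < min_sigma <= max_sigma")
    img = field.projection(channel).astype(float)
    peak = img.max()
    if peak <= 0:
        return FociSet([], channel)
    blobs = blob_log(img / peak, min_sigma=min_sigma, max_sigma=max_sigma,
                     num_sigma=5, threshold=threshold)
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    out = []
    for y, x, sigma in blobs:
        r = max(2.0 * sigma, 2.0)
        disc = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
        out.append((float(x), float(y), float(img[disc].sum())))
    return FociSet(out, channel)


def _cluster_once(xy: np.ndarray, w: np.ndarray, merge_distance: float):
    """One single-linkage pass: components of the d < merge_distance graph."""
    n = len(xy)
    d = squareform(pdist(xy))
    adj = coo_matrix(d < merge_distance)
    n_comp, labels = connected_components(adj, directed=False)
    pos = np.zeros((n_comp, 2))
    wt = np.zeros(n_comp)
    for k in range(n_comp):
        m = labels == k
        wk = w[m]
        tot = wk.sum()
        if tot > 0:
            pos[k] = (xy[m] * wk[:, None]).sum(axis=0) / tot
        else:                       # zero-intensity cluster: plain mean
            pos[k] = xy[m].mean(axis=0)
        wt[k] = tot
    return n_comp < n, pos, wt


def merge_foci(foci: FociSet, merge_distance: float = 8.0) -> FociSet:
    """Merge foci strictly closer than ``merge_distance`` px.

    Single-linkage clusters are collapsed to their intensity-weighted
    centroid with summed intensity; the pass is repeated until no pair lies
    below the threshold (collapsing can create new close pairs), so the
    result is idempotent and all pairwise distances are >= merge_distance.
    """
    if merge_distance <= 0:
        raise ValueError("merge_distance must be > 0")
    if len(foci) <= 1:
        return FociSet(list(foci.foci), foci.source_channel)
    xy, w = foci.xy, foci.intensities
    changed = True
    while changed and len(xy) > 1:
        changed, xy, w = _cluster_once(xy, w, merge_distance)
    merged = [(float(x), float(y), float(i)) for (x, y), i in zip(xy, w)]
    merged.sort()
    return FociSet(merged, foci.source_channel)


def shrink_to_points(foci: FociSet) -> FociSet:
    """Map each focus to its nearest integer pixel (round-half-to-even).

    Distinct foci landing on the same pixel collapse into one with summed
    intensity.
    """
    acc: dict = {}
    for x, y, w in foci.foci:
        key = (int(np.round(x)), int(np.round(y)))
        acc[key] = acc.get(key, 0.0) + float(w)
    pts = sorted((float(x), float(y), w) for (x, y), w in acc.items())
    return FociSet(pts, foci.source_channel)
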