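"""Synthetic fluorescence microscopy with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be validated against known truth without any
raw-image download:

* a cell disc containing one centrosome (a pair — optionally two pairs — of
  diffraction-limited centriole spots in the centriole channel);
* a pericentrosomal aggresome in the aggresome channel: a disc of
  controllable radius in the wild-type-like condition, or a thin ring hugging
  each centriole in the knockout-like condition (the phenotype seen when
  satellite trafficking is lost), growing over a simulated time course;
* satellite puncta in the satellite channel, either clustered around the
  centrosome (isotropic Gaussian truncated to the cell disc) or dispersed
  uniformly over the cell; the knockout-like condition has none;
* an aggresome-sharing second marker channel (``ub``, emulating ubiquitin
  co-staining) and a signal-free ``noise`` control channel for
  colocalization contrasts;
* Gaussian PSF blur followed by Poisson shot noise and additive Gaussian
  read noise on a constant background.

Ground truth (seed positions, aggresome mask and area, satellite records) is
recorded pre-noise. A fixed seed reproduces fields bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import AnalysisConfig
from .io import ImageField

WT_LIKE = "wt"
KO_LIKE = "ko"
DISPERSED = "dispersed"
CONDITIONS = (WT_LIKE, KO_LIKE, DISPERSED)


@dataclass
class GroundTruth:
    """Pre-noise truth for one synthetic field."""

    centrosome_positions: list       # merged-seed (x, y) px, one per pair
    centriole_positions: list        # individual spot (x, y) px
    aggresome_mask: np.ndarray       # boolean raster
    aggresome_area_um2: float
    satellite_records: list          # of (position (x, y), intensity, inner)
    condition: str

    @property
    def aggresome_area_px(self) -> int:
        return int(self.aggresome_mask.sum())


def _disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2


def _gauss_spot(shape, center, amp, sigma):
    """Analytic 2-D Gaussian bump (not an impulse through the PSF)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    return amp * np.exp(-d2 / (2.0 * sigma ** 2))


def sample_satellite_positions(center: tuple, n: int, condition: str,
                               rng: np.random.Generator, *,
                               cell_radius: float,
                               cluster_sigma: float,
                               min_separation: float = 0.0) -> np.ndarray:
    """Draw satellite positions for a condition.

    Clustered (wild-type-like): isotropic Gaussian of ``cluster_sigma``
    around the centrosome, truncated to the cell disc. Dispersed: uniform on
    the cell disc. ``min_separation`` > 0 enforces discrete granules by
    rejection sampling.
    """
    if condition == KO_LIKE or n == 0:
        return np.empty((0, 2))
    pts = []
    attempts = 0
    max_attempts = 1000 * max(n, 1)
    while len(pts) < n and attempts < max_attempts:
        attempts += 1
        if condition == DISPERSED:
            r = cell_radius * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            p = (center[0] + r * math.cos(th), center[1] + r * math.sin(th))
        else:
            p = tuple(rng.normal(loc=center, scale=cluster_sigma))
            if math.hypot(p[0] - center[0], p[1] - center[1]) > cell_radius:
                continue
        if min_separation > 0 and any(
                math.hypot(p[0] - q[0], p[1] - q[1]) < min_separation
                for q in pts):
            continue
        pts.append(p)
    if len(pts) < n:
        raise ValueError("could not place satellites at requested separation")
    return np.array(pts)


def _aggresome_mask(config: AnalysisConfig, condition: str, center,
                    centrioles, radius_px: float, shape):
    if radius_px <= 0:
        return np.zeros(shape, dtype=bool)
    if condition == KO_LIKE:
        # thin ring hugging each centriole
        mask = np.zeros(shape, dtype=bool)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        for cx, cy in centrioles:
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            mask |= ((d2 >= config.ring_inner_px ** 2)
                     & (d2 <= config.ring_outer_px ** 2))
        return mask
    return _disc_mask(shape, center, radius_px)


def _apply_noise(clean: np.ndarray, config: AnalysisConfig,
                 rng: np.random.Generator) -> np.ndarray:
    img = clean
    if config.psf_sigma_px > 0:
        img = gaussian_filter(img, config.psf_sigma_px)
    img = img + config.background_level
    if config.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if config.read_noise_sigma > 0:
        img = img + rng.normal(0, config.read_noise_sigma, img.shape)
    return np.clip(img, 0.0, None)


def generate_field(config: AnalysisConfig, condition: str, rng_seed: int,
                   *, aggresome_radius_px: float | None = None,
                   n_satellites: int | None = None,
                   center: tuple | None = None,
                   field_id: str = "") -> tuple:
    """Generate one multi-channel field and its ground truth.

    Channels: ``cep135`` (centriole spots), ``phsp27`` (aggresome), ``ub``
    (co-stains the aggresome), ``pcm1`` (satellites), ``noise`` (background
    only — a null control for colocalization). Identical seeds give
    bit-identical output.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(rng_seed)
    n = config.raster_size
    shape = (n, n)
    radius = (config.aggresome_radius_px if aggresome_radius_px is None
              else aggresome_radius_px)
    if 2 * radius >= n:
        raise ValueError("aggresome larger than the raster")
    if 2 * config.cell_radius_px > 1.5 * n:
        raise ValueError("cell larger than the raster")
    n_sat = config.n_satellites if n_satellites is None else n_satellites

    # centrosome: 1 or 2 centriole pairs near the field centre
    if center is None:
        center = (n / 2.0 + rng.uniform(-5, 5), n / 2.0 + rng.uniform(-5, 5))
    n_pairs = max(1, config.n_centriole_foci // 2)
    pair_centers = [center]
    if n_pairs == 2:
        off = config.centriole_pair_sep_px * 2.5
        pair_centers = [(center[0] - off, center[1]),
                        (center[0] + off, center[1])]
    centrioles = []
    for pc in pair_centers:
        th = rng.uniform(0, 2 * math.pi)
        dx = 0.5 * config.centriole_pair_sep_px * math.cos(th)
        dy = 0.5 * config.centriole_pair_sep_px * math.sin(th)
        centrioles += [(pc[0] - dx, pc[1] - dy), (pc[0] + dx, pc[1] + dy)]

    cep = np.zeros(shape)
    for c in centrioles:
        cep += _gauss_spot(shape, c, config.centriole_amp,
                           config.centriole_sigma_px)

    agg_mask = _aggresome_mask(config, condition, center, centrioles,
                               radius, shape)
    agg = np.where(agg_mask, config.aggresome_amp, 0.0)
    ub = 0.6 * agg

    sat_pos = sample_satellite_positions(
        center, n_sat, condition, rng, cell_radius=config.cell_radius_px,
        cluster_sigma=config.satellite_cluster_sigma_px,
        min_separation=config.satellite_min_sep_px)
    pcm = np.zeros(shape)
    sat_records = []
    for p in sat_pos:
        spot = _gauss_spot(shape, p, config.satellite_amp,
                           config.satellite_sigma_px)
        pcm += spot
        inner = math.hypot(p[0] - center[0], p[1] - center[1]) <= 13.0
        sat_records.append(((float(p[0]), float(p[1])), float(spot.sum()),
                            bool(inner)))
    # dim nonspecific puncta present in every condition (the only objects in
    # the satellite channel of knockout-like fields); not part of the truth
    # satellite list — the knockout-based correction exists to remove them
    for _ in range(config.spurious_count):
        r = config.cell_radius_px * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        p = (center[0] + r * math.cos(th), center[1] + r * math.sin(th))
        pcm += _gauss_spot(shape, p, config.spurious_amp,
                           config.satellite_sigma_px)

    clean = {"cep135": cep, "phsp27": agg, "ub": ub, "pcm1": pcm,
             "noise": np.zeros(shape)}
    channels = {}
    for name, plane in clean.items():
        if config.n_z_planes > 1:
            mid = (config.n_z_planes - 1) / 2.0
            stack = [
                _apply_noise(plane * math.exp(
                    -((z - mid) ** 2) / (2 * config.z_focus_sigma ** 2)),
                    config, rng)
                for z in range(config.n_z_planes)]
            channels[name] = np.stack(stack)
        else:
            channels[name] = _apply_noise(plane, config, rng)

    field = ImageField(channels, config.pixel_size_um,
                       field_id=field_id or f"{condition}-{rng_seed}",
                       condition=condition)
    truth = GroundTruth(
        centrosome_positions=[tuple(map(float, pc)) for pc in pair_centers],
        centriole_positions=[tuple(map(float, c)) for c in centrioles],
        aggresome_mask=agg_mask,
        aggresome_area_um2=float(agg_mask.sum()) * config.pixel_size_um ** 2,
        satellite_records=sat_records,
        condition=condition)
    return field, truth


def timecourse_radius(config: AnalysisConfig, hours: float,
                      condition: str) -> float:
    """Aggresome radius at a given time: 0 before onset, then saturating.

    Wild-type-like growth ramps from the onset time to a maximum radius at
    the plateau time (square-root-in-time front, i.e. linear area growth);
    knockout-like fields keep only the small pericentriolar ring after onset.
    """
    if hours < config.onset_h:
        return 0.0
    if condition == KO_LIKE:
        return config.ring_outer_px           # ring geometry ignores radius
    frac = min(1.0, (hours - config.onset_h)
               / max(config.plateau_h - config.onset_h, 1e-9))
    return config.aggresome_radius_px * math.sqrt(frac)


def generate_timecourse(config: AnalysisConfig, hours: list, rng_seed: int,
                        condition: str = WT_LIKE) -> list:
    """One field per time point, following a single cell.

    The cell centre is drawn once so growing aggresome masks are nested and
    the ground-truth area is monotone non-decreasing in the wild-type-like
    condition; noise and satellites are re-drawn per time point.
    """
    if any(h < 0 for h in hours) or list(hours) != sorted(hours):
        raise ValueError("hours must be nonnegative and sorted")
    out = []
    ss = np.random.SeedSequence(rng_seed)
    n = config.raster_size
    placer = np.random.default_rng(ss.spawn(1)[0])
    center = (n / 2.0 + placer.uniform(-5, 5), n / 2.0 + placer.uniform(-5, 5))
    for h, child in zip(hours, ss.spawn(len(hours))):
        r = timecourse_radius(config, h, condition)
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        f, t = generate_field(config, condition, seed,
                              aggresome_radius_px=r, center=center,
                              field_id=f"{condition}-t{h}h")
        out.append((h, f, t))
    return out


def generate_plate(config: AnalysisConfig, colony_count: int,
                   rng_seed: int) -> tuple:
    """Synthetic crystal-violet plate scan.

    Dark colonies (Gaussian-blurred flat discs) on a bright background with
    a smooth illumination gradient. Truth is the summed colony signal after
    inversion and before the gradient — exactly what masked, rolling-ball-
    subtracted quantification should recover.
    """
    if colony_count < 0:
        raise ValueError("colony_count must be >= 0")
    rng = np.random.default_rng(rng_seed)
    n = config.plate_size
    shape = (n, n)
    colony = np.zeros(shape)
    margin = 3 * config.colony_radius_px
    for _ in range(colony_count):
        c = rng.uniform(margin, n - margin, size=2)
        disc = _disc_mask(shape, c, config.colony_radius_px).astype(float)
        colony += config.colony_amp * disc
    if config.colony_edge_sigma_px > 0:
        colony = gaussian_filter(colony, config.colony_edge_sigma_px)
    truth = float(colony.sum())
    yy, xx = np.mgrid[0:n, 0:n]
    gradient = config.plate_gradient_amp * (
        0.5 * xx / n + 0.5 * yy / n)
    plate = config.plate_background + gradient - colony
    plate = plate + rng.normal(0, config.read_noise_sigma, shape)
    return np.clip(plate, 0.0, None), truth
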