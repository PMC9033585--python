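"""Pipeline configuration.

All spatial constants of the analysis live here: the 8-px centrosome-focus
merge distance, the 13-px inner pericentrosomal (PCM) disc, the 100-px outer
annulus expansion, the 7.5 µm colocalization crop and the 50-px rolling-ball
radius, together with the parameters of the synthetic-microscopy generator.
Distances are in pixels unless the name says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Constants of the measurement pipeline and the synthetic generator.

    Parameters
    ----------
    merge_distance_px:
        Centrosome foci strictly closer than this are merged into one seed.
    inner_expand_px:
        Radius (Euclidean, px) of the inner PCM disc around each seed.
    outer_expand_px:
        Further expansion defining the outer PCM annulus
        (inner < d <= inner + outer).
    crop_size_um:
        Side of the square colocalization crop, in micrometres.
    rolling_ball_radius_px:
        Radius of the rolling-ball background estimator for plate scans.
    channel_roles:
        Map role -> channel name (``centriole``, ``aggresome``, ``satellite``).
    """

    # --- measurement constants ------------------------------------------
    merge_distance_px: float = 8.0
    inner_expand_px: float = 13.0
    outer_expand_px: float = 100.0
    crop_size_um: float = 7.5
    rolling_ball_radius_px: int = 50
    min_area_um2: float = 1.0              # aggresome-positive call threshold
    adaptive_window_px: int = 51           # adaptive-Otsu tile size
    min_object_px: int = 3                 # smallest satellite object kept
    measure_dilation_px: int = 2           # footprint expansion for intensity
    hexbin_width_px: float = 5.0
    detect_min_sigma: float = 1.0
    detect_max_sigma: float = 3.0
    detect_threshold: float = 0.1          # relative to channel max
    channel_roles: dict = field(default_factory=lambda: {
        "centriole": "cep135",
        "aggresome": "phsp27",
        "satellite": "pcm1",
    })

    # --- synthetic-generator conditions ---------------------------------
    raster_size: int = 256
    pixel_size_um: float = 0.1
    n_centriole_foci: int = 2
    centriole_pair_sep_px: float = 4.0
    centriole_amp: float = 500.0
    centriole_sigma_px: float = 1.5
    aggresome_radius_px: float = 20.0
    aggresome_amp: float = 200.0
    ring_inner_px: float = 2.0             # KO-like pericentriolar ring
    ring_outer_px: float = 4.0
    cell_radius_px: float = 100.0
    n_satellites: int = 30
    satellite_cluster_sigma_px: float = 10.0
    satellite_amp: float = 300.0
    satellite_sigma_px: float = 1.2
    satellite_min_sep_px: float = 5.0
    spurious_count: int = 4                # nonspecific dim puncta, all conditions
    spurious_amp: float = 60.0
    psf_sigma_px: float = 1.0
    background_level: float = 10.0
    read_noise_sigma: float = 2.0
    poisson_noise: bool = True
    n_z_planes: int = 1
    z_focus_sigma: float = 2.0             # planes of defocus attenuation
    # time-course shape (hours)
    onset_h: float = 2.0
    plateau_h: float = 5.0
    # plate generator
    plate_size: int = 200
    colony_radius_px: float = 6.0
    colony_amp: float = 120.0
    colony_edge_sigma_px: float = 1.0
    plate_background: float = 220.0
    plate_gradient_amp: float = 20.0

    def __post_init__(self) -> None:
        for name in ("merge_distance_px", "inner_expand_px", "outer_expand_px",
                     "crop_size_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rolling_ball_radius_px < 1:
            raise ValueError("rolling_ball_radius_px must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config, overriding defaults with keys found in the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
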