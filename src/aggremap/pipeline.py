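"""End-to-end helpers wiring the stages together for one or many fields.

These are the functions the CLI and the reproduction script call: seed
detection (detect → merge → shrink), per-field aggresome measurement, and
per-condition satellite cartography with knockout correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggresome import classify_positive, segment_aggresomes
from .coloc import coloc_pipeline
from .config import AnalysisConfig
from .foci import FociSet, detect_foci, merge_foci, shrink_to_points
from .io import ImageField
from .satellites import (correct_intensity, define_regions,
                         ko_reference_intensity, overlay_and_map,
                         segment_satellites)


def find_seeds(field: ImageField, config: AnalysisConfig) -> FociSet:
    """Centrosome seeds: LoG detection, 8-px merge, shrink to pixels."""
    channel = config.channel_roles["centriole"]
    raw = detect_foci(field, channel,
                      min_sigma=config.detect_min_sigma,
                      max_sigma=config.detect_max_sigma,
                      threshold=config.detect_threshold)
    return shrink_to_points(merge_foci(raw, config.merge_distance_px))


def measure_aggresomes(field: ImageField, config: AnalysisConfig,
                       seeds: FociSet | None = None) -> pd.DataFrame:
    """Aggresome morphometry rows for one field (empty if no seeds found)."""
    seeds = find_seeds(field, config) if seeds is None else seeds
    if len(seeds) == 0:
        return pd.DataFrame(columns=["field_id", "condition", "seed_x",
                                     "seed_y", "area_px", "area_um2",
                                     "total_intensity", "positive"])
    ms = segment_aggresomes(field, seeds, config.channel_roles["aggresome"])
    return pd.DataFrame([{
        "field_id": m.field_id, "condition": m.condition,
        "seed_x": m.seed[0], "seed_y": m.seed[1],
        "area_px": m.area_px, "area_um2": m.area_um2,
        "total_intensity": m.total_intensity,
        "positive": classify_positive(m, config.min_area_um2),
    } for m in ms])


def satellites_for_field(field: ImageField, config: AnalysisConfig,
                         seeds: FociSet | None = None) -> list:
    """Uncorrected satellite records for one field."""
    seeds = find_seeds(field, config) if seeds is None else seeds
    if len(seeds) == 0:
        return []
    regions = define_regions(seeds, field.shape, config.inner_expand_px,
                             config.outer_expand_px)
    return segment_satellites(field, config.channel_roles["satellite"],
                              regions,
                              adaptive_window_px=config.adaptive_window_px,
                              inner_expand_px=config.inner_expand_px,
                              min_object_px=config.min_object_px,
                              measure_dilation_px=config.measure_dilation_px)


def satellite_cartography(fields: list, config: AnalysisConfig,
                          ko_fields: list = (), n_replicates: int = 1):
    """Pooled, knockout-corrected satellite map across many cells.

    ``ko_fields`` (satellite-null condition) calibrate the scalar spurious-
    object correction. Returns ``(records, DensityMap)``; the normalizer is
    n_cells × n_replicates with one cell per field.
    """
    ko_recs = [satellites_for_field(f, config) for f in ko_fields]
    ko_ref = ko_reference_intensity(ko_recs)
    records = []
    for f in fields:
        records.extend(correct_intensity(satellites_for_field(f, config),
                                         ko_ref))
    normalizer = max(len(fields), 1) * n_replicates
    dmap = overlay_and_map(records, config.hexbin_width_px, normalizer)
    return records, dmap


def coloc_for_field(field: ImageField, config: AnalysisConfig, pairs: list,
                    seeds: FociSet | None = None) -> list:
    """Aggresome-centred colocalization; crop centre = brightest seed."""
    seeds = find_seeds(field, config) if seeds is None else seeds
    if len(seeds) == 0:
        return []
    best = int(np.argmax(seeds.intensities))
    center = tuple(seeds.xy[best])
    return coloc_pipeline(field, center, pairs, config.crop_size_um)


def records_to_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "field_id": r.field_id, "condition": r.condition,
        "x": r.centroid[0], "y": r.centroid[1],
        "dx": r.rel_position[0], "dy": r.rel_position[1],
        "region": r.region,
        "intensity_corrected": r.total_intensity_corrected,
    } for r in records])
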