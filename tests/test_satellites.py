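import math

import numpy as np
import pytest

from aggremap import (AnalysisConfig, FociSet, ImageField, SatelliteRecord,
                      correct_intensity, define_regions, generate_field,
                      ko_reference_intensity, overlay_and_map,
                      sample_satellite_positions, segment_satellites)
from aggremap import pipeline


def lattice_disc_count(radius):
    """Integer lattice points within Euclidean distance <= radius of origin."""
    r = int(math.ceil(radius))
    return sum(1 for dx in range(-r, r + 1) for dy in range(-r, r + 1)
               if dx * dx + dy * dy <= radius * radius)


class TestDefineRegions:
    def test_inner_count_matches_lattice_enumeration(self):
        seeds = FociSet([(100.0, 100.0, 1.0)])
        reg = define_regions(seeds, (201, 201), 13, 100)
        assert reg.inner_mask.sum() == lattice_disc_count(13)

    def test_two_distant_seeds_double_inner_area(self):
        seeds = FociSet([(150.0, 150.0, 1.0), (500.0, 500.0, 1.0)])
        reg = define_regions(seeds, (700, 700), 13, 100)
        assert reg.inner_mask.sum() == 2 * lattice_disc_count(13)

    def test_corner_seed_clipped(self):
        corner = define_regions(FociSet([(0.0, 0.0, 1.0)]), (300, 300), 13, 100)
        assert corner.inner_mask.sum() < lattice_disc_count(13)

    def test_masks_disjoint_and_seed_inner(self):
        seeds = FociSet([(40.0, 60.0, 1.0)])
        reg = define_regions(seeds, (120, 120), 13, 100)
        assert not (reg.inner_mask & reg.outer_mask).any()
        assert reg.inner_mask[60, 40]

    def test_annulus_width(self):
        reg = define_regions(FociSet([(200.0, 200.0, 1.0)]), (401, 401), 13, 100)
        both = reg.inner_mask | reg.outer_mask
        assert both.sum() == lattice_disc_count(113)


class TestSegmentSatellites:
    def test_clean_clustered_puncta_recovered(self, clean_config):
        cfg = AnalysisConfig(**{**clean_config.__dict__, "n_satellites": 20})
        field, truth = generate_field(cfg, "wt", 7)
        seeds = pipeline.find_seeds(field, cfg)
        reg = define_regions(seeds, field.shape)
        recs = segment_satellites(field, "pcm1", reg)
        matched = 0
        for (pos, _w, _inner) in truth.satellite_records:
            d = [math.hypot(r.centroid[0] - pos[0], r.centroid[1] - pos[1])
                 for r in recs]
            if d and min(d) <= 1.0:
                matched += 1
        assert matched >= 18

    def test_clean_intensity_close_to_truth(self, clean_config):
        cfg = AnalysisConfig(**{**clean_config.__dict__, "n_satellites": 20})
        field, truth = generate_field(cfg, "wt", 7)
        seeds = pipeline.find_seeds(field, cfg)
        recs = segment_satellites(field, "pcm1",
                                  define_regions(seeds, field.shape))
        meas = np.mean([r.total_intensity_corrected for r in recs])
        want = np.mean([w for _p, w, _i in truth.satellite_records])
        assert abs(meas - want) / want <= 0.10

    def test_ko_spurious_intensity_small_vs_wt(self, config):
        def total(cond, seed):
            field, _ = generate_field(config, cond, seed)
            recs = pipeline.satellites_for_field(field, config)
            return sum(r.total_intensity_corrected for r in recs)
        wt = np.mean([total("wt", 100 + i) for i in range(3)])
        ko = np.mean([total("ko", 200 + i) for i in range(3)])
        assert ko <= 0.05 * wt

    def test_all_zero_channel_gives_no_records(self):
        f = ImageField({"pcm1": np.zeros((80, 80))}, 0.1)
        reg = define_regions(FociSet([(40.0, 40.0, 1.0)]), (80, 80))
        assert segment_satellites(f, "pcm1", reg) == []

    def test_region_label_consistent_with_distance(self, config):
        field, _ = generate_field(config, "wt", 21)
        seeds = pipeline.find_seeds(field, config)
        recs = pipeline.satellites_for_field(field, config, seeds)
        for r in recs:
            d = math.hypot(*r.rel_position)
            assert r.region == ("inner" if d <= 13 else "outer")


def _rec(dx, dy, w, region=None):
    region = region or ("inner" if math.hypot(dx, dy) <= 13 else "outer")
    return SatelliteRecord((dx, dy), (dx, dy), region, w)


class TestCorrectIntensity:
    def test_zero_reference_is_identity(self):
        recs = [_rec(1, 1, 10.0), _rec(30, 0, 5.0)]
        out = correct_intensity(recs, 0.0)
        assert [r.total_intensity_corrected for r in out] == [10.0, 5.0]

    def test_below_reference_clamps_to_zero_but_keeps_record(self):
        out = correct_intensity([_rec(1, 1, 3.0)], 5.0)
        assert len(out) == 1
        assert out[0].total_intensity_corrected == 0.0

    def test_negative_reference_rejected(self):
        with pytest.raises(ValueError):
            correct_intensity([], -1.0)

    def test_ko_reference_is_mean_per_object(self):
        per_field = [[_rec(0, 0, 4.0)], [_rec(0, 0, 6.0)], []]
        assert ko_reference_intensity(per_field) == 5.0
        assert ko_reference_intensity([]) == 0.0

    def test_end_to_end_correction_recovers_true_amplitude(self, config):
        """Knockout calibration removes the spurious baseline from true puncta."""
        ko_fields = [generate_field(config, "ko", 300 + i)[0] for i in range(3)]
        ko_recs = [pipeline.satellites_for_field(f, config) for f in ko_fields]
        ko_ref = ko_reference_intensity(ko_recs)
        assert ko_ref > 0                       # spurious objects exist
        field, truth = generate_field(config, "wt", 77)
        recs = correct_intensity(
            pipeline.satellites_for_field(field, config), ko_ref)
        # match corrected records to true puncta
        matched = []
        for (pos, w, _i) in truth.satellite_records:
            d = [math.hypot(r.centroid[0] - pos[0], r.centroid[1] - pos[1])
                 for r in recs]
            if d and min(d) <= 2.0:
                matched.append(recs[int(np.argmin(d))].total_intensity_corrected)
        want = np.mean([w for _p, w, _i in truth.satellite_records]) - ko_ref
        assert abs(np.mean(matched) - want) / want <= 0.10


class TestOverlayAndMap:
    def test_all_inner_gives_100_percent(self):
        recs = [_rec(1, 0, 5.0), _rec(0, 2, 3.0)]
        assert overlay_and_map(recs).inner_percentage == 100.0

    def test_30_70_split(self):
        recs = [_rec(2, 0, 30.0), _rec(50, 0, 70.0)]
        assert overlay_and_map(recs).inner_percentage == pytest.approx(30.0)

    def test_normalizer_scales_bins_not_percentage(self):
        recs = [_rec(2, 0, 30.0), _rec(50, 0, 70.0)]
        a = overlay_and_map(recs, normalizer=1.0)
        b = overlay_and_map(recs, normalizer=2.0)
        np.testing.assert_allclose(b.bin_values, a.bin_values / 2)
        assert a.inner_percentage == b.inner_percentage

    def test_conservation_of_total_weight(self, rng):
        recs = [_rec(*rng.uniform(-80, 80, 2), rng.uniform(0, 9))
                for _ in range(200)]
        dm = overlay_and_map(recs, bin_width_px=5.0, normalizer=7.0)
        total = sum(r.total_intensity_corrected for r in recs)
        assert dm.bin_values.sum() * 7.0 == pytest.approx(total, rel=1e-6)

    def test_percentage_invariant_under_weight_rescaling(self, rng):
        recs = [_rec(*rng.uniform(-60, 60, 2), rng.uniform(1, 5))
                for _ in range(50)]
        scaled = [SatelliteRecord(r.centroid, r.rel_position, r.region,
                                  13.7 * r.total_intensity_corrected)
                  for r in recs]
        assert (overlay_and_map(recs).inner_percentage
                == pytest.approx(overlay_and_map(scaled).inner_percentage))

    def test_empty_records(self):
        dm = overlay_and_map([])
        assert dm.inner_percentage == 0.0 and len(dm.bin_values) == 0

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError):
            overlay_and_map([_rec(0, 0, 1.0)], normalizer=0.0)


class TestDispersedLawOfLargeNumbers:
    def test_uniform_inner_fraction_matches_area_ratio(self, config):
        """At n = 10,000 the inner share converges to (13/R_cell)²."""
        rng = np.random.default_rng(99)
        pts = sample_satellite_positions(
            (0.0, 0.0), 10_000, "dispersed", rng,
            cell_radius=config.cell_radius_px,
            cluster_sigma=config.satellite_cluster_sigma_px,
            min_separation=0.0)
        inner = np.hypot(pts[:, 0], pts[:, 1]) <= 13.0
        analytic = (13.0 / config.cell_radius_px) ** 2
        assert abs(inner.mean() - analytic) <= 0.02
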