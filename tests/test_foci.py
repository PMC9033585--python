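import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggremap import (FociSet, detect_foci, generate_field, merge_foci,
                      shrink_to_points)


def brute_force_merge(foci, d):
    """Naive fixed-point single-linkage merge: O(n²) closure per pass."""
    pts = [(x, y, w) for x, y, w in foci]
    while True:
        n = len(pts)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if math.hypot(pts[i][0] - pts[j][0],
                              pts[i][1] - pts[j][1]) < d:
                    parent[find(i)] = find(j)
        clusters = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(pts[i])
        merged = []
        for members in clusters.values():
            w = sum(m[2] for m in members)
            if w > 0:
                x = sum(m[0] * m[2] for m in members) / w
                y = sum(m[1] * m[2] for m in members) / w
            else:
                x = sum(m[0] for m in members) / len(members)
                y = sum(m[1] for m in members) / len(members)
            merged.append((x, y, w))
        if len(merged) == n:
            return sorted(merged)
        pts = merged


class TestMergeFoci:
    def test_equal_weights_merge_to_midpoint(self):
        got = merge_foci(FociSet([(0, 0, 1.0), (5, 0, 1.0)]), 8)
        assert got.foci == [(2.5, 0.0, 2.0)]

    def test_distance_exactly_at_threshold_not_merged(self):
        # "closer than" is strict: d = 8 keeps both
        got = merge_foci(FociSet([(0, 0, 1.0), (8, 0, 1.0)]), 8)
        assert len(got) == 2

    def test_empty_set(self):
        assert merge_foci(FociSet([]), 8).foci == []

    def test_intensity_weighted_centroid(self):
        got = merge_foci(FociSet([(0, 0, 3.0), (4, 0, 1.0)]), 8)
        assert got.foci == [(1.0, 0.0, 4.0)]

    def test_idempotent(self, rng):
        foci = FociSet([tuple(rng.uniform(0, 50, 2)) + (rng.uniform(1, 5),)
                        for _ in range(30)])
        once = merge_foci(foci, 8)
        twice = merge_foci(once, 8)
        assert once.foci == twice.foci

    def test_pairwise_distance_invariant(self, rng):
        foci = FociSet([tuple(rng.uniform(0, 40, 2)) + (1.0,)
                        for _ in range(25)])
        xy = merge_foci(foci, 8).xy
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                assert np.hypot(*(xy[i] - xy[j])) >= 8

    def test_order_invariance(self, rng):
        pts = [tuple(rng.uniform(0, 30, 2)) + (rng.uniform(1, 3),)
               for _ in range(15)]
        a = merge_foci(FociSet(pts), 8).foci
        b = merge_foci(FociSet(pts[::-1]), 8).foci
        np.testing.assert_allclose(a, b, atol=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 20))
        pts = [tuple(rng.uniform(0, 60, 2)) + (float(rng.uniform(0.5, 4)),)
               for _ in range(n)]
        got = merge_foci(FociSet(pts), 8).foci
        want = brute_force_merge(pts, 8)
        np.testing.assert_allclose(got, want, atol=1e-8)


class TestShrinkToPoints:
    def test_round_half_to_even(self):
        got = shrink_to_points(FociSet([(2.5, 0.0, 1.0)]))
        assert got.foci == [(2.0, 0.0, 1.0)]

    def test_integer_coordinates_unchanged(self):
        got = shrink_to_points(FociSet([(3.0, 7.0, 2.0)]))
        assert got.foci == [(3.0, 7.0, 2.0)]

    def test_duplicates_collapse_with_summed_intensity(self):
        # enumeration: both round to (2, 1)
        got = shrink_to_points(FociSet([(2.2, 1.1, 1.0), (1.8, 0.9, 2.0)]))
        assert got.foci == [(2.0, 1.0, 3.0)]

    def test_count_preserved_without_collisions(self, rng):
        pts = [(float(3 * i), float(3 * i), 1.0) for i in range(10)]
        assert len(shrink_to_points(FociSet(pts))) == 10


class TestDetectFoci:
    def test_two_clean_spots_recovered(self, clean_config):
        field, truth = generate_field(clean_config, "wt", 3)
        got = detect_foci(field, "cep135", min_sigma=1, max_sigma=3,
                          threshold=0.1)
        merged = merge_foci(got, clean_config.merge_distance_px)
        assert len(merged) == 1           # one centriole pair -> one seed
        cx, cy = truth.centrosome_positions[0]
        x, y, _ = merged.foci[0]
        assert math.hypot(x - cx, y - cy) <= 1.0

    def test_all_zero_channel_gives_empty_set(self, config):
        from aggremap import ImageField
        f = ImageField({"c": np.zeros((32, 32))}, 0.1)
        assert len(detect_foci(f, "c")) == 0

    def test_unknown_channel(self, clean_config):
        field, _ = generate_field(clean_config, "wt", 3)
        with pytest.raises(KeyError):
            detect_foci(field, "nope")

    def test_detection_f1_at_default_snr(self, config):
        """Nearest-neighbor matching (<= 2 px) against generator truth."""
        tp = fp = fn = 0
        for seed in range(8):
            field, truth = generate_field(config, "wt", seed)
            got = merge_foci(detect_foci(field, "cep135"), 8)
            truths = list(truth.centrosome_positions)
            used = set()
            for x, y, _ in got.foci:
                d = [math.hypot(x - tx, y - ty) if i not in used else 99
                     for i, (tx, ty) in enumerate(truths)]
                if d and min(d) <= 2.0:
                    tp += 1
                    used.add(int(np.argmin(d)))
                else:
                    fp += 1
            fn += len(truths) - len(used)
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.9
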