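"""Unit tests for the raster landscape metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from landqgen import landscape as lsc
from landqgen.datatypes import LandscapeScene

from conftest import scene_from_raster
from oracles import brute_bmq, brute_shdi


def full_cover_buffer(scene):
    nrow, ncol = scene.raster.shape
    cx = ncol * scene.cell_size / 2
    cy = nrow * scene.cell_size / 2
    r = math.hypot(ncol, nrow) * scene.cell_size
    return lsc.BufferSpec((cx, cy), r)


class TestClassPercentages:
    def test_uniform_habitat_is_hundred_percent(self):
        scene = scene_from_raster(np.full((10, 10), 2))
        pct = lsc.class_percentages(scene, full_cover_buffer(scene))
        assert pct[2] == pytest.approx(100.0)

    def test_direct_count_toy(self, rng):
        raster = np.ones((10, 10), dtype=int)
        idx = rng.choice(100, size=37, replace=False)
        raster.ravel()[idx] = 2
        scene = scene_from_raster(raster)
        pct = lsc.class_percentages(scene, full_cover_buffer(scene))
        assert pct[2] == pytest.approx(37.0)

    def test_half_plane_split(self):
        raster = np.ones((200, 200), dtype=int)
        raster[:, 100:] = 2
        scene = scene_from_raster(raster)
        buf = lsc.BufferSpec((1000.0, 1000.0), 800.0)
        pct = lsc.class_percentages(scene, buf)
        assert pct[1] == pytest.approx(50.0, abs=1.0)
        assert pct[2] == pytest.approx(50.0, abs=1.0)

    def test_percentages_sum_to_hundred(self, rng):
        raster = rng.integers(1, 6, size=(50, 50))
        scene = scene_from_raster(raster)
        buf = lsc.BufferSpec((250.0, 250.0), 150.0)
        pct = lsc.class_percentages(scene, buf)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_composite_class_sums_members(self):
        raster = np.ones((10, 10), dtype=int)
        raster[:5] = 2
        raster[5:8] = 3
        scene = scene_from_raster(raster)
        pct = lsc.class_percentages(scene, full_cover_buffer(scene),
                                    composites={"open": [2, 3]})
        assert pct["open"] == pytest.approx(pct[2] + pct[3])

    def test_empty_intersection_rejected(self):
        scene = scene_from_raster(np.ones((10, 10), dtype=int))
        with pytest.raises(ValueError):
            lsc.class_percentages(scene, lsc.BufferSpec((1e6, 1e6), 50.0))


class TestDonut:
    def test_identical_composition_gives_zero(self):
        scene = scene_from_raster(np.full((50, 50), 2))
        v = lsc.donut_metric(scene, (250.0, 250.0), 100.0, 200.0, [2])
        assert v == pytest.approx(0.0)

    def test_habitat_only_inside_inner_is_negative(self):
        raster = np.ones((100, 100), dtype=int)
        raster[45:55, 45:55] = 2  # small central habitat block
        scene = scene_from_raster(raster)
        v = lsc.donut_metric(scene, (500.0, 500.0), 100.0, 400.0, [2])
        assert v < 0

    def test_matches_two_direct_counts(self, rng):
        raster = rng.integers(1, 4, size=(60, 60))
        scene = scene_from_raster(raster)
        center = (300.0, 300.0)
        inner = lsc.class_percentages(scene, lsc.BufferSpec(center, 120.0))
        outer = lsc.class_percentages(scene, lsc.BufferSpec(center, 250.0))
        want = outer.get(2, 0) - inner.get(2, 0)
        assert lsc.donut_metric(scene, center, 120.0, 250.0, [2]) == \
            pytest.approx(want, abs=1e-12)

    def test_inverted_radii_rejected(self):
        scene = scene_from_raster(np.ones((10, 10), dtype=int))
        with pytest.raises(ValueError):
            lsc.donut_metric(scene, (50.0, 50.0), 200.0, 100.0, [1])


class TestShannon:
    def test_single_class_zero(self):
        scene = scene_from_raster(np.full((20, 20), 3))
        assert lsc.shannon_heterogeneity(scene, full_cover_buffer(scene)) == 0.0

    def test_four_equal_classes(self):
        raster = np.repeat(np.arange(1, 5), 100).reshape(20, 20)
        scene = scene_from_raster(raster)
        shdi = lsc.shannon_heterogeneity(scene, full_cover_buffer(scene))
        assert shdi == pytest.approx(math.log(4), abs=1e-12)

    def test_known_proportions(self):
        # proportions (0.5, 0.3, 0.2) over 100 cells
        raster = np.concatenate([np.full(50, 1), np.full(30, 2),
                                 np.full(20, 3)]).reshape(10, 10)
        scene = scene_from_raster(raster)
        shdi = lsc.shannon_heterogeneity(scene, full_cover_buffer(scene))
        want = -(0.5 * math.log(0.5) + 0.3 * math.log(0.3) + 0.2 * math.log(0.2))
        assert shdi == pytest.approx(want, abs=1e-12)
        assert shdi == pytest.approx(1.0297, abs=1e-4)

    def test_matches_direct_evaluation(self, rng):
        raster = rng.integers(1, 7, size=(30, 30))
        scene = scene_from_raster(raster)
        buf = lsc.BufferSpec((150.0, 150.0), 100.0)
        mask = lsc.buffer_mask(scene, buf)
        want = brute_shdi(scene.raster[mask].tolist())
        assert lsc.shannon_heterogeneity(scene, buf) == pytest.approx(want, abs=1e-12)


class TestBMQ:
    def _scene(self, raster, qualities):
        codes = sorted(qualities)
        ct = pd.DataFrame({"code": codes, "name": [f"c{c}" for c in codes],
                           "quality": [qualities[c] for c in codes],
                           "groups": [""] * len(codes)})
        return scene_from_raster(raster, class_table=ct)

    def test_uniform_quality_one(self):
        scene = self._scene(np.ones((10, 10), dtype=int), {1: 1.0})
        assert lsc.buffer_matrix_quality(scene, full_cover_buffer(scene)) == 1.0

    def test_fifty_fifty_hand_value(self):
        raster = np.ones((10, 10), dtype=int)
        raster[5:] = 2
        scene = self._scene(raster, {1: 1.0, 2: 0.2})
        bmq = lsc.buffer_matrix_quality(scene, full_cover_buffer(scene))
        assert bmq == pytest.approx(0.6, abs=1e-12)

    def test_bounded_by_class_qualities(self, rng):
        raster = rng.integers(1, 5, size=(20, 20))
        q = {1: 0.2, 2: 0.5, 3: 0.8, 4: 1.0}
        scene = self._scene(raster, q)
        bmq = lsc.buffer_matrix_quality(scene, full_cover_buffer(scene))
        assert 0.2 <= bmq <= 1.0
        mask = lsc.buffer_mask(scene, full_cover_buffer(scene))
        want = brute_bmq(scene.raster[mask].tolist(), q)
        assert bmq == pytest.approx(want, abs=1e-12)

    def test_missing_quality_named_in_error(self):
        ct = pd.DataFrame({"code": [1, 2], "name": ["a", "b"],
                           "quality": [1.0, np.nan], "groups": ["", ""]})
        raster = np.ones((5, 5), dtype=int)
        raster[0, 0] = 2
        scene = scene_from_raster(raster, class_table=ct)
        with pytest.raises(KeyError, match="2"):
            lsc.buffer_matrix_quality(scene, full_cover_buffer(scene))


class TestConnectivity:
    def _patch_scene(self, cell):
        n = int(3000 / cell)
        raster = np.ones((n, n), dtype=int)
        half = int(500 / cell)
        c0 = n // 2
        raster[c0 - half:c0 + half, c0 - half:c0 + half] = 2
        return scene_from_raster(raster, cell_size=float(cell))

    def test_no_habitat_zero(self):
        scene = scene_from_raster(np.ones((50, 50), dtype=int))
        area, n = lsc.functional_connectivity(
            scene, full_cover_buffer(scene), [2], 500.0)
        assert area == 0.0 and n == 0

    def test_minkowski_convergence(self):
        analytic = (1e6 + 4 * 1000 * 500 + math.pi * 500 ** 2) / 1e4
        errors = []
        for cell in (20, 10, 5):
            scene = self._patch_scene(cell)
            buf = lsc.BufferSpec((1500.0, 1500.0), 1400.0)
            area, _ = lsc.functional_connectivity(scene, buf, [2], 500.0)
            errors.append(abs(area - analytic) / analytic)
        assert errors[1] < 0.02
        assert errors[2] < errors[1]

    def test_two_patches_within_reach_link_up(self):
        raster = np.ones((200, 200), dtype=int)
        raster[95:105, 40:50] = 2
        raster[95:105, 110:120] = 2  # gap of 600 m at 10 m cells
        scene = scene_from_raster(raster)
        buf = lsc.BufferSpec((1000.0, 1000.0), 900.0)
        _, n_components = lsc.functional_connectivity(scene, buf, [2], 500.0)
        assert n_components == 1

    def test_monotone_in_radius_and_habitat(self):
        rng = np.random.default_rng(3)
        raster = np.ones((100, 100), dtype=int)
        raster[rng.random((100, 100)) < 0.2] = 2
        scene = scene_from_raster(raster)
        buf = lsc.BufferSpec((500.0, 500.0), 450.0)
        a1, _ = lsc.functional_connectivity(scene, buf, [2], 100.0)
        a2, _ = lsc.functional_connectivity(scene, buf, [2], 300.0)
        assert a2 >= a1
        more = raster.copy()
        more[:10, :10] = 2
        scene2 = scene_from_raster(more)
        a3, _ = lsc.functional_connectivity(scene2, buf, [2], 100.0)
        assert a3 >= a1

    def test_corridor_variant_smaller_than_union(self):
        raster = np.ones((200, 200), dtype=int)
        raster[95:105, 40:50] = 2
        raster[95:105, 110:120] = 2
        scene = scene_from_raster(raster)
        buf = lsc.BufferSpec((1000.0, 1000.0), 900.0)
        union, _ = lsc.functional_connectivity(scene, buf, [2], 500.0)
        corridors, _ = lsc.functional_connectivity(
            scene, buf, [2], 500.0, variant="patches_plus_corridors")
        assert corridors < union


class TestScaleScreen:
    def test_duplicated_metric_keeps_smallest_scale(self, rng):
        base = rng.normal(size=5)
        rows = []
        for i in range(5):
            for r in (2000, 4000, 6000):
                rows.append({"landscape": f"L{i}", "radius": r,
                             "hab": base[i] + r * 1e-9,
                             "other": rng.normal()})
        kept = lsc.scale_of_effect_screen(pd.DataFrame(rows))
        assert "hab" in kept  # collapsed to the 2 km column

    def test_orthogonal_metrics_all_kept(self, rng):
        rows = []
        vals = rng.normal(size=(8, 2, 3))
        for i in range(8):
            for j, r in enumerate((2000, 4000, 6000)):
                rows.append({"landscape": f"L{i}", "radius": r,
                             "m1": vals[i, 0, j], "m2": vals[i, 1, j]})
        kept = lsc.scale_of_effect_screen(pd.DataFrame(rows))
        assert any(k.startswith("m1") for k in kept)
        assert any(k.startswith("m2") for k in kept)

    def test_too_few_observations_rejected(self, rng):
        rows = [{"landscape": "L1", "radius": 2000, "m": 1.0},
                {"landscape": "L2", "radius": 2000, "m": 2.0}]
        with pytest.raises(ValueError):
            lsc.scale_of_effect_screen(pd.DataFrame(rows))
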