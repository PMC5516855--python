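"""Semantic-zoom assignment and tile geometry."""

import math
import random

import pytest

from pathmap.errors import TileOutOfRange
from pathmap.model import ElementType, MapModel
from pathmap.zoom import (
    TileCoord,
    compute_semantic_zoom,
    cover_paint_order,
    max_native_zoom,
    tile_transform,
)

from conftest import geometric_depth_oracle, make_element, random_nested_area_model


def _two_disjoint_compartments():
    m = MapModel(map_id="m", width=400, height=200)
    m.add_element(make_element("c1", ElementType.COMPARTMENT, 10, 10, 180, 180))
    m.add_element(make_element("c2", ElementType.COMPARTMENT, 210, 10, 180, 180))
    return m


class TestComputeSemanticZoom:
    def test_disjoint_top_level_compartments_share_level_one(self):
        za = compute_semantic_zoom(_two_disjoint_compartments())
        assert za.reveal_level == {"c1": 1, "c2": 1}
        assert set(za.visible_covers(0)) == {"c1", "c2"}
        assert za.visible_covers(1) == []

    def test_nested_pair_levels_one_and_two(self):
        m = MapModel(map_id="m", width=400, height=300)
        m.add_element(make_element("c1", ElementType.COMPARTMENT, 10, 10, 380, 280))
        m.add_element(make_element("x1", ElementType.COMPLEX, 50, 50, 200, 150,
                                   compartment_ref="c1"))
        za = compute_semantic_zoom(m)
        assert za.reveal_level["c1"] == 1
        assert za.reveal_level["x1"] == 2
        assert za.n_levels == 3

    def test_no_candidate_areas_gives_empty_assignment(self):
        m = MapModel(map_id="m", width=100, height=100)
        m.add_element(make_element("p1", ElementType.PROTEIN, 10, 10, 50, 20))
        za = compute_semantic_zoom(m)
        assert za.reveal_level == {} and za.n_levels == 1

    def test_small_areas_filtered_by_cover_fraction(self):
        m = _two_disjoint_compartments()
        m.add_element(make_element("tiny", ElementType.COMPLEX, 50, 50, 4, 4,
                                   compartment_ref="c1"))
        za = compute_semantic_zoom(m, min_cover_fraction=0.002)
        assert "tiny" not in za.reveal_level  # 16 < 0.002 * 400 * 200

    @pytest.mark.parametrize("seed", range(10))
    def test_reveal_level_matches_pairwise_containment_oracle(self, seed):
        rng = random.Random(seed)
        m = random_nested_area_model(rng)
        za = compute_semantic_zoom(m, min_cover_fraction=0.0)
        assert za.reveal_level == geometric_depth_oracle(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_visibility_is_monotone_in_zoom(self, seed):
        rng = random.Random(100 + seed)
        m = random_nested_area_model(rng)
        za = compute_semantic_zoom(m, min_cover_fraction=0.0)
        for z in range(za.n_levels):
            # covers only disappear with zoom-in: the covered (hidden) set
            # shrinks, so visible content grows monotonically
            assert set(za.visible_covers(z + 1)) <= set(za.visible_covers(z))

    def test_reveal_level_strictly_increases_along_nesting(self):
        rng = random.Random(7)
        m = random_nested_area_model(rng)
        za = compute_semantic_zoom(m, min_cover_fraction=0.0)
        areas = {e.element_id: e for e in m.areas()}
        for a in areas.values():
            for b in areas.values():
                if a is not b and a.bounds.strictly_contains(b.bounds):
                    assert za.reveal_level[a.element_id] < za.reveal_level[b.element_id]


class TestCoverPaintOrder:
    def test_inner_painted_before_outer(self):
        m = MapModel(map_id="m", width=400, height=300)
        m.add_element(make_element("outer", ElementType.COMPARTMENT, 10, 10, 380, 280))
        m.add_element(make_element("inner", ElementType.COMPLEX, 50, 50, 100, 80))
        za = compute_semantic_zoom(m)
        assert cover_paint_order(za, m) == ["inner", "outer"]

    def test_same_depth_larger_area_on_top(self):
        m = MapModel(map_id="m", width=400, height=200)
        m.add_element(make_element("big", ElementType.COMPARTMENT, 10, 10, 100, 100))
        m.add_element(make_element("sml", ElementType.COMPARTMENT, 210, 10, 50, 100))
        za = compute_semantic_zoom(m)
        assert cover_paint_order(za, m) == ["sml", "big"]

    @pytest.mark.parametrize("seed", [3, 11])
    def test_order_matches_independent_sort_key(self, seed):
        rng = random.Random(seed)
        m = random_nested_area_model(rng)
        za = compute_semantic_zoom(m, min_cover_fraction=0.0)
        order = cover_paint_order(za, m)
        keys = [
            (-za.reveal_level[eid], m.elements[eid].bounds.area, eid)
            for eid in order
        ]
        assert keys == sorted(keys)


class TestTiles:
    def test_zoom_zero_tile_covers_whole_square(self):
        m = MapModel(map_id="m", width=800, height=600)
        b = tile_transform(m, 0, 0, 0)
        assert (b.x, b.y, b.w, b.h) == (0, 0, 800, 800)

    def test_max_native_zoom_of_1024_canvas(self):
        m = MapModel(map_id="m", width=1024, height=512)
        assert max_native_zoom(m, tile_px=256) == 2
        assert max_native_zoom(m, tile_px=1024) == 0

    def test_out_of_range_tile_rejected(self):
        m = MapModel(map_id="m", width=100, height=100)
        with pytest.raises(TileOutOfRange):
            tile_transform(m, 1, 2, 0)
        with pytest.raises(TileOutOfRange):
            TileCoord(0, 0, 1)

    @pytest.mark.parametrize("z", [0, 1, 2, 3])
    def test_tiles_partition_the_square_exactly(self, z):
        m = MapModel(map_id="m", width=640, height=480)
        side = 640.0
        tiles = [
            tile_transform(m, z, tx, ty)
            for tx in range(2**z)
            for ty in range(2**z)
        ]
        assert math.isclose(sum(t.area for t in tiles), side * side)
        for i, a in enumerate(tiles):
            for b in tiles[i + 1:]:
                assert not a.intersects(b)
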