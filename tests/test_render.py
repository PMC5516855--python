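"""Raster output: style lookups, semantic-zoom covers, tile consistency."""

import pytest

from pathmap.errors import EmptyRegion, TileOutOfRange
from pathmap.fixtures import generate_fixture_map
from pathmap.model import Bounds
from pathmap.overlay import OverlayDataset, OverlayEntry, match_entries
from pathmap.render import (
    RenderStyle,
    compartment_color,
    max_pixel_difference,
    render_full_square,
    render_region,
    render_tile,
    stitch_tiles,
)
from pathmap.zoom import TileCoord, compute_semantic_zoom


@pytest.fixture(scope="module")
def model():
    return generate_fixture_map(
        n_compartments=3, n_complexes=2, n_proteins=8, n_reactions=4,
        nesting_depth=2, n_text_areas=1, seed=7,
    )


@pytest.fixture(scope="module")
def assignment(model):
    return compute_semantic_zoom(model)


def _px(img, canvas_xy, scale=1.0):
    x, y = canvas_xy
    return img.getpixel((round(x * scale), round(y * scale)))


class TestRenderRegion:
    def test_zoom_zero_cover_pixel_is_compartment_palette_color(
        self, model, assignment
    ):
        img = render_region(
            model, Bounds(0, 0, model.width, model.height), 1.0,
            zoom_level=0, assignment=assignment,
        )
        style = RenderStyle()
        comp = model.elements["c2"]  # top-level, no nested chain inside
        expected = compartment_color(model, style, "c2")
        # sample below the centered label so we read the cover fill itself
        cx, cy = comp.bounds.center
        r, g, b = _px(img, (cx, cy + 20))
        assert "#{:02X}{:02X}{:02X}".format(r, g, b) == expected

    def test_max_zoom_has_no_covers_entity_fill_visible(self, model, assignment):
        img = render_region(
            model, Bounds(0, 0, model.width, model.height), 1.0,
            zoom_level=assignment.n_levels, assignment=assignment,
        )
        style = RenderStyle()
        protein = next(
            e for e in model.elements.values()
            if e.element_type.value == "PROTEIN" and e.parent_complex is None
        )
        cx, cy = protein.bounds.center
        r, g, b = _px(img, (cx, protein.bounds.y + 4))  # off the label
        assert "#{:02X}{:02X}{:02X}".format(r, g, b) == style.fill(
            protein.element_type
        )

    def test_overlay_color_applied_last(self, model):
        protein = next(
            e for e in model.elements.values()
            if e.element_type.value == "PROTEIN"
        )
        ds = OverlayDataset(entries=[
            OverlayEntry(name=protein.name, color="#123456"),
        ])
        binding = match_entries(ds, model)
        img = render_region(
            model, Bounds(0, 0, model.width, model.height), 1.0,
            overlays=[binding],
        )
        # sample off-center to avoid the label glyphs
        cx, cy = protein.bounds.center
        assert img.getpixel((round(cx), round(protein.bounds.y + 3))) == (
            0x12, 0x34, 0x56)

    def test_empty_bounds_raise(self, model):
        with pytest.raises(EmptyRegion):
            render_region(model, Bounds(0, 0, 0, 10), 1.0)

    def test_identical_inputs_render_byte_identically(self, model, assignment):
        a = render_region(model, Bounds(0, 0, 400, 300), 1.5,
                          zoom_level=1, assignment=assignment)
        b = render_region(model, Bounds(0, 0, 400, 300), 1.5,
                          zoom_level=1, assignment=assignment)
        assert a.tobytes() == b.tobytes()


class TestRenderTile:
    def test_tile_outside_map_extent_is_background_only(self, model, assignment):
        # map is wider than tall: bottom-right tile at z=2 is past the canvas
        img = render_tile(model, TileCoord(2, 3, 3), assignment, tile_px=128)
        assert set(img.getdata()) == {(0xFF, 0xFF, 0xFF)}

    def test_zoom_zero_tile_equals_full_square_render(self, model, assignment):
        tile = render_tile(model, TileCoord(0, 0, 0), assignment)
        full = render_full_square(model, 0, assignment)
        assert max_pixel_difference(tile, full) == 0

    def test_invalid_tile_coordinates_rejected(self):
        with pytest.raises(TileOutOfRange):
            TileCoord(1, 2, 0)

    @pytest.mark.parametrize("z", [0, 1, 2])
    def test_stitched_tiles_equal_full_square_render(self, model, assignment, z):
        tiles = {
            (tx, ty): render_tile(model, TileCoord(z, tx, ty), assignment,
                                  tile_px=128)
            for tx in range(2**z)
            for ty in range(2**z)
        }
        stitched = stitch_tiles(tiles, z, tile_px=128)
        full = render_full_square(model, z, assignment, tile_px=128)
        assert max_pixel_difference(stitched, full) == 0

    def test_any_tile_equals_crop_of_full_render(self, model, assignment):
        z, tpx = 2, 128
        full = render_full_square(model, z, assignment, tile_px=tpx)
        for tx, ty in [(0, 0), (1, 1), (2, 0), (3, 2)]:
            tile = render_tile(model, TileCoord(z, tx, ty), assignment,
                               tile_px=tpx)
            crop = full.crop((tx * tpx, ty * tpx, (tx + 1) * tpx, (ty + 1) * tpx))
            assert max_pixel_difference(tile, crop) == 0
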