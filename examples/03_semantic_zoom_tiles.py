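"""Compute the semantic-zoom assignment of a nested map and render its tile
pyramid for the first three zoom levels."""

from pathmap import TileCoord, compute_semantic_zoom, generate_fixture_map
from pathmap.render import render_tile

model = generate_fixture_map(
    n_compartments=3, n_complexes=2, n_proteins=8, n_reactions=4,
    nesting_depth=3, seed=7,
)
assignment = compute_semantic_zoom(model)
# reveal_level is the zoom at which an area's opaque cover disappears
print(f"zoom levels: {assignment.n_levels}")
for eid, level in sorted(assignment.reveal_level.items()):
    print(f"  {eid} ({model.elements[eid].name}): uncovers at zoom {level}")

for z in (0, 1, 2):
    tiles = [render_tile(model, TileCoord(z, tx, ty))
             for tx in range(2**z) for ty in range(2**z)]
    print(f"zoom {z}: rendered {len(tiles)} tiles of "
          f"{tiles[0].width}x{tiles[0].height} px")
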