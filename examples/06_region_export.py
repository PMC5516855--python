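"""Cut a rectangular region out of a map and export it as an annotated
model, a TSV table and a SIF network."""

from pathmap import Bounds, generate_fixture_map, select_region, write_celldesigner
from pathmap.export import export_network, export_table

model = generate_fixture_map(
    n_compartments=2, n_complexes=1, n_proteins=6, n_reactions=4, seed=1,
)
region = select_region(model, Bounds(0, 0, model.width / 2, model.height))
print(f"selection kept {len(region.elements)}/{len(model.elements)} elements "
      f"and {len(region.interactions)}/{len(model.interactions)} interactions")
# the exported model opens directly in a CellDesigner-compatible editor
print(f"CellDesigner export: {len(write_celldesigner(region))} characters")
# table: one row per element and interaction; network: one SIF edge per
# (reactant, product) and (modifier, product) pair
print(f"table rows: {len(export_table(region).splitlines()) - 1}")
print(f"network edges: {len(export_network(region).splitlines())}")
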