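"""Generate a small map, write it as CellDesigner SBML and SBGN-ML, and
check that reading each file back reproduces the model."""

from pathmap import (
    generate_fixture_map, model_diff, read_celldesigner, read_sbgnml,
    write_celldesigner, write_sbgnml,
)
from pathmap.io.sbgnml import canonicalize_for_sbgn

model = generate_fixture_map(
    n_compartments=2, n_complexes=1, n_proteins=6, n_reactions=3, seed=1,
)
print(f"generated: {len(model.elements)} elements, "
      f"{len(model.interactions)} interactions")

cd_diffs = model_diff(model, read_celldesigner(write_celldesigner(model)))
sbgn_model = canonicalize_for_sbgn(model)  # SBGN-expressible type subset
sbgn_diffs = model_diff(sbgn_model, read_sbgnml(write_sbgnml(sbgn_model)))

# a round trip is lossless when the diff list is empty
print(f"CellDesigner round-trip differences: {len(cd_diffs)}")
print(f"SBGN-ML round-trip differences:      {len(sbgn_diffs)}")
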