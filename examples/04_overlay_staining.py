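"""Parse a tab-delimited expression dataset and map its values onto element
colors (map staining)."""

from pathmap import generate_fixture_map, match_entries, parse_overlay

model = generate_fixture_map(n_proteins=6, n_reactions=2, seed=2)
names = [e.name for e in model.elements.values()
         if e.element_type.value == "PROTEIN"][:3]
tsv = "#name: demo transcriptome\nname\tvalue\n" + "\n".join(
    f"{name}\t{v}" for name, v in zip(names, (0.8, -0.5, 0.0))
)
dataset = parse_overlay(tsv)
binding = match_entries(dataset, model)
# values in [-1, 1] interpolate white->red (up) or white->blue (down)
for entry, ids in zip(dataset.entries, binding.element_matches):
    color = dataset.entry_color(entry)
    print(f"{entry.name}: value {entry.value:+.1f} -> fill {color} on {ids}")
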