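"""Query drug targets for two Parkinson's disease drugs against the bundled
offline DrugBank/ChEMBL fixture clients and locate them on the map."""

from pathmap import default_drug_clients, find_drug_targets, generate_fixture_map

model = generate_fixture_map(n_proteins=12, n_reactions=4, seed=4)
report = find_drug_targets(model, "levodopa, carbidopa", default_drug_clients())
# each result group gets its own marker color on the rendered map
for result in report.results:
    sources = ", ".join(rec.source for rec in result.records)
    targets = [model.elements[eid].name for eid in result.matched_element_ids]
    print(f"{result.term} (marker color {result.color_index}; {sources}): "
          f"targets on map = {targets or 'none present'}")
print(f"unknown drugs: {report.misses}")
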