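# pathmap

A Python toolkit for hosting, curating and exploring molecular interaction
maps in SBGN-compliant formats — the computational core of a disease-map
platform, as a library.

Mechanistic disease maps (Parkinson's disease map-style repositories) are
drawn in editors such as CellDesigner or SBGN editors and then need a
service layer: format translation, automatic annotation against
bioinformatics registries, quality-control rules, tiled semantic-zoom
visualization, experimental-data overlays, drug-target lookup, and
annotation-preserving export of map regions. `pathmap` implements that layer
for offline, scriptable use. It is aimed at curators of molecular-network
repositories and at bioinformaticians who need to automate map QC and
export pipelines.

## What it does

* **Model** — a format-neutral `MapModel`: typed elements (protein, gene,
  RNA, simple chemical, complex, compartment, text area, …) with bounds on
  a top-left-origin canvas, typed interactions with reactant/product/
  modifier lists and polylines, MIRIAM annotations, comments and submap
  links; a structural validator returns one violation per broken invariant.
* **I/O** — readers/writers for SBML Level 2 with the CellDesigner 4.x
  extension and for SBGN-ML Process Description 0.2; read∘write is the
  identity on the model (cross-format trips lose exactly the documented
  `LOSSY_FIELDS` type collapses). Multi-map bundles are assembled from a
  CellDesigner configuration diagram whose elements name the member maps.
* **Annotation** — a user-extensible MIRIAM registry resolving
  `(namespace, identifier)` pairs to identifiers.org URIs; NAME-triggered
  (HGNC, BioCompendium) and identifier-triggered (ChEBI, Ensembl, Entrez,
  UniProt, GO) annotators behind one offline-fixture client contract;
  rule-based verification (e.g. *every interaction needs a PubMed
  reference*) emitting one warning per unmet (rule, target) pair.
* **Semantic zoom & tiles** — cover areas (compartments, complexes, text
  areas) are assigned reveal levels by containment depth, so zoomed-out
  views show only the most generic areas, with larger areas covering
  smaller ones; a quadtree tile transform and Pillow renderer produce a
  256-px tile pyramid whose tiles stitch pixel-exactly.
* **Overlays ("map staining")** — tab-delimited datasets with values in
  [−1, 1] map linearly onto a negative/neutral/positive color scheme and
  are matched to elements by identifier (precedent) or case-insensitive
  name/synonym.
* **Queries** — comma-separated multi-term element search with distinct
  marker colors per term; drug-target lookup against DrugBank/ChEMBL-style
  clients with per-drug result groups.
* **Export** — rectangular region extraction that preserves every
  annotation and never dangles a reference (interactions are kept only when
  all reactants and products are inside; out-of-region modifiers are
  dropped and reported); TSV element/interaction tables; SIF edge lists.
* **Fixtures** — a deterministic generator of small valid maps with
  plausible MIRIAM annotations, so the whole toolkit is testable with no
  network access.

## Worked example

```python
from pathmap import (
    Bounds, compute_semantic_zoom, default_drug_clients, find_drug_targets,
    generate_fixture_map, select_region,
)

model = generate_fixture_map(
    n_compartments=3, n_complexes=2, n_proteins=8, n_reactions=4,
    nesting_depth=3, seed=7,
)
assignment = compute_semantic_zoom(model)
print(assignment.n_levels)                  # 4
print(assignment.reveal_level["s1"])        # 3  (complex nested two deep)

report = find_drug_targets(model, "levodopa, carbidopa",
                           default_drug_clients())
print(len(report.results), report.misses)   # 2 []
```

`n_levels = 4` means the map needs zoom levels 0–3: at zoom 0 every cover
is opaque, the nested compartment chain uncovers at 1 and 2, and the
complexes (reveal level 3) uncover last. The drug query returns one result
group per comma-separated term — each with its own marker color — and an
empty miss list because both drugs resolve in the bundled offline
DrugBank/ChEMBL fixtures. The example scripts in `examples/` walk through
each capability end to end; the CLI (`pathmap convert|annotate|verify|zoom|
tile|render|overlay|search|drugs|export-region|export-table|export-network|
fixture`) exposes the same operations to shell pipelines.

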