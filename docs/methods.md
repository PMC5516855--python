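# Methods

This note documents the models, algorithms and conventions behind
`pathmap`, the design choices made where the behaviour of such a platform
is genuinely open, and what the synthetic fixtures do and do not establish
about real curated maps.

## Data model and geometry

All dialects translate into one in-memory `MapModel`. Geometry uses
continuous canvas units with the origin at the top-left corner and y
increasing downward — the natural frame for raster tiling — and every
reader normalizes to it. Element types are the CellDesigner species-class
vocabulary (`PROTEIN`, `GENE`, `RNA`, `ANTISENSE_RNA`, `SIMPLE_MOLECULE`,
`ION`, `DRUG`, `PHENOTYPE`, `DEGRADED`, `UNKNOWN`, `COMPLEX`,
`COMPARTMENT`, `TEXT_AREA`); unrecognized source classes map to `UNKNOWN`
with a logged warning rather than failing, so dialect drift degrades
gracefully. Ids are preserved verbatim from source files; generated
objects use counter ids (`cN` compartments/comments, `sN` species, `rN`
reactions, `tN` text areas).

Modifiers are stored as `(element_id, role)` pairs rather than bare ids:
the role (catalysis, inhibition, stimulation, trigger/necessary
stimulation, modulation) is what the CellDesigner modification type and
the SBGN modulation-arc class carry, and network export needs it to type
`(modifier, product)` edges.

Validation returns violations as data (dangling references, non-positive
or out-of-canvas bounds, children escaping their container, containment
cycles, missing interaction participants, short polylines) instead of
raising; writers refuse invalid models with the violation list attached.
Containment-cycle detection runs on a directed graph of parent references
via networkx.

## Dialects

**CellDesigner.** SBML Level 2 (any minor version) whose model annotation
carries the CellDesigner extension namespace; other levels are rejected as
unsupported. Bounds come from the extension's alias lists; complex
membership from the `complexSpeciesAlias` reference on a species alias;
reaction types, edit points and modification types from the reaction
extension; MIRIAM annotations from BioModels-qualifier RDF (`urn:miriam:`
URNs and identifiers.org URIs both accepted; URNs written). Simplifying
conventions of this writer/reader pair, documented as the dialect: one
alias per species (multi-alias inputs keep the first and warn), complex
members serialized as ordinary species, text areas as layer texts without
annotations, and comments/submap links not serialized (they are
platform-level state). Reading never silently drops an annotation: each
parse reports `resources = parsed + unrecognized`.

**SBGN-ML PD (0.2).** Glyph and arc classes map through fixed tables
(macromolecule↔protein, nucleic acid feature↔gene, simple
chemical↔simple molecule, annotation glyph↔text area, association/
dissociation/uncertain process↔the corresponding interaction types,
catalysis/inhibition/stimulation/necessary stimulation/modulation arcs↔
modifier roles). One process glyph is emitted per interaction at the
polyline midpoint. SBGN-ML core has no slot for MIRIAM annotations,
synonyms, notes, canvas size or exact polylines, so this dialect stores
them in the standard `<extension>` element (annotations as
identifiers.org URIs) — the same route existing CellDesigner↔SBGN
converters use. What cannot survive is the type detail PD does not
express; `LOSSY_FIELDS` enumerates exactly that: RNA/antisense-RNA
collapse to the nucleic-acid feature (read back as `GENE`), ion/drug to
simple chemical, transport and the direct-regulation reaction types to
plain process, unknown modifier roles to modulation.
`canonicalize_for_sbgn` applies these collapses explicitly, which makes
cross-format round-trip assertions exact: CD→SBGN→model equals the
canonicalized source, field for field.

**Bundles.** A bundle is a set of map files plus a configuration diagram
(itself CellDesigner). Config elements are matched to member maps by
case-insensitive file base name; a non-area element naming no file is an
error. When the config has interactions, each (reactant map, product map)
pair yields one link; otherwise each non-main named element links the main
map (first non-config file) to its map. The semantics of config
interactions beyond hyperlinking are not interpreted — they are recorded
in the link graph.

## MIRIAM registry and annotators

The registry ships with 22 namespaces (UniProt, ChEBI, Ensembl, Entrez/
NCBI Gene, GO, HGNC id and symbol, PubMed, DOI, DrugBank, ChEMBL, KEGG
compound/pathway, taxonomy, EC, InterPro, Pfam, Reactome, miRBase, MeSH,
RefSeq, OMIM), each with an identifiers.org URI pattern and an identifier
regex; a YAML config file extends or overrides it, so deployments carry
whatever registry set their content needs rather than a hard-coded count.
URI resolution and parsing are exact inverses over the registry.

Annotators are `(id, trigger, client)` triples. NAME-triggered annotators
(HGNC, BioCompendium) query with the element's raw display name — no fuzzy
matching; ambiguous or empty responses are recorded and skipped.
Identifier-triggered annotators (ChEBI, Ensembl, Entrez, UniProt, GO) fire
once per existing annotation in their namespace. Returned cross-references
merge as a set union (so the pass is idempotent and monotone), synonyms
dedupe case-insensitively, and client failures are recorded per element
without aborting the run. The default client reads one JSON document per
(annotator, query) from a fixture directory; a live HTTP adapter would
implement the same two-method contract. BioCompendium is represented only
by this generic fixture record. Verification rules require *at least one*
of a namespace set per target class; conjunctions are expressed as
multiple rules. Warnings are exactly the unmet (rule, target) pairs.

## Semantic zoom

Candidate cover areas are all compartments, complexes and text areas with
area ≥ `min_cover_fraction` × map area (default 0.002 — small enough that
any visually meaningful area qualifies, large enough to drop slivers).
The reveal level of a candidate is its geometric containment depth among
candidates: parents are found as the smallest candidate strictly
containing an area, with bounds-inclusion tested at 1e-6 canvas-unit
tolerance; coincident or partially overlapping areas are siblings. An
area's opaque cover is drawn at zoom levels strictly below its reveal
level, so level 0 shows only top-level areas and zooming in peels nesting
one level at a time; visibility is therefore monotone in zoom.
`n_levels` is the maximum reveal level + 1; the pixel resolution of the
deepest useful tile level is a separate quantity, `max_native_zoom` =
⌈log₂(max(width, height)/tile_px)⌉ clamped to ≥ 0. Paint order is deepest
cover first; within a level larger areas paint later (on top), ids break
ties — this realizes "larger areas cover smaller ones" deterministically.

## Tiling and rendering

The map embeds top-left into a square of side S = max(width, height) (no
centering, so transforms are deterministic); tile (z, tx, ty) covers the
square's [tx·S/2^z, (tx+1)·S/2^z) × [ty·S/2^z, (ty+1)·S/2^z) rectangle,
giving an exact 4^z partition at every level. Tiles default to 256 px.

Rendering uses Pillow with SBGN-flavoured fixed glyph geometry (rounded
rectangles for proteins, ellipses for small molecules, hexagons for
phenotypes, palette-colored compartments, neutral-gray complex/text-area
covers) and the built-in bitmap font, center-anchored and truncated with
an ellipsis. Styling is configuration (`RenderStyle`), not contract. The
raster contract *is*: identical inputs render byte-identically, and a tile
equals the corresponding crop of a full render pixel for pixel. The
mechanism is coordinate snapping — all drawing coordinates are rounded to
the device pixel grid before drawing, and rounding commutes with the
integer pixel translation between a tile's frame and the full frame
(float subtraction of an integer is exact at these magnitudes). Without
the snap, Pillow's coordinate truncation behaves differently for the
negative coordinates that occur in tile frames. Overlay colors are applied
last, as opaque fills over the matched objects.

## Overlays

The accepted file dialect is self-documented: UTF-8 TSV, `#` comments, an
optional `#name:` title, and the header vocabulary
`name identifier type value color line_width`. Values live in [−1, 1] and
interpolate channel-wise linearly from the neutral color (default white)
to the positive (red) or negative (blue) pole, rounding half-up per
channel; an explicit color overrides the computed one. Identifier matches
take precedence over name matches; names match case-insensitively against
names and synonyms; the optional type filter lets one file carry several
'omics layers. Invalid rows are rejected row-by-row with reasons, never
fatally. Multiple datasets apply in upload order, later datasets winning
conflicts. No statistics (normalization, testing) are performed on
uploaded values.

## Queries

Query strings split on commas; terms match exactly (case-insensitive,
against names, synonyms and annotation identifiers) before substring
matching is attempted, so short terms cannot light up the whole map.
Terms get consecutive marker color indices. Drug lookups query every
configured client per term; DrugBank- and ChEMBL-style records for the
same drug are both kept and their target sets unioned; targets match to
elements by identifier first, then by gene symbol via the same matcher as
overlays. Per-drug failures and misses are reported, never raised.

## Region export

An element is included when its bounds intersect the selection; complexes
are atomic (any intersecting part pulls in the whole complex tree);
containers of included elements come along with bounds unclipped; an
interaction survives iff all reactants and products are included, with
out-of-region modifiers dropped and reported. These rules guarantee the
exported model validates — the all-participants rule exists precisely so
no exported file ever carries a dangling reference — and make selection
idempotent and monotone in the selection rectangle. The canvas size is
preserved, so full-canvas selection is the identity.

## Synthetic fixtures

The generator emulates a small curated map: compartments in a grid, an
optional nested-compartment chain (so a requested nesting depth is reached
exactly), complexes with two members each, proteins named from a table of
neurodegeneration-relevant genes with real UniProt/Entrez/HGNC
cross-references, text areas in a reserved strip, and reactions between
random protein pairs — every second reaction carries a PubMed annotation
and every second a catalyst. Slot-based placement guarantees
non-overlapping siblings and proper nesting; all randomness flows from the
seed, so serialization is byte-identical per seed. What the fixtures do
*not* reproduce: real maps' scale (thousands of elements), partial overlap
and hand-drawn layout irregularities, multi-alias species, residue-level
modification states, and the breadth of real registry responses. Green
tests therefore establish the algorithms' contracts, not performance or
robustness to arbitrary third-party files.

The property measurements in `scripts/acceptance.py` run at modest sizes —
20 maps per dialect for round trips, 100 random nested-area models for the
zoom oracle, tile levels 0–2 at 128 px, 200 random rectangles for region
export — chosen so the whole script completes in seconds while still
exercising every rule on varied geometry.

## Known limitations

* Live HTTP annotator/drug clients are not shipped; the offline fixture
  client defines the contract an adapter must meet.
* SBGN-ML entity/activity-flow sub-languages, SBML Level 3 layout/render
  packages, and KEGG/BioPAX import are out of scope.
* Emitted documents are checked structurally and by round trip, not
  against the official XSD schemas.
* Layout is taken from the input; no automatic graph layout, edge
  bundling or node duplication is performed.
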