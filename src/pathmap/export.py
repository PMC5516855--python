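"""Region extraction and table/network export.

``select_region`` cuts a rectangular selection out of a map and returns a
self-contained, valid model carrying every annotation, note and name
verbatim — the use case is downloading part of a hosted diagram and opening
it directly in an editor.  Inclusion rules:

* an element is included when its bounds intersect the selection;
* a complex is included whole (with all members) when any part of it
  intersects;
* containers (compartments) of included elements are included, transitively,
  with bounds preserved unclipped;
* an interaction is included iff all its reactants and products are
  included; modifiers outside the region are dropped from the interaction
  and listed in the extraction report (this guarantees no dangling
  references in the exported model).

``export_table`` writes one TSV row per element and per interaction;
``export_network`` expands each interaction into SIF-style edges: one line
per (reactant, product) pair typed by the interaction, plus one per
(modifier, product) pair typed by the modifier's role.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field

from .errors import EmptyRegion
from .model import (
    Bounds,
    ElementType,
    Interaction,
    MapModel,
    Modifier,
    copy_model,
)


# ---------------------------------------------------------------------------
# Region selection
# ---------------------------------------------------------------------------


@dataclass
class RegionReport:
    included_elements: list[str] = field(default_factory=list)
    included_interactions: list[str] = field(default_factory=list)
    dropped_interactions: list[str] = field(default_factory=list)
    #: (interaction id, modifier element id) pairs removed from kept interactions
    dropped_modifiers: list[tuple[str, str]] = field(default_factory=list)


def _complex_root(model: MapModel, element_id: str) -> str:
    """Topmost complex enclosing an element (or the element itself)."""
    current = model.elements[element_id]
    root = element_id
    seen = {element_id}
    while current.parent_complex and current.parent_complex in model.elements:
        if current.parent_complex in seen:
            break
        root = current.parent_complex
        seen.add(root)
        current = model.elements[root]
    return root


def region_element_ids(model: MapModel, bounds: Bounds) -> set[str]:
    """Element ids included by the selection rules (no interactions)."""
    included: set[str] = {
        eid for eid, el in model.elements.items() if el.bounds.intersects(bounds)
    }
    # complexes are atomic: hitting any part pulls in the whole complex tree
    for eid in list(included):
        root = _complex_root(model, eid)
        root_el = model.elements[root]
        if root_el.element_type is ElementType.COMPLEX or root != eid:
            included.add(root)
            included.update(
                m.element_id for m in model.complex_members(root)
            )
    # containers of included elements, transitively
    frontier = list(included)
    while frontier:
        el = model.elements[frontier.pop()]
        for ref in (el.compartment_ref, el.parent_complex):
            if ref and ref in model.elements and ref not in included:
                included.add(ref)
                frontier.append(ref)
    return included


def extract_region(model: MapModel, bounds: Bounds) -> tuple[MapModel, RegionReport]:
    """Apply the inclusion rules; return the sub-model and a report."""
    if bounds.w <= 0 or bounds.h <= 0:
        raise EmptyRegion(f"selection {bounds} has no extent")
    included = region_element_ids(model, bounds)
    if not included:
        raise EmptyRegion("selection intersects no elements")

    source = copy_model(model)
    report = RegionReport()
    out = MapModel(
        map_id=model.map_id,
        name=model.name,
        width=model.width,
        height=model.height,
    )
    for eid, el in source.elements.items():
        if eid in included:
            out.add_element(el)
            report.included_elements.append(eid)

    for iid, inter in source.interactions.items():
        participants = [*inter.reactants, *inter.products]
        if participants and all(p in included for p in participants):
            kept_modifiers: list[Modifier] = []
            for m in inter.modifiers:
                if m.element_id in included:
                    kept_modifiers.append(m)
                else:
                    report.dropped_modifiers.append((iid, m.element_id))
            inter.modifiers = kept_modifiers
            out.add_interaction(inter)
            report.included_interactions.append(iid)
        else:
            report.dropped_interactions.append(iid)

    out.submap_links = [
        link for link in source.submap_links if link.source_element_id in included
    ]
    out.comments = [
        c
        for c in source.comments
        if not isinstance(c.target, str)
        or c.target in out.elements
        or c.target in out.interactions
    ]
    return out, report


def select_region(model: MapModel, bounds: Bounds) -> MapModel:
    """Extract a rectangular region as a stand-alone valid model.

    Selecting the full canvas returns a model equivalent to the input;
    the operation is idempotent on its own output.
    """
    sub, _report = extract_region(model, bounds)
    return sub


# ---------------------------------------------------------------------------
# Table export
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "kind", "id", "name", "type", "compartment",
    "reactants", "products", "modifiers", "annotations",
    "x", "y", "w", "h",
]


def _annotations_cell(annotations) -> str:
    return ";".join(
        sorted(f"{a.namespace}:{a.identifier}" for a in set(annotations))
    )


def export_table(model: MapModel) -> str:
    """Tab-delimited table: element rows (by id) then interaction rows
    (by id); annotation cells are semicolon-joined and sorted."""
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(TABLE_COLUMNS)
    for eid in sorted(model.elements):
        el = model.elements[eid]
        writer.writerow([
            "element", eid, el.name, el.element_type.value,
            el.compartment_ref or "",
            "", "", "",
            _annotations_cell(el.annotations),
            repr(el.bounds.x), repr(el.bounds.y),
            repr(el.bounds.w), repr(el.bounds.h),
        ])
    for iid in sorted(model.interactions):
        inter = model.interactions[iid]
        writer.writerow([
            "interaction", iid, "", inter.interaction_type.value, "",
            ";".join(inter.reactants),
            ";".join(inter.products),
            ";".join(f"{m.element_id}:{m.role.value}" for m in inter.modifiers),
            _annotations_cell(inter.annotations),
            "", "", "", "",
        ])
    return buf.getvalue()


def parse_table(text: str) -> dict:
    """Parse-back of :func:`export_table` output: recovers ids, types and
    annotation sets (the invariant the exporter guarantees)."""
    reader = csv.reader(_io.StringIO(text), delimiter="\t")
    header = next(reader)
    if header != TABLE_COLUMNS:
        raise ValueError(f"unexpected table header: {header}")
    elements: dict[str, dict] = {}
    interactions: dict[str, dict] = {}
    for row in reader:
        record = dict(zip(TABLE_COLUMNS, row))
        annotations = set()
        if record["annotations"]:
            for token in record["annotations"].split(";"):
                ns, ident = token.split(":", 1)
                annotations.add((ns, ident))
        if record["kind"] == "element":
            elements[record["id"]] = {
                "name": record["name"],
                "type": record["type"],
                "compartment": record["compartment"] or None,
                "annotations": annotations,
                "bounds": tuple(float(record[k]) for k in ("x", "y", "w", "h")),
            }
        else:
            interactions[record["id"]] = {
                "type": record["type"],
                "reactants": record["reactants"].split(";") if record["reactants"] else [],
                "products": record["products"].split(";") if record["products"] else [],
                "modifiers": [
                    tuple(tok.rsplit(":", 1))
                    for tok in record["modifiers"].split(";")
                    if tok
                ],
                "annotations": annotations,
            }
    return {"elements": elements, "interactions": interactions}


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def interaction_edges(interaction: Interaction) -> list[tuple[str, str, str]]:
    """SIF edges for one interaction: (source, relation, target)."""
    edges = [
        (r, interaction.interaction_type.value, p)
        for r in interaction.reactants
        for p in interaction.products
    ]
    edges.extend(
        (m.element_id, m.role.value, p)
        for m in interaction.modifiers
        for p in interaction.products
    )
    return edges


def export_network(model: MapModel) -> str:
    """SIF-style edge list: ``source<TAB>relation<TAB>target`` per line,
    interactions in id order, pairs in participant order."""
    lines = []
    for iid in sorted(model.interactions):
        for s, rel, t in interaction_edges(model.interactions[iid]):
            lines.append(f"{s}\t{rel}\t{t}")
    return "\n".join(lines) + ("\n" if lines else "")
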