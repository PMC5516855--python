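"""CellDesigner-dialect SBML reader and writer.

Supported input is SBML Level 2 (any version) whose model annotation carries
the CellDesigner 4.x extension namespace.  Layout comes from the extension's
alias lists (compartment aliases, complex species aliases, species aliases);
species classes map onto the model's element-type vocabulary; the extension's
reaction type field types interactions; BioModels-qualifier RDF becomes
annotations.

Dialect notes (documented simplifications of this writer/reader pair):

* every species has exactly one alias — the model keeps one bounds per
  element, so multi-alias files keep the first alias and log a warning;
* complex members are serialized as ordinary SBML species whose alias
  references the parent ``complexSpeciesAlias`` (CellDesigner's separate
  "included species" list is accepted on read if present as plain species);
* text areas are serialized as layer texts; they carry no annotations or
  synonyms in this dialect;
* comments and submap links are platform-level state and are not serialized.
"""

from __future__ import annotations

import logging
from urllib.parse import unquote  # noqa: F401  (re-export convenience)

from lxml import etree

from ..annotate import MiriamRegistry, default_registry
from ..errors import ModelInvalid, ParseError, UnsupportedDialect
from ..model import (
    Bounds,
    Element,
    ElementType,
    Interaction,
    InteractionType,
    MapModel,
    Modifier,
    ModifierRole,
    validate_model,
)
from ._rdf import ReadReport, build_rdf, fmt, parse_rdf_annotations

log = logging.getLogger(__name__)

SBML_L2_PREFIX = "http://www.sbml.org/sbml/level2"
SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CD_NS = "http://www.sbml.org/2001/ns/celldesigner"
XHTML_NS = "http://www.w3.org/1999/xhtml"

_DEFAULT_COMPARTMENT = "default"

_SPECIES_CLASSES = {t.value for t in ElementType} - {
    ElementType.COMPARTMENT.value,
    ElementType.TEXT_AREA.value,
}


def _q(tag: str, ns: str = CD_NS) -> str:
    return f"{{{ns}}}{tag}"


def _parse_xml(xml_text: str | bytes) -> etree._Element:
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        return etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from None


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_celldesigner(
    xml_text: str | bytes, registry: MiriamRegistry | None = None
) -> MapModel:
    """Parse a CellDesigner-dialect SBML document into a :class:`MapModel`."""
    model, _report = read_celldesigner_report(xml_text, registry)
    return model


def read_celldesigner_report(
    xml_text: str | bytes, registry: MiriamRegistry | None = None
) -> tuple[MapModel, ReadReport]:
    """As :func:`read_celldesigner`, also returning the parse report with
    annotation accounting and dialect warnings."""
    registry = registry or default_registry()
    report = ReadReport()
    root = _parse_xml(xml_text)

    qname = etree.QName(root)
    if qname.localname != "sbml":
        raise UnsupportedDialect(f"root element is <{qname.localname}>, expected <sbml>")
    if not (qname.namespace or "").startswith(SBML_L2_PREFIX):
        raise UnsupportedDialect(
            f"SBML namespace {qname.namespace!r} is not Level 2"
        )
    sbml_ns = qname.namespace
    model_el = root.find(_q("model", sbml_ns))
    if model_el is None:
        raise UnsupportedDialect("no <model> element")
    extension = model_el.find(f"{_q('annotation', sbml_ns)}/{_q('extension')}")
    if extension is None:
        raise UnsupportedDialect("SBML model carries no CellDesigner extension")

    model = MapModel(
        map_id=model_el.get("id", "map"),
        name=model_el.get("name", ""),
    )
    display = extension.find(_q("modelDisplay"))
    if display is not None:
        model.width = float(display.get("sizeX", model.width))
        model.height = float(display.get("sizeY", model.height))

    # --- alias lists: geometry + complex membership -------------------------
    def read_bounds(el: etree._Element) -> Bounds | None:
        b = el.find(_q("bounds"))
        if b is None:
            return None
        return Bounds(
            float(b.get("x", 0)), float(b.get("y", 0)),
            float(b.get("w", 0)), float(b.get("h", 0)),
        )

    compartment_bounds: dict[str, Bounds] = {}
    for alias in extension.iterfind(f"{_q('listOfCompartmentAliases')}/{_q('compartmentAlias')}"):
        b = read_bounds(alias)
        cid = alias.get("compartment")
        if cid and b and cid not in compartment_bounds:
            compartment_bounds[cid] = b

    species_bounds: dict[str, Bounds] = {}
    alias_species: dict[str, str] = {}        # alias id -> species id
    parent_alias: dict[str, str] = {}         # species id -> parent complex alias id
    for list_tag, alias_tag in (
        ("listOfComplexSpeciesAliases", "complexSpeciesAlias"),
        ("listOfSpeciesAliases", "speciesAlias"),
    ):
        for alias in extension.iterfind(f"{_q(list_tag)}/{_q(alias_tag)}"):
            sid = alias.get("species")
            aid = alias.get("id")
            if sid is None:
                continue
            if sid in species_bounds:
                report.warn(f"species {sid!r} has multiple aliases; keeping the first")
                continue
            b = read_bounds(alias)
            if b is not None:
                species_bounds[sid] = b
            if aid:
                alias_species[aid] = sid
            parent = alias.get("complexSpeciesAlias")
            if parent:
                parent_alias[sid] = parent

    # --- compartments --------------------------------------------------------
    for comp in model_el.iterfind(
        f"{_q('listOfCompartments', sbml_ns)}/{_q('compartment', sbml_ns)}"
    ):
        cid = comp.get("id")
        if cid is None or cid == _DEFAULT_COMPARTMENT:
            continue
        ann_el = comp.find(_q("annotation", sbml_ns))
        outside = comp.get("outside")
        bounds = compartment_bounds.get(
            cid, Bounds(0.0, 0.0, model.width, model.height)
        )
        model.add_element(Element(
            element_id=cid,
            element_type=ElementType.COMPARTMENT,
            name=comp.get("name", cid),
            bounds=bounds,
            compartment_ref=None if outside in (None, _DEFAULT_COMPARTMENT) else outside,
            synonyms=_read_synonyms(ann_el),
            annotations=parse_rdf_annotations(ann_el, registry, report, f"compartment {cid}"),
            notes=_read_notes(comp, sbml_ns),
        ))

    # --- species -------------------------------------------------------------
    for sp in model_el.iterfind(
        f"{_q('listOfSpecies', sbml_ns)}/{_q('species', sbml_ns)}"
    ):
        sid = sp.get("id")
        if sid is None:
            continue
        ann_el = sp.find(_q("annotation", sbml_ns))
        cls = None
        if ann_el is not None:
            cls_el = ann_el.find(
                f"{_q('extension')}/{_q('speciesIdentity')}/{_q('class')}"
            )
            if cls_el is not None and cls_el.text:
                cls = cls_el.text.strip()
        if cls in _SPECIES_CLASSES:
            etype = ElementType(cls)
        else:
            report.warn(f"species {sid!r}: unknown class {cls!r}, mapped to UNKNOWN")
            etype = ElementType.UNKNOWN
        comp_ref = sp.get("compartment")
        if comp_ref in (None, _DEFAULT_COMPARTMENT) or comp_ref not in model.elements:
            comp_ref = None
        parent_complex = None
        if sid in parent_alias:
            parent_complex = alias_species.get(parent_alias[sid])
        bounds = species_bounds.get(sid)
        if bounds is None:
            report.warn(f"species {sid!r} has no alias; defaulting bounds")
            bounds = Bounds(0.0, 0.0, 80.0, 40.0)
        model.add_element(Element(
            element_id=sid,
            element_type=etype,
            name=sp.get("name", sid),
            bounds=bounds,
            compartment_ref=comp_ref,
            parent_complex=parent_complex,
            synonyms=_read_synonyms(ann_el),
            annotations=parse_rdf_annotations(ann_el, registry, report, f"species {sid}"),
            notes=_read_notes(sp, sbml_ns),
        ))

    # --- text areas (layer texts) -------------------------------------------
    for text_el in extension.iterfind(
        f"{_q('listOfLayers')}/{_q('layer')}/{_q('listOfTexts')}/{_q('layerSpeciesAlias')}"
    ):
        tid = text_el.get("id")
        if tid is None:
            continue
        b = read_bounds(text_el)
        label = text_el.findtext(_q("text")) or ""
        model.add_element(Element(
            element_id=tid,
            element_type=ElementType.TEXT_AREA,
            name=label.strip(),
            bounds=b or Bounds(0.0, 0.0, 100.0, 40.0),
        ))

    # --- reactions -----------------------------------------------------------
    for rxn in model_el.iterfind(
        f"{_q('listOfReactions', sbml_ns)}/{_q('reaction', sbml_ns)}"
    ):
        rid = rxn.get("id")
        if rid is None:
            continue
        ann_el = rxn.find(_q("annotation", sbml_ns))
        rtype = InteractionType.STATE_TRANSITION
        polyline: list[tuple[float, float]] = []
        modifiers: list[Modifier] = []
        ext = ann_el.find(_q("extension")) if ann_el is not None else None
        if ext is not None:
            rt = ext.findtext(_q("reactionType"))
            if rt:
                rt = rt.strip()
                try:
                    rtype = InteractionType(rt)
                except ValueError:
                    report.warn(f"reaction {rid!r}: unknown type {rt!r}, mapped to UNKNOWN")
                    rtype = InteractionType.UNKNOWN
            pts = ext.findtext(_q("editPoints"))
            if pts:
                for token in pts.split():
                    xs, ys = token.split(",")
                    polyline.append((float(xs), float(ys)))
            for mod in ext.iterfind(f"{_q('listOfModification')}/{_q('modification')}"):
                mid = mod.get("modifiers")
                mtype = mod.get("type", ModifierRole.CATALYSIS.value)
                try:
                    role = ModifierRole(mtype)
                except ValueError:
                    report.warn(f"reaction {rid!r}: unknown modification type {mtype!r}")
                    role = ModifierRole.UNKNOWN
                if mid:
                    modifiers.append(Modifier(mid, role))

        def refs(tag: str, ref_tag: str) -> list[str]:
            return [
                sr.get("species")
                for sr in rxn.iterfind(f"{_q(tag, sbml_ns)}/{_q(ref_tag, sbml_ns)}")
                if sr.get("species")
            ]

        reactants = refs("listOfReactants", "speciesReference")
        products = refs("listOfProducts", "speciesReference")
        declared = {m.element_id for m in modifiers}
        for mid in refs("listOfModifiers", "modifierSpeciesReference"):
            if mid not in declared:
                modifiers.append(Modifier(mid, ModifierRole.CATALYSIS))
        if not polyline:
            polyline = _default_polyline(model, reactants, products)
        model.add_interaction(Interaction(
            interaction_id=rid,
            interaction_type=rtype,
            reactants=reactants,
            products=products,
            modifiers=modifiers,
            polyline=polyline,
            annotations=parse_rdf_annotations(ann_el, registry, report, f"reaction {rid}"),
            notes=_read_notes(rxn, sbml_ns),
        ))

    return model, report


def _default_polyline(model, reactants, products):
    """Straight segment between first reactant and first product centers."""
    start = end = (0.0, 0.0)
    if reactants and reactants[0] in model.elements:
        start = model.elements[reactants[0]].bounds.center
    if products and products[0] in model.elements:
        end = model.elements[products[0]].bounds.center
    return [start, end]


def _read_notes(obj: etree._Element, sbml_ns: str) -> str:
    notes = obj.find(_q("notes", sbml_ns))
    if notes is None:
        return ""
    return " ".join(t.strip() for t in notes.itertext() if t.strip())


def _read_synonyms(ann_el: etree._Element | None) -> list[str]:
    if ann_el is None:
        return []
    return [
        s.text.strip()
        for s in ann_el.iterfind(f"{_q('extension')}/{_q('listOfSynonyms')}/{_q('synonym')}")
        if s.text and s.text.strip()
    ]


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_celldesigner(model: MapModel) -> str:
    """Serialize a valid model as CellDesigner-dialect SBML Level 2.

    Raises :class:`ModelInvalid` (listing the violations) on an invalid
    model.  ``read_celldesigner(write_celldesigner(m))`` is
    model-equivalent to ``m``.
    """
    violations = validate_model(model)
    if violations:
        raise ModelInvalid(violations)

    nsmap = {None: SBML_NS, "celldesigner": CD_NS}
    root = etree.Element(_q("sbml", SBML_NS), nsmap=nsmap)
    root.set("level", "2")
    root.set("version", "4")
    model_el = etree.SubElement(root, _q("model", SBML_NS))
    model_el.set("id", model.map_id or "map")
    if model.name:
        model_el.set("name", model.name)

    ann = etree.SubElement(model_el, _q("annotation", SBML_NS))
    ext = etree.SubElement(ann, _q("extension"))
    etree.SubElement(ext, _q("modelVersion")).text = "4.0"
    display = etree.SubElement(ext, _q("modelDisplay"))
    display.set("sizeX", fmt(model.width))
    display.set("sizeY", fmt(model.height))

    compartments = [e for e in model.elements.values()
                    if e.element_type is ElementType.COMPARTMENT]
    complexes = [e for e in model.elements.values()
                 if e.element_type is ElementType.COMPLEX]
    text_areas = [e for e in model.elements.values()
                  if e.element_type is ElementType.TEXT_AREA]
    species = [e for e in model.elements.values()
               if e.element_type not in (
                   ElementType.COMPARTMENT, ElementType.TEXT_AREA)]

    def bounds_el(parent: etree._Element, b: Bounds) -> None:
        be = etree.SubElement(parent, _q("bounds"))
        be.set("x", fmt(b.x))
        be.set("y", fmt(b.y))
        be.set("w", fmt(b.w))
        be.set("h", fmt(b.h))

    comp_aliases = etree.SubElement(ext, _q("listOfCompartmentAliases"))
    for comp in compartments:
        alias = etree.SubElement(comp_aliases, _q("compartmentAlias"))
        alias.set("id", f"{comp.element_id}_alias")
        alias.set("compartment", comp.element_id)
        bounds_el(alias, comp.bounds)

    complex_aliases = etree.SubElement(ext, _q("listOfComplexSpeciesAliases"))
    species_aliases = etree.SubElement(ext, _q("listOfSpeciesAliases"))
    for el in species:
        is_complex = el.element_type is ElementType.COMPLEX
        alias = etree.SubElement(
            complex_aliases if is_complex else species_aliases,
            _q("complexSpeciesAlias" if is_complex else "speciesAlias"),
        )
        alias.set("id", f"{el.element_id}_alias")
        alias.set("species", el.element_id)
        if el.compartment_ref:
            alias.set("compartmentAlias", f"{el.compartment_ref}_alias")
        if el.parent_complex:
            alias.set("complexSpeciesAlias", f"{el.parent_complex}_alias")
        bounds_el(alias, el.bounds)

    if text_areas:
        layers = etree.SubElement(ext, _q("listOfLayers"))
        layer = etree.SubElement(layers, _q("layer"))
        layer.set("id", "1")
        layer.set("name", "text areas")
        layer.set("visible", "true")
        texts = etree.SubElement(layer, _q("listOfTexts"))
        for ta in text_areas:
            te = etree.SubElement(texts, _q("layerSpeciesAlias"))
            te.set("id", ta.element_id)
            bounds_el(te, ta.bounds)
            etree.SubElement(te, _q("text")).text = ta.name

    # --- SBML core lists -----------------------------------------------------
    comp_list = etree.SubElement(model_el, _q("listOfCompartments", SBML_NS))
    default_comp = etree.SubElement(comp_list, _q("compartment", SBML_NS))
    default_comp.set("id", _DEFAULT_COMPARTMENT)
    for comp in compartments:
        ce = etree.SubElement(comp_list, _q("compartment", SBML_NS))
        ce.set("id", comp.element_id)
        if comp.name:
            ce.set("name", comp.name)
        ce.set("outside", comp.compartment_ref or _DEFAULT_COMPARTMENT)
        _write_notes(ce, comp.notes)
        _write_object_annotation(ce, comp.element_id, comp.annotations, comp.synonyms)

    if species:
        sp_list = etree.SubElement(model_el, _q("listOfSpecies", SBML_NS))
        for el in species:
            se = etree.SubElement(sp_list, _q("species", SBML_NS))
            se.set("id", el.element_id)
            if el.name:
                se.set("name", el.name)
            se.set("compartment", el.compartment_ref or _DEFAULT_COMPARTMENT)
            _write_notes(se, el.notes)
            _write_object_annotation(
                se, el.element_id, el.annotations, el.synonyms,
                species_class=el.element_type.value,
            )

    if model.interactions:
        rxn_list = etree.SubElement(model_el, _q("listOfReactions", SBML_NS))
        for inter in model.interactions.values():
            re_ = etree.SubElement(rxn_list, _q("reaction", SBML_NS))
            re_.set("id", inter.interaction_id)
            re_.set("reversible", "false")
            _write_notes(re_, inter.notes)
            ra = etree.SubElement(re_, _q("annotation", SBML_NS))
            rext = etree.SubElement(ra, _q("extension"))
            etree.SubElement(rext, _q("reactionType")).text = (
                inter.interaction_type.value
            )
            if inter.polyline:
                etree.SubElement(rext, _q("editPoints")).text = " ".join(
                    f"{fmt(x)},{fmt(y)}" for x, y in inter.polyline
                )
            if inter.modifiers:
                mods = etree.SubElement(rext, _q("listOfModification"))
                for m in inter.modifiers:
                    me = etree.SubElement(mods, _q("modification"))
                    me.set("modifiers", m.element_id)
                    me.set("type", m.role.value)
            build_rdf(ra, inter.interaction_id, inter.annotations)
            for tag, ref_tag, ids in (
                ("listOfReactants", "speciesReference", inter.reactants),
                ("listOfProducts", "speciesReference", inter.products),
                ("listOfModifiers", "modifierSpeciesReference", inter.modifier_ids()),
            ):
                if not ids:
                    continue
                le = etree.SubElement(re_, _q(tag, SBML_NS))
                for sid in ids:
                    sr = etree.SubElement(le, _q(ref_tag, SBML_NS))
                    sr.set("species", sid)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _write_notes(obj: etree._Element, notes: str) -> None:
    if not notes:
        return
    ne = etree.SubElement(obj, _q("notes", SBML_NS))
    body = etree.SubElement(ne, _q("body", XHTML_NS), nsmap={None: XHTML_NS})
    body.text = notes


def _write_object_annotation(
    obj: etree._Element,
    object_id: str,
    annotations,
    synonyms,
    species_class: str | None = None,
) -> None:
    if not (annotations or synonyms or species_class):
        return
    ann = etree.SubElement(obj, _q("annotation", SBML_NS))
    if species_class or synonyms:
        ext = etree.SubElement(ann, _q("extension"))
        if species_class:
            identity = etree.SubElement(ext, _q("speciesIdentity"))
            etree.SubElement(identity, _q("class")).text = species_class
        if synonyms:
            syn_list = etree.SubElement(ext, _q("listOfSynonyms"))
            for s in synonyms:
                etree.SubElement(syn_list, _q("synonym")).text = s
    build_rdf(ann, object_id, annotations)
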