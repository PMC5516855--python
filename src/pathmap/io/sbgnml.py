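"""SBGN-ML Process Description (0.2 schema) reader and writer.

Glyph and arc classes map bidirectionally onto the model vocabulary through
the tables below.  SBGN-ML core carries no MIRIAM RDF, no synonyms and no
free-text notes; this dialect stores those — plus the map's canvas size and
the exact interaction polyline — in the SBGN-ML ``<extension>`` element as
identifiers.org URIs and simple attribute records (the documented pathmap
dialect).

What cannot survive the trip is the type detail the SBGN PD class set does
not express; those collapses are enumerated in :data:`LOSSY_FIELDS` /
:data:`TYPE_COLLAPSE` / :data:`INTERACTION_COLLAPSE` and cross-format
round-trip tests exclude exactly these fields.
"""

from __future__ import annotations

import logging

from lxml import etree

from ..annotate import MiriamRegistry, default_registry, parse_uri, resolve_uri
from ..errors import ModelInvalid, ParseError, UnsupportedDialect
from ..model import (
    Annotation,
    Bounds,
    Element,
    ElementType,
    Interaction,
    InteractionType,
    MapModel,
    Modifier,
    ModifierRole,
    copy_model,
    validate_model,
)
from ._rdf import ReadReport, fmt

log = logging.getLogger(__name__)

SBGN_NS = "http://sbgn.org/libsbgn/0.2"
EXT_NS = "urn:pathmap:sbgnml"
PD_LANGUAGE = "process description"

# --- mapping tables ---------------------------------------------------------

ELEMENT_TO_GLYPH: dict[ElementType, str] = {
    ElementType.PROTEIN: "macromolecule",
    ElementType.GENE: "nucleic acid feature",
    ElementType.RNA: "nucleic acid feature",
    ElementType.ANTISENSE_RNA: "nucleic acid feature",
    ElementType.SIMPLE_MOLECULE: "simple chemical",
    ElementType.ION: "simple chemical",
    ElementType.DRUG: "simple chemical",
    ElementType.PHENOTYPE: "phenotype",
    ElementType.DEGRADED: "source and sink",
    ElementType.UNKNOWN: "unspecified entity",
    ElementType.COMPLEX: "complex",
    ElementType.COMPARTMENT: "compartment",
    ElementType.TEXT_AREA: "annotation",
}

GLYPH_TO_ELEMENT: dict[str, ElementType] = {
    "macromolecule": ElementType.PROTEIN,
    "macromolecule multimer": ElementType.PROTEIN,
    "nucleic acid feature": ElementType.GENE,
    "nucleic acid feature multimer": ElementType.GENE,
    "simple chemical": ElementType.SIMPLE_MOLECULE,
    "simple chemical multimer": ElementType.SIMPLE_MOLECULE,
    "phenotype": ElementType.PHENOTYPE,
    "source and sink": ElementType.DEGRADED,
    "unspecified entity": ElementType.UNKNOWN,
    "complex": ElementType.COMPLEX,
    "complex multimer": ElementType.COMPLEX,
    "compartment": ElementType.COMPARTMENT,
    "annotation": ElementType.TEXT_AREA,
}

INTERACTION_TO_PROCESS: dict[InteractionType, str] = {
    InteractionType.STATE_TRANSITION: "process",
    InteractionType.TRANSPORT: "process",
    InteractionType.HETERODIMER_ASSOCIATION: "association",
    InteractionType.DISSOCIATION: "dissociation",
    InteractionType.CATALYSIS: "process",
    InteractionType.INHIBITION: "process",
    InteractionType.TRIGGER: "process",
    InteractionType.PHYSICAL_STIMULATION: "process",
    InteractionType.MODULATION: "process",
    InteractionType.UNKNOWN: "uncertain process",
}

PROCESS_TO_INTERACTION: dict[str, InteractionType] = {
    "process": InteractionType.STATE_TRANSITION,
    "omitted process": InteractionType.STATE_TRANSITION,
    "uncertain process": InteractionType.UNKNOWN,
    "association": InteractionType.HETERODIMER_ASSOCIATION,
    "dissociation": InteractionType.DISSOCIATION,
}

ROLE_TO_ARC: dict[ModifierRole, str] = {
    ModifierRole.CATALYSIS: "catalysis",
    ModifierRole.INHIBITION: "inhibition",
    ModifierRole.PHYSICAL_STIMULATION: "stimulation",
    ModifierRole.TRIGGER: "necessary stimulation",
    ModifierRole.MODULATION: "modulation",
    ModifierRole.UNKNOWN: "modulation",
}

ARC_TO_ROLE: dict[str, ModifierRole] = {
    "catalysis": ModifierRole.CATALYSIS,
    "inhibition": ModifierRole.INHIBITION,
    "stimulation": ModifierRole.PHYSICAL_STIMULATION,
    "necessary stimulation": ModifierRole.TRIGGER,
    "modulation": ModifierRole.MODULATION,
}

#: Type detail collapsed by the SBGN PD class vocabulary.  Cross-format
#: round trips lose exactly this; everything else survives.
TYPE_COLLAPSE: dict[ElementType, ElementType] = {
    ElementType.RNA: ElementType.GENE,
    ElementType.ANTISENSE_RNA: ElementType.GENE,
    ElementType.ION: ElementType.SIMPLE_MOLECULE,
    ElementType.DRUG: ElementType.SIMPLE_MOLECULE,
}

INTERACTION_COLLAPSE: dict[InteractionType, InteractionType] = {
    InteractionType.TRANSPORT: InteractionType.STATE_TRANSITION,
    InteractionType.CATALYSIS: InteractionType.STATE_TRANSITION,
    InteractionType.INHIBITION: InteractionType.STATE_TRANSITION,
    InteractionType.TRIGGER: InteractionType.STATE_TRANSITION,
    InteractionType.PHYSICAL_STIMULATION: InteractionType.STATE_TRANSITION,
    InteractionType.MODULATION: InteractionType.STATE_TRANSITION,
}

ROLE_COLLAPSE: dict[ModifierRole, ModifierRole] = {
    ModifierRole.UNKNOWN: ModifierRole.MODULATION,
}

#: model_diff ``ignore`` keys for a cross-format comparison.
LOSSY_FIELDS: frozenset[str] = frozenset(
    {"element_type", "interaction_type", "modifier_role"}
)


def canonicalize_for_sbgn(model: MapModel) -> MapModel:
    """Map a model onto the SBGN-expressible type subset: the image of a
    write→read trip through this dialect.  Useful for exact cross-format
    round-trip assertions."""
    out = copy_model(model)
    for el in out.elements.values():
        el.element_type = TYPE_COLLAPSE.get(el.element_type, el.element_type)
    for inter in out.interactions.values():
        inter.interaction_type = INTERACTION_COLLAPSE.get(
            inter.interaction_type, inter.interaction_type
        )
        inter.modifiers = [
            Modifier(m.element_id, ROLE_COLLAPSE.get(m.role, m.role))
            for m in inter.modifiers
        ]
    return out


def _q(tag: str, ns: str = SBGN_NS) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_PROCESS_SIZE = 14.0


def write_sbgnml(model: MapModel) -> str:
    """Serialize a valid model as SBGN-ML PD.

    ``read_sbgnml(write_sbgnml(m))`` equals ``canonicalize_for_sbgn(m)``
    (identity whenever ``m`` already uses SBGN-expressible types).
    """
    violations = validate_model(model)
    if violations:
        raise ModelInvalid(violations)

    nsmap = {None: SBGN_NS, "pathmap": EXT_NS}
    root = etree.Element(_q("sbgn"), nsmap=nsmap)
    map_el = etree.SubElement(root, _q("map"))
    map_el.set("language", PD_LANGUAGE)
    ext = etree.SubElement(map_el, _q("extension"))
    props = etree.SubElement(ext, _q("mapProperties", EXT_NS))
    props.set("id", model.map_id)
    if model.name:
        props.set("name", model.name)
    props.set("width", fmt(model.width))
    props.set("height", fmt(model.height))

    registry = default_registry()

    def write_extension(parent, annotations=(), synonyms=(), notes="", polyline=()):
        if not (annotations or synonyms or notes or polyline):
            return
        e = etree.SubElement(parent, _q("extension"))
        if annotations:
            anns = etree.SubElement(e, _q("annotations", EXT_NS))
            for ann in annotations:
                ae = etree.SubElement(anns, _q("annotation", EXT_NS))
                ae.set("uri", resolve_uri(registry, ann))
                ae.set("namespace", ann.namespace)
                ae.set("identifier", ann.identifier)
                ae.set("relation", ann.relation)
        if synonyms:
            syns = etree.SubElement(e, _q("synonyms", EXT_NS))
            for s in synonyms:
                etree.SubElement(syns, _q("synonym", EXT_NS)).text = s
        if notes:
            etree.SubElement(e, _q("notes", EXT_NS)).text = notes
        if polyline:
            etree.SubElement(e, _q("polyline", EXT_NS)).text = " ".join(
                f"{fmt(x)},{fmt(y)}" for x, y in polyline
            )

    def write_glyph(parent, el: Element) -> etree._Element:
        g = etree.SubElement(parent, _q("glyph"))
        g.set("class", ELEMENT_TO_GLYPH[el.element_type])
        g.set("id", el.element_id)
        if el.compartment_ref:
            g.set("compartmentRef", el.compartment_ref)
        write_extension(g, el.annotations, el.synonyms, el.notes)
        label = etree.SubElement(g, _q("label"))
        label.set("text", el.name)
        bbox = etree.SubElement(g, _q("bbox"))
        bbox.set("x", fmt(el.bounds.x))
        bbox.set("y", fmt(el.bounds.y))
        bbox.set("w", fmt(el.bounds.w))
        bbox.set("h", fmt(el.bounds.h))
        return g

    # compartments first (SBGN convention), then top-level entities with
    # complex members nested inside their parent's glyph
    glyph_parents: dict[str, etree._Element] = {}
    for el in model.elements.values():
        if el.element_type is ElementType.COMPARTMENT:
            glyph_parents[el.element_id] = write_glyph(map_el, el)
    pending = [
        el for el in model.elements.values()
        if el.element_type is not ElementType.COMPARTMENT
    ]
    while pending:
        progressed = False
        still: list[Element] = []
        for el in pending:
            if el.parent_complex is None:
                parent = map_el
            elif el.parent_complex in glyph_parents:
                parent = glyph_parents[el.parent_complex]
            else:
                still.append(el)
                continue
            glyph_parents[el.element_id] = write_glyph(parent, el)
            progressed = True
        if not progressed:  # cycle guard; validation precludes this
            for el in still:
                glyph_parents[el.element_id] = write_glyph(map_el, el)
            still = []
        pending = still

    # one process glyph per interaction, arcs to/from it
    for inter in model.interactions.values():
        mid = _polyline_midpoint(inter.polyline)
        g = etree.SubElement(map_el, _q("glyph"))
        g.set("class", INTERACTION_TO_PROCESS[inter.interaction_type])
        g.set("id", inter.interaction_id)
        write_extension(g, inter.annotations, notes=inter.notes,
                        polyline=inter.polyline)
        bbox = etree.SubElement(g, _q("bbox"))
        bbox.set("x", fmt(mid[0] - _PROCESS_SIZE / 2))
        bbox.set("y", fmt(mid[1] - _PROCESS_SIZE / 2))
        bbox.set("w", fmt(_PROCESS_SIZE))
        bbox.set("h", fmt(_PROCESS_SIZE))

        def arc(cls: str, source: str, target: str, n: int) -> None:
            a = etree.SubElement(map_el, _q("arc"))
            a.set("class", cls)
            a.set("id", f"{inter.interaction_id}_a{n}")
            a.set("source", source)
            a.set("target", target)
            s = model.elements.get(source)
            t = model.elements.get(target)
            sp = s.bounds.center if s is not None else mid
            tp = t.bounds.center if t is not None else mid
            se = etree.SubElement(a, _q("start"))
            se.set("x", fmt(sp[0]))
            se.set("y", fmt(sp[1]))
            ee = etree.SubElement(a, _q("end"))
            ee.set("x", fmt(tp[0]))
            ee.set("y", fmt(tp[1]))

        n = 0
        for rid in inter.reactants:
            arc("consumption", rid, inter.interaction_id, n)
            n += 1
        for pid in inter.products:
            arc("production", inter.interaction_id, pid, n)
            n += 1
        for m in inter.modifiers:
            arc(ROLE_TO_ARC[m.role], m.element_id, inter.interaction_id, n)
            n += 1

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _polyline_midpoint(polyline):
    if not polyline:
        return (0.0, 0.0)
    k = (len(polyline) - 1) // 2
    if len(polyline) % 2:
        return polyline[k]
    (x1, y1), (x2, y2) = polyline[k], polyline[k + 1]
    return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_PROCESS_CLASSES = set(PROCESS_TO_INTERACTION)


def read_sbgnml(
    xml_text: str | bytes, registry: MiriamRegistry | None = None
) -> MapModel:
    model, _report = read_sbgnml_report(xml_text, registry)
    return model


def read_sbgnml_report(
    xml_text: str | bytes, registry: MiriamRegistry | None = None
) -> tuple[MapModel, ReadReport]:
    registry = registry or default_registry()
    report = ReadReport()
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from None

    qname = etree.QName(root)
    if qname.localname != "sbgn":
        raise UnsupportedDialect(f"root element is <{qname.localname}>, expected <sbgn>")
    ns = qname.namespace or SBGN_NS
    map_el = root.find(f"{{{ns}}}map")
    if map_el is None:
        raise UnsupportedDialect("no <map> element")
    language = map_el.get("language", PD_LANGUAGE)
    if language != PD_LANGUAGE:
        raise UnsupportedDialect(f"SBGN language {language!r} not supported (PD only)")

    model = MapModel(map_id="map")
    props = map_el.find(f"{{{ns}}}extension/{{{EXT_NS}}}mapProperties")
    if props is not None:
        model.map_id = props.get("id", "map")
        model.name = props.get("name", "")
        model.width = float(props.get("width", 0) or 0)
        model.height = float(props.get("height", 0) or 0)

    def read_extension(obj) -> tuple[list, list, str, list]:
        annotations, synonyms, notes, polyline = [], [], "", []
        e = obj.find(f"{{{ns}}}extension")
        if e is None:
            return annotations, synonyms, notes, polyline
        for ae in e.iterfind(f"{{{EXT_NS}}}annotations/{{{EXT_NS}}}annotation"):
            nsp, ident = ae.get("namespace"), ae.get("identifier")
            relation = ae.get("relation", "is")
            report.n_resources += 1
            if nsp and ident and nsp in registry:
                annotations.append(Annotation(nsp, ident, relation))
                report.n_parsed += 1
            elif ae.get("uri"):
                try:
                    ann = parse_uri(registry, ae.get("uri"))
                    annotations.append(
                        Annotation(ann.namespace, ann.identifier, relation)
                    )
                    report.n_parsed += 1
                except Exception:
                    report.unrecognized.append(ae.get("uri"))
                    report.warn(f"unrecognized annotation uri {ae.get('uri')!r}")
            else:
                report.unrecognized.append(f"{nsp}:{ident}")
                report.warn(f"unrecognized annotation {nsp}:{ident}")
        for se in e.iterfind(f"{{{EXT_NS}}}synonyms/{{{EXT_NS}}}synonym"):
            if se.text and se.text.strip():
                synonyms.append(se.text.strip())
        notes = (e.findtext(f"{{{EXT_NS}}}notes") or "").strip()
        pl = e.findtext(f"{{{EXT_NS}}}polyline")
        if pl:
            for token in pl.split():
                xs, ys = token.split(",")
                polyline.append((float(xs), float(ys)))
        return annotations, synonyms, notes, polyline

    def read_bbox(obj) -> Bounds:
        b = obj.find(f"{{{ns}}}bbox")
        if b is None:
            return Bounds(0.0, 0.0, 1.0, 1.0)
        return Bounds(
            float(b.get("x", 0)), float(b.get("y", 0)),
            float(b.get("w", 1)), float(b.get("h", 1)),
        )

    process_glyphs: dict[str, dict] = {}

    def walk_glyphs(parent, parent_complex: str | None):
        for g in parent.iterfind(f"{{{ns}}}glyph"):
            cls = g.get("class", "")
            gid = g.get("id")
            if gid is None:
                continue
            if cls in _PROCESS_CLASSES:
                annotations, _syn, notes, polyline = read_extension(g)
                process_glyphs[gid] = {
                    "type": PROCESS_TO_INTERACTION[cls],
                    "annotations": annotations,
                    "notes": notes,
                    "polyline": polyline,
                    "center": read_bbox(g).center,
                }
                continue
            etype = GLYPH_TO_ELEMENT.get(cls)
            if etype is None:
                report.warn(f"glyph {gid!r}: unknown class {cls!r}, mapped to UNKNOWN")
                etype = ElementType.UNKNOWN
            annotations, synonyms, notes, _pl = read_extension(g)
            label = g.find(f"{{{ns}}}label")
            name = label.get("text", "") if label is not None else ""
            model.add_element(Element(
                element_id=gid,
                element_type=etype,
                name=name,
                bounds=read_bbox(g),
                compartment_ref=g.get("compartmentRef"),
                parent_complex=parent_complex,
                synonyms=synonyms,
                annotations=annotations,
                notes=notes,
            ))
            walk_glyphs(
                g,
                gid if etype is ElementType.COMPLEX else parent_complex,
            )

    walk_glyphs(map_el, None)

    # group arcs by their process glyph
    participants: dict[str, dict[str, list]] = {
        pid: {"reactants": [], "products": [], "modifiers": []}
        for pid in process_glyphs
    }
    for a in map_el.iterfind(f"{{{ns}}}arc"):
        cls = a.get("class", "")
        source, target = a.get("source"), a.get("target")
        if cls == "consumption" and target in participants:
            participants[target]["reactants"].append(source)
        elif cls == "production" and source in participants:
            participants[source]["products"].append(target)
        elif cls in ARC_TO_ROLE and target in participants:
            participants[target]["modifiers"].append(
                Modifier(source, ARC_TO_ROLE[cls])
            )
        else:
            report.warn(f"arc {a.get('id')!r}: class {cls!r} not mapped, dropped")

    for pid, info in process_glyphs.items():
        parts = participants[pid]
        polyline = info["polyline"]
        if not polyline:
            centers = []
            for sid in parts["reactants"][:1]:
                if sid in model.elements:
                    centers.append(model.elements[sid].bounds.center)
            centers.append(info["center"])
            for sid in parts["products"][:1]:
                if sid in model.elements:
                    centers.append(model.elements[sid].bounds.center)
            polyline = centers if len(centers) >= 2 else [info["center"]] * 2
        model.add_interaction(Interaction(
            interaction_id=pid,
            interaction_type=info["type"],
            reactants=parts["reactants"],
            products=parts["products"],
            modifiers=parts["modifiers"],
            polyline=polyline,
            annotations=info["annotations"],
            notes=info["notes"],
        ))

    if model.width <= 0 or model.height <= 0:
        # no mapProperties extension: size the canvas to the content
        xs = [e.bounds.x2 for e in model.elements.values()] or [800.0]
        ys = [e.bounds.y2 for e in model.elements.values()] or [600.0]
        model.width = max(xs) + 10.0
        model.height = max(ys) + 10.0

    return model, report
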