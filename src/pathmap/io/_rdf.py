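"""Shared MIRIAM/RDF annotation block handling for the XML dialects.

CellDesigner files carry BioModels-qualifier RDF with ``urn:miriam:`` (or
identifiers.org) resources.  Readers must never silently drop a resource:
anything that cannot be mapped onto the registry is counted and logged, so
``parsed + unrecognized == source resources`` always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from urllib.parse import quote, unquote

from lxml import etree

from ..annotate import MiriamRegistry, default_registry
from ..model import Annotation

log = logging.getLogger(__name__)

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"
DC_NS = "http://purl.org/dc/elements/1.1/"

RDF_NSMAP = {"rdf": RDF_NS, "bqbiol": BQBIOL_NS, "bqmodel": BQMODEL_NS}

#: urn:miriam tokens seen in the wild mapped onto registry namespaces.
_URN_ALIASES = {
    "obo.chebi": "chebi",
    "obo.go": "go",
    "ncbigene": "entrez",
    "entrez.gene": "entrez",
    "chembl.compound": "chembl",
}


@dataclass
class ReadReport:
    """Bookkeeping for one parse: annotation accounting and dialect warnings."""

    n_resources: int = 0
    n_parsed: int = 0
    unrecognized: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        log.warning(message)


def resource_to_annotation(
    resource: str, relation: str, registry: MiriamRegistry
) -> Annotation | None:
    """Map an RDF resource URI/URN onto a registry annotation, or None."""
    ns = ident = None
    if resource.startswith("urn:miriam:"):
        rest = resource[len("urn:miriam:"):]
        if ":" in rest:
            ns, ident = rest.split(":", 1)
            ident = unquote(ident)
    elif "identifiers.org/" in resource:
        rest = resource.split("identifiers.org/", 1)[1]
        if "/" in rest:
            ns, ident = rest.split("/", 1)
            ident = unquote(ident)
        elif ":" in rest:
            # compact form: CHEBI:15355 -> (chebi, CHEBI:15355); ns:id otherwise
            prefix, tail = rest.split(":", 1)
            if prefix.isupper():
                ns, ident = prefix.lower(), unquote(rest)
            else:
                ns, ident = prefix, unquote(tail)
    if ns is None:
        return None
    ns = _URN_ALIASES.get(ns, ns)
    if ns not in registry:
        return None
    return Annotation(namespace=ns, identifier=ident, relation=relation)


def parse_rdf_annotations(
    annotation_el: etree._Element | None,
    registry: MiriamRegistry,
    report: ReadReport,
    context: str,
) -> list[Annotation]:
    """Collect MIRIAM annotations from an SBML ``<annotation>`` element."""
    out: list[Annotation] = []
    if annotation_el is None:
        return out
    for li in annotation_el.iter(f"{{{RDF_NS}}}li"):
        resource = li.get(f"{{{RDF_NS}}}resource")
        if resource is None:
            continue
        report.n_resources += 1
        qualifier = li.getparent().getparent()  # li -> Bag -> qualifier
        relation = etree.QName(qualifier).localname if qualifier is not None else "is"
        ann = resource_to_annotation(resource, relation, registry)
        if ann is None:
            report.unrecognized.append(resource)
            report.warn(f"{context}: unrecognized annotation resource {resource!r}")
        else:
            out.append(ann)
            report.n_parsed += 1
    return out


def build_rdf(parent: etree._Element, about: str, annotations: list[Annotation]) -> None:
    """Append a BioModels-qualifier RDF block carrying ``urn:miriam`` URNs."""
    if not annotations:
        return
    rdf = etree.SubElement(parent, f"{{{RDF_NS}}}RDF", nsmap=RDF_NSMAP)
    desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
    desc.set(f"{{{RDF_NS}}}about", f"#{about}")
    by_relation: dict[str, list[Annotation]] = {}
    for ann in annotations:
        by_relation.setdefault(ann.relation, []).append(ann)
    for relation, group in by_relation.items():
        qualifier = etree.SubElement(desc, f"{{{BQBIOL_NS}}}{relation}")
        bag = etree.SubElement(qualifier, f"{{{RDF_NS}}}Bag")
        for ann in group:
            li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
            li.set(
                f"{{{RDF_NS}}}resource",
                f"urn:miriam:{ann.namespace}:{quote(ann.identifier, safe='')}",
            )


def fmt(value: float) -> str:
    """Shortest exact decimal text for a float (round-trips bit-exactly)."""
    return repr(float(value))
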