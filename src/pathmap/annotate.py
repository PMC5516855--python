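"""MIRIAM registry, cross-reference resolution, automatic annotation and
rule-based verification.

Annotators come in two flavours, mirroring how curation platforms wire them:

* NAME-triggered — queried with the element's display name (e.g. an HGNC
  symbol lookup);
* MIRIAM-triggered — queried with the element's existing identifier in the
  namespace the annotator declares (e.g. a UniProt accession already on the
  element).

All clients satisfy the same :class:`AnnotatorClient` contract.  The default
client is an offline fixture client reading one JSON document per
(annotator, query); live HTTP adapters can implement the same contract.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .errors import InvalidIdentifier, UnknownNamespace
from .model import Annotation, Element, ElementType, Interaction, MapModel

log = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "_data"


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistryEntry:
    namespace: str
    display_name: str
    uri_pattern: str  # contains exactly one "{id}" placeholder
    id_regex: str

    def compiled(self) -> re.Pattern:
        return re.compile(self.id_regex)


#: Namespaces seeded out of the box.  The registry is user-extensible via a
#: YAML config file, so deployments can grow it to whatever their maps need.
_DEFAULT_ENTRIES = [
    # (namespace, display name, identifiers.org path, identifier regex)
    ("uniprot", "UniProt", "https://identifiers.org/uniprot/{id}",
     r"^([A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})|([OPQ][0-9][A-Z0-9]{3}[0-9])(\.\d+)?$"),
    ("chebi", "ChEBI", "https://identifiers.org/CHEBI:{id}", r"^CHEBI:\d+$"),
    ("ensembl", "Ensembl", "https://identifiers.org/ensembl/{id}",
     r"^ENS[A-Z]*[GTP]\d{11}(\.\d+)?$"),
    ("entrez", "NCBI Gene (Entrez)", "https://identifiers.org/ncbigene/{id}", r"^\d+$"),
    ("go", "Gene Ontology", "https://identifiers.org/GO:{id}", r"^GO:\d{7}$"),
    ("hgnc", "HGNC", "https://identifiers.org/hgnc/{id}", r"^\d{1,5}$"),
    ("hgnc.symbol", "HGNC Symbol", "https://identifiers.org/hgnc.symbol/{id}",
     r"^[A-Za-z0-9_\-]+(@)?$"),
    ("pubmed", "PubMed", "https://identifiers.org/pubmed/{id}", r"^\d+$"),
    ("doi", "DOI", "https://identifiers.org/doi/{id}", r"^10\.\d{4,9}/\S+$"),
    ("drugbank", "DrugBank", "https://identifiers.org/drugbank/{id}", r"^DB\d{5}$"),
    ("chembl", "ChEMBL", "https://identifiers.org/chembl.compound/{id}", r"^CHEMBL\d+$"),
    ("kegg.compound", "KEGG Compound", "https://identifiers.org/kegg.compound/{id}",
     r"^C\d+$"),
    ("kegg.pathway", "KEGG Pathway", "https://identifiers.org/kegg.pathway/{id}",
     r"^\w{2,4}\d{5}$"),
    ("taxonomy", "NCBI Taxonomy", "https://identifiers.org/taxonomy/{id}", r"^\d+$"),
    ("ec-code", "Enzyme Nomenclature", "https://identifiers.org/ec-code/{id}",
     r"^\d+\.-(\.-){0,2}$|^\d+(\.\d+){1,3}$"),
    ("interpro", "InterPro", "https://identifiers.org/interpro/{id}", r"^IPR\d{6}$"),
    ("pfam", "Pfam", "https://identifiers.org/pfam/{id}", r"^PF\d{5}$"),
    ("reactome", "Reactome", "https://identifiers.org/reactome/{id}",
     r"^R-[A-Z]{3}-\d+(-\d+)?$"),
    ("mirbase", "miRBase", "https://identifiers.org/mirbase/{id}", r"^MI\d{7}$"),
    ("mesh", "MeSH", "https://identifiers.org/mesh/{id}", r"^[CD]\d{6,9}$"),
    ("refseq", "RefSeq", "https://identifiers.org/refseq/{id}",
     r"^[A-Z]{2}_\d+(\.\d+)?$"),
    ("omim", "OMIM", "https://identifiers.org/mim/{id}", r"^\d{6}$"),
]


class MiriamRegistry:
    """Maps registry namespaces to identifiers.org URI patterns and
    identifier validation regexes."""

    def __init__(self, entries: Optional[Iterable[RegistryEntry]] = None):
        self.entries: dict[str, RegistryEntry] = {}
        for e in entries if entries is not None else default_entries():
            self.add(e)

    def add(self, entry: RegistryEntry) -> None:
        if entry.uri_pattern.count("{id}") != 1:
            raise ValueError(
                f"{entry.namespace}: URI pattern must contain exactly one {{id}}"
            )
        self.entries[entry.namespace] = entry

    def __contains__(self, namespace: str) -> bool:
        return namespace in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, namespace: str) -> RegistryEntry:
        try:
            return self.entries[namespace]
        except KeyError:
            raise UnknownNamespace(namespace) from None

    def validate(self, annotation: Annotation) -> None:
        entry = self.get(annotation.namespace)
        if not entry.compiled().fullmatch(annotation.identifier):
            raise InvalidIdentifier(
                f"{annotation.identifier!r} does not match the "
                f"{annotation.namespace} pattern {entry.id_regex}"
            )

    def is_valid(self, annotation: Annotation) -> bool:
        try:
            self.validate(annotation)
        except (UnknownNamespace, InvalidIdentifier):
            return False
        return True

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "MiriamRegistry":
        """Load defaults merged with a YAML config file.

        Schema::

            namespaces:
              mynamespace:
                name: Display Name
                uri_pattern: "https://identifiers.org/mynamespace/{id}"
                id_regex: "^\\d+$"
        """
        registry = cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        for ns, spec in (data.get("namespaces") or {}).items():
            registry.add(
                RegistryEntry(
                    namespace=ns,
                    display_name=spec.get("name", ns),
                    uri_pattern=spec["uri_pattern"],
                    id_regex=spec.get("id_regex", ".*"),
                )
            )
        return registry


def default_entries() -> list[RegistryEntry]:
    return [RegistryEntry(*row) for row in _DEFAULT_ENTRIES]


_default_registry: Optional[MiriamRegistry] = None


def default_registry() -> MiriamRegistry:
    global _default_registry
    if _default_registry is None:
        _default_registry = MiriamRegistry()
    return _default_registry


def resolve_uri(registry: MiriamRegistry, annotation: Annotation) -> str:
    """identifiers.org URI for a (namespace, identifier) annotation."""
    entry = registry.get(annotation.namespace)
    registry.validate(annotation)
    identifier = annotation.identifier
    # compact-identifier style patterns embed the prefix, e.g. CHEBI:{id}
    if ":{id}" in entry.uri_pattern and ":" in identifier:
        identifier = identifier.split(":", 1)[1]
    return entry.uri_pattern.replace("{id}", identifier)


def parse_uri(registry: MiriamRegistry, uri: str) -> Annotation:
    """Inverse of :func:`resolve_uri` for URIs built from registry patterns."""
    for entry in registry.entries.values():
        prefix, suffix = entry.uri_pattern.split("{id}")
        if uri.startswith(prefix) and uri.endswith(suffix):
            ident = uri[len(prefix): len(uri) - len(suffix) if suffix else len(uri)]
            if ":" in prefix.rsplit("/", 1)[-1]:
                # compact style: re-attach the embedded prefix
                ident = prefix.rsplit("/", 1)[-1] + ident
            ann = Annotation(namespace=entry.namespace, identifier=ident)
            if entry.compiled().fullmatch(ident):
                return ann
    raise UnknownNamespace(uri)


# ---------------------------------------------------------------------------
# Annotator clients
# ---------------------------------------------------------------------------


@dataclass
class AnnotatorRecord:
    """What a lookup returns: a preferred name, synonyms, cross-references
    and a free-text description."""

    preferred_name: str = ""
    synonyms: list[str] = field(default_factory=list)
    cross_references: list[tuple[str, str]] = field(default_factory=list)
    description: str = ""


class AnnotatorClient:
    """Contract all annotator backends satisfy."""

    def lookup(self, query: str) -> Optional[AnnotatorRecord]:  # pragma: no cover
        raise NotImplementedError


def _fixture_slug(query: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.\-]", "_", query.strip())


class FixtureAnnotatorClient(AnnotatorClient):
    """Offline client reading one JSON document per (annotator, query) from
    a fixture directory: ``<root>/<annotator_id>/<query>.json``.

    Queries are case-insensitive (slugs are matched lowercased).
    """

    def __init__(self, annotator_id: str, root: Union[str, Path, None] = None):
        self.annotator_id = annotator_id
        self.root = Path(root) if root is not None else _DATA_DIR / "annotators"

    def lookup(self, query: str) -> Optional[AnnotatorRecord]:
        folder = self.root / self.annotator_id
        if not folder.is_dir():
            return None
        want = _fixture_slug(query).lower()
        for candidate in sorted(folder.glob("*.json")):
            if candidate.stem.lower() == want:
                data = json.loads(candidate.read_text())
                return AnnotatorRecord(
                    preferred_name=data.get("preferred_name", ""),
                    synonyms=list(data.get("synonyms", [])),
                    cross_references=[
                        (ns, ident) for ns, ident in data.get("cross_references", [])
                    ],
                    description=data.get("description", ""),
                )
        return None


class BlockingClient(AnnotatorClient):
    """Client that fails every lookup; used to assert offline behaviour."""

    def __init__(self, message: str = "network access forbidden"):
        self.message = message
        self.calls: list[str] = []

    def lookup(self, query: str) -> Optional[AnnotatorRecord]:
        self.calls.append(query)
        raise ConnectionError(self.message)


NAME = "NAME"


@dataclass
class AnnotatorSpec:
    """One configured annotator: what fires it and which client serves it.

    ``trigger`` is either :data:`NAME` or the registry namespace whose
    presence on an element fires a MIRIAM-triggered lookup.
    """

    annotator_id: str
    trigger: str  # NAME or a registry namespace
    client: AnnotatorClient

    @property
    def is_name_triggered(self) -> bool:
        return self.trigger == NAME


#: annotator id -> trigger, as wired in the platform this emulates.
DEFAULT_ANNOTATOR_TRIGGERS: dict[str, str] = {
    "hgnc": NAME,
    "biocompendium": NAME,
    "chebi": "chebi",
    "ensembl": "ensembl",
    "entrez": "entrez",
    "uniprot": "uniprot",
    "go": "go",
}


def default_annotator_specs(
    fixture_root: Union[str, Path, None] = None,
) -> list[AnnotatorSpec]:
    """The stock annotator set, backed by offline fixture clients."""
    return [
        AnnotatorSpec(aid, trig, FixtureAnnotatorClient(aid, fixture_root))
        for aid, trig in DEFAULT_ANNOTATOR_TRIGGERS.items()
    ]


# ---------------------------------------------------------------------------
# Automatic annotation
# ---------------------------------------------------------------------------


@dataclass
class ElementAnnotationReport:
    element_id: str
    added: list[Annotation] = field(default_factory=list)
    synonyms_added: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)   # "annotator: reason"
    failed: list[str] = field(default_factory=list)    # "annotator: error"


@dataclass
class AnnotationReport:
    per_element: dict[str, ElementAnnotationReport] = field(default_factory=dict)

    def entry(self, element_id: str) -> ElementAnnotationReport:
        return self.per_element.setdefault(
            element_id, ElementAnnotationReport(element_id)
        )

    @property
    def n_added(self) -> int:
        return sum(len(r.added) for r in self.per_element.values())

    @property
    def n_failed(self) -> int:
        return sum(len(r.failed) for r in self.per_element.values())


def _merge_record(
    element: Element,
    record: AnnotatorRecord,
    registry: MiriamRegistry,
    report: ElementAnnotationReport,
    annotator_id: str,
) -> None:
    existing = element.annotation_set()
    for ns, ident in record.cross_references:
        if ns not in registry:
            report.skipped.append(f"{annotator_id}: unknown namespace {ns!r}")
            continue
        ann = Annotation(namespace=ns, identifier=ident)
        if not registry.is_valid(ann):
            report.skipped.append(f"{annotator_id}: invalid id {ns}:{ident}")
            continue
        if ann in existing:
            continue
        element.annotations.append(ann)
        existing.add(ann)
        report.added.append(ann)
    known = {element.name.casefold()} | {s.casefold() for s in element.synonyms}
    for syn in [record.preferred_name, *record.synonyms]:
        if syn and syn.casefold() not in known:
            element.synonyms.append(syn)
            known.add(syn.casefold())
            report.synonyms_added.append(syn)


def annotate_model(
    model: MapModel,
    specs: Iterable[AnnotatorSpec],
    registry: Optional[MiriamRegistry] = None,
) -> AnnotationReport:
    """Run every annotator over every element; merge cross-references and
    synonyms as set unions.

    Idempotent and monotone: annotations are only ever added, and a second
    run adds nothing.  Client failures are recorded per element and never
    abort the run.
    """
    registry = registry or default_registry()
    specs = list(specs)
    report = AnnotationReport()
    for element in model.elements.values():
        entry = report.entry(element.element_id)
        for spec in specs:
            if spec.is_name_triggered:
                queries = [element.name] if element.name else []
            else:
                queries = [
                    a.identifier
                    for a in element.annotations
                    if a.namespace == spec.trigger
                ]
            for query in queries:
                try:
                    record = spec.client.lookup(query)
                except Exception as exc:  # noqa: BLE001 - contract: never abort
                    entry.failed.append(f"{spec.annotator_id}: {exc}")
                    continue
                if record is None:
                    entry.skipped.append(f"{spec.annotator_id}: no hit for {query!r}")
                    continue
                _merge_record(element, record, registry, entry, spec.annotator_id)
    return report


# ---------------------------------------------------------------------------
# Verification rules
# ---------------------------------------------------------------------------

INTERACTION = "INTERACTION"


@dataclass(frozen=True)
class VerificationRule:
    """Completeness requirement: targets of a class must carry at least one
    annotation from ``required_namespaces``."""

    target: str  # an ElementType value or INTERACTION
    required_namespaces: frozenset[str]
    message: str = "{target} {id} lacks a required annotation ({namespaces})"

    def render(self, object_id: str) -> str:
        return self.message.format(
            target=self.target,
            id=object_id,
            namespaces=", ".join(sorted(self.required_namespaces)),
        )


@dataclass(frozen=True)
class VerificationWarning:
    rule: VerificationRule
    target_id: str
    message: str


def verify_annotations(
    model: MapModel, rules: Iterable[VerificationRule]
) -> list[VerificationWarning]:
    """One warning per (rule, target) pair whose annotations contain none of
    the rule's required namespaces.

    Each rule requires *at least one of* its namespace set; conjunctions are
    expressed with several rules.
    """
    warnings: list[VerificationWarning] = []
    for rule in rules:
        targets: list[tuple[str, Union[Element, Interaction]]]
        if rule.target == INTERACTION:
            targets = list(model.interactions.items())
        else:
            wanted = ElementType(rule.target)
            targets = [
                (eid, e)
                for eid, e in model.elements.items()
                if e.element_type is wanted
            ]
        for oid, obj in targets:
            if not obj.has_namespace(rule.required_namespaces):
                warnings.append(
                    VerificationWarning(rule, oid, rule.render(oid))
                )
    return warnings


def load_rules(path: Union[str, Path]) -> list[VerificationRule]:
    """Read verification rules from YAML::

        rules:
          - target: INTERACTION
            requires: [pubmed]
            message: "interaction {id} has no literature reference"
          - target: PROTEIN
            requires: [uniprot, hgnc.symbol]
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    rules = []
    for spec in data.get("rules", []):
        kwargs = {}
        if "message" in spec:
            kwargs["message"] = spec["message"]
        rules.append(
            VerificationRule(
                target=spec["target"],
                required_namespaces=frozenset(spec["requires"]),
                **kwargs,
            )
        )
    return rules
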