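"""Content search and drug-target lookup.

Queries are comma-separated term lists.  Each term gets its own marker
color index so multi-element queries can show "markers of different color"
on the map; indices are consecutive and distinct within a query.

Matching is exact-first: a term matches element names, synonyms and
annotation identifiers case-insensitively; substring matching is attempted
only when exact matching yields nothing (so short terms don't light up the
whole map).

Drug-target search queries every configured DrugBank/ChEMBL-style client
per term; retrieved target identifiers and gene symbols are matched to map
elements with identifier precedence (the overlay matcher semantics).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .model import Element, MapModel
from .overlay import OverlayEntry, entry_matches_element

log = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "_data"


def split_terms(query_text: str) -> list[str]:
    return [t.strip() for t in query_text.split(",") if t.strip()]


# ---------------------------------------------------------------------------
# Element search
# ---------------------------------------------------------------------------


@dataclass
class SearchHit:
    term: str
    element_ids: list[str]
    color_index: int


def _element_tokens(element: Element) -> list[str]:
    return [
        element.name,
        *element.synonyms,
        *(a.identifier for a in element.annotations),
    ]


def _term_matches(model: MapModel, term: str) -> list[str]:
    wanted = term.casefold()
    exact = [
        eid
        for eid, el in model.elements.items()
        if any(tok.casefold() == wanted for tok in _element_tokens(el) if tok)
    ]
    if exact:
        return exact
    return [
        eid
        for eid, el in model.elements.items()
        if any(wanted in tok.casefold() for tok in _element_tokens(el) if tok)
    ]


def search_elements(model: MapModel, query_text: str) -> list[SearchHit]:
    """One :class:`SearchHit` per comma-separated term, in query order.

    Terms without matches yield hits with empty id lists (reported, not
    errors).  Color indices are consecutive: 0, 1, 2, …
    """
    return [
        SearchHit(term=term, element_ids=_term_matches(model, term), color_index=i)
        for i, term in enumerate(split_terms(query_text))
    ]


# ---------------------------------------------------------------------------
# Drug-target lookup
# ---------------------------------------------------------------------------


@dataclass
class DrugRecord:
    name: str
    source: str  # "drugbank" | "chembl"
    description: str = ""
    synonyms: list[str] = field(default_factory=list)
    #: cross-reference targets: (namespace, identifier)
    targets: list[tuple[str, str]] = field(default_factory=list)
    #: gene-symbol targets
    target_symbols: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.name:
            raise ValueError("drug record requires a name")
        if not self.source:
            raise ValueError("drug record requires a source")


class DrugClient:
    """Contract for drug database backends."""

    source = "unknown"

    def lookup(self, name: str) -> Optional[DrugRecord]:  # pragma: no cover
        raise NotImplementedError


def _fixture_slug(query: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.\-]", "_", query.strip())


class FixtureDrugClient(DrugClient):
    """Offline client reading one JSON document per (source, drug name)
    from ``<root>/<source>/<name>.json`` (name matched case-insensitively)."""

    def __init__(self, source: str, root: Union[str, Path, None] = None):
        self.source = source
        self.root = Path(root) if root is not None else _DATA_DIR / "drugs"

    def lookup(self, name: str) -> Optional[DrugRecord]:
        folder = self.root / self.source
        if not folder.is_dir():
            return None
        want = _fixture_slug(name).lower()
        for candidate in sorted(folder.glob("*.json")):
            if candidate.stem.lower() != want:
                continue
            data = json.loads(candidate.read_text())
            return DrugRecord(
                name=data.get("name", name),
                source=self.source,
                description=data.get("description", ""),
                synonyms=list(data.get("synonyms", [])),
                targets=[(ns, ident) for ns, ident in data.get("targets", [])],
                target_symbols=list(data.get("target_symbols", [])),
            )
        return None


def default_drug_clients(root: Union[str, Path, None] = None) -> list[DrugClient]:
    return [FixtureDrugClient("drugbank", root), FixtureDrugClient("chembl", root)]


@dataclass
class DrugQueryResult:
    """All hits for one queried drug term: records from every client that
    knew it (kept separately per source), the union of matched element ids,
    and the term's marker color."""

    term: str
    records: list[DrugRecord]
    matched_element_ids: list[str]
    color_index: int
    failures: list[str] = field(default_factory=list)


@dataclass
class DrugQueryReport:
    results: list[DrugQueryResult]
    #: terms no client returned a record for
    misses: list[str] = field(default_factory=list)


def _match_targets(model: MapModel, records: Iterable[DrugRecord]) -> list[str]:
    matched: list[str] = []
    seen: set[str] = set()
    for record in records:
        entries = [
            OverlayEntry(namespace=ns, identifier=ident)
            for ns, ident in record.targets
        ] + [OverlayEntry(name=symbol) for symbol in record.target_symbols]
        for entry in entries:
            for eid, el in model.elements.items():
                if eid not in seen and entry_matches_element(entry, el):
                    matched.append(eid)
                    seen.add(eid)
    return matched


def find_drug_targets(
    model: MapModel, query_text: str, clients: list[DrugClient]
) -> DrugQueryReport:
    """Query every client for every comma-separated drug name and map the
    retrieved targets onto the model.

    A client failure for one drug is recorded on that drug's result and the
    remaining drugs are still processed.  Records from several sources for
    the same drug are all kept; their target sets are unioned for marker
    placement.
    """
    if not clients:
        raise ValueError("at least one drug client is required")
    results: list[DrugQueryResult] = []
    misses: list[str] = []
    for i, term in enumerate(split_terms(query_text)):
        records: list[DrugRecord] = []
        failures: list[str] = []
        for client in clients:
            try:
                record = client.lookup(term)
            except Exception as exc:  # noqa: BLE001 - contract: keep going
                failures.append(f"{client.source}: {exc}")
                continue
            if record is not None:
                records.append(record)
        if not records:
            misses.append(term)
        results.append(DrugQueryResult(
            term=term,
            records=records,
            matched_element_ids=_match_targets(model, records),
            color_index=i,
            failures=failures,
        ))
    return DrugQueryReport(results=results, misses=misses)
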