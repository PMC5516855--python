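"""Experimental-data overlays ("map staining").

Datasets arrive as UTF-8 tab-delimited text.  ``#`` starts a comment line;
a leading ``#name: <title>`` comment names the dataset.  The header row uses
the documented column vocabulary::

    name  identifier  type  value  color  line_width

* ``name`` — element/interaction display name (case-insensitive match
  against names and synonyms);
* ``identifier`` — ``namespace:identifier`` MIRIAM cross-reference;
  identifier matches take precedence over name matches;
* ``type`` — optional element-type filter, so one file can carry multiple
  'omics layers (e.g. ``PROTEIN`` rows and ``RNA`` rows);
* ``value`` — real in [-1, 1], mapped through the dataset color scheme;
* ``color`` — explicit ``#RRGGBB``, overriding the computed color;
* ``line_width`` — positive real, applied to matched interactions.

Values map to colors by linear per-channel interpolation between the scheme
poles: −1 → negative color, 0 → neutral, +1 → positive, with rounding
half-up per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .errors import EmptyDataset, FormatError, ValueOutOfRange
from .model import ElementType, MapModel

log = logging.getLogger(__name__)

COLUMNS = ("name", "identifier", "type", "value", "color", "line_width")

DEFAULT_SCHEME = {
    "negative": "#0000FF",
    "neutral": "#FFFFFF",
    "positive": "#FF0000",
}


def _parse_hex(color: str) -> tuple[int, int, int]:
    c = color.strip().lstrip("#")
    if len(c) != 6 or any(ch not in "0123456789abcdefABCDEF" for ch in c):
        raise ValueError(f"not a hex color: {color!r}")
    return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)


def _to_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


@dataclass(frozen=True)
class OverlayEntry:
    name: Optional[str] = None
    namespace: Optional[str] = None
    identifier: Optional[str] = None
    element_type: Optional[ElementType] = None
    value: Optional[float] = None
    color: Optional[str] = None
    line_width: Optional[float] = None


@dataclass
class ColorScheme:
    negative: str = DEFAULT_SCHEME["negative"]
    neutral: str = DEFAULT_SCHEME["neutral"]
    positive: str = DEFAULT_SCHEME["positive"]

    def __post_init__(self):
        for c in (self.negative, self.neutral, self.positive):
            _parse_hex(c)  # raises on invalid hex


@dataclass
class RejectedRow:
    row_number: int  # 1-based physical line number
    reason: str


@dataclass
class OverlayDataset:
    name: str = ""
    entries: list[OverlayEntry] = field(default_factory=list)
    scheme: ColorScheme = field(default_factory=ColorScheme)
    rejected: list[RejectedRow] = field(default_factory=list)

    def entry_color(self, entry: OverlayEntry) -> Optional[str]:
        """Explicit color if present, else the scheme color of the value."""
        if entry.color is not None:
            return entry.color
        if entry.value is not None:
            return value_to_color(entry.value, self.scheme)
        return None


def value_to_color(value: float, scheme: Optional[ColorScheme] = None) -> str:
    """Linear channel-wise interpolation: 0 → neutral, ±1 → poles."""
    scheme = scheme or ColorScheme()
    if not -1.0 <= value <= 1.0:
        raise ValueOutOfRange(f"overlay value {value} outside [-1, 1]")
    neutral = _parse_hex(scheme.neutral)
    pole = _parse_hex(scheme.positive if value >= 0 else scheme.negative)
    t = abs(value)
    rgb = tuple(
        int(n + (p - n) * t + 0.5)  # round half up per channel
        for n, p in zip(neutral, pole)
    )
    return _to_hex(rgb)


def parse_overlay(text: str) -> OverlayDataset:
    """Parse a tab-delimited overlay file into a dataset.

    Rows violating entry invariants are rejected with their line numbers in
    ``dataset.rejected``; an unknown header column raises
    :class:`FormatError`; a file with no valid rows raises
    :class:`EmptyDataset`.
    """
    dataset = OverlayDataset()
    header: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n\r")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip().lstrip("#").strip()
            if body.lower().startswith("name:"):
                dataset.name = body[len("name:"):].strip()
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip().lower() for c in cells]
            unknown = [c for c in header if c not in COLUMNS]
            if unknown:
                raise FormatError(f"unknown header column(s): {', '.join(unknown)}")
            continue
        row = {
            col: cells[i].strip() if i < len(cells) else ""
            for i, col in enumerate(header)
        }
        try:
            dataset.entries.append(_row_to_entry(row))
        except ValueError as exc:
            dataset.rejected.append(RejectedRow(lineno, str(exc)))
            log.warning("overlay row %d rejected: %s", lineno, exc)
    if header is None:
        raise FormatError("no header row found")
    if not dataset.entries:
        raise EmptyDataset(
            "no valid data rows"
            + (f" ({len(dataset.rejected)} rejected)" if dataset.rejected else "")
        )
    return dataset


def _row_to_entry(row: dict[str, str]) -> OverlayEntry:
    name = row.get("name") or None
    namespace = identifier = None
    if row.get("identifier"):
        ident = row["identifier"]
        if ":" not in ident:
            raise ValueError(f"identifier {ident!r} is not namespace:identifier")
        namespace, identifier = ident.split(":", 1)
        if namespace.isupper():  # compact form, e.g. CHEBI:15355
            namespace, identifier = namespace.lower(), ident
    element_type = None
    if row.get("type"):
        try:
            element_type = ElementType(row["type"].upper())
        except ValueError:
            raise ValueError(f"unknown element type {row['type']!r}") from None
    value = None
    if row.get("value"):
        value = float(row["value"])
        if not -1.0 <= value <= 1.0:
            raise ValueError(f"value {value} out of [-1,1]")
    color = None
    if row.get("color"):
        _parse_hex(row["color"])
        color = row["color"].upper() if row["color"].startswith("#") else "#" + row["color"].upper()
    line_width = None
    if row.get("line_width"):
        line_width = float(row["line_width"])
        if line_width <= 0:
            raise ValueError(f"line_width {line_width} must be positive")
    if value is None and color is None:
        raise ValueError("row carries neither value nor color")
    if name is None and identifier is None:
        raise ValueError("row carries neither name nor identifier")
    return OverlayEntry(
        name=name,
        namespace=namespace,
        identifier=identifier,
        element_type=element_type,
        value=value,
        color=color,
        line_width=line_width,
    )


def serialize_overlay(dataset: OverlayDataset) -> str:
    """Inverse of :func:`parse_overlay` on valid datasets."""
    lines = []
    if dataset.name:
        lines.append(f"#name: {dataset.name}")
    lines.append("\t".join(COLUMNS))
    for e in dataset.entries:
        ident = ""
        if e.identifier is not None:
            ident = (
                e.identifier
                if ":" in e.identifier
                else f"{e.namespace}:{e.identifier}"
            )
        lines.append("\t".join([
            e.name or "",
            ident,
            e.element_type.value if e.element_type else "",
            "" if e.value is None else repr(e.value),
            e.color or "",
            "" if e.line_width is None else repr(e.line_width),
        ]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Matching entries to model objects
# ---------------------------------------------------------------------------


@dataclass
class OverlayBinding:
    """Result of matching a dataset against a model: per entry, the matched
    element and interaction ids; entries matching nothing are listed (and
    reported, never fatal)."""

    dataset: OverlayDataset
    element_matches: list[list[str]] = field(default_factory=list)
    interaction_matches: list[list[str]] = field(default_factory=list)
    unmatched: list[int] = field(default_factory=list)  # entry indices

    def element_styles(self) -> dict[str, str]:
        """element id -> fill color, later entries winning conflicts."""
        styles: dict[str, str] = {}
        for entry, ids in zip(self.dataset.entries, self.element_matches):
            color = self.dataset.entry_color(entry)
            if color is None:
                continue
            for eid in ids:
                styles[eid] = color
        return styles

    def interaction_styles(self) -> dict[str, tuple[str | None, float | None]]:
        """interaction id -> (line color, line width)."""
        styles: dict[str, tuple[str | None, float | None]] = {}
        for entry, ids in zip(self.dataset.entries, self.interaction_matches):
            color = self.dataset.entry_color(entry)
            for iid in ids:
                styles[iid] = (color, entry.line_width)
        return styles


def entry_matches_element(entry: OverlayEntry, element) -> bool:
    """Single-pair match predicate (shared with the drug-target matcher).

    Identifier match takes precedence: when the entry carries an identifier,
    only annotation matches count.  Name matching is case-insensitive over
    name + synonyms.  The element-type filter applies in both modes.
    """
    if entry.element_type is not None and element.element_type is not entry.element_type:
        return False
    if entry.identifier is not None:
        return any(
            a.namespace == entry.namespace and a.identifier == entry.identifier
            for a in element.annotations
        )
    if entry.name is not None:
        wanted = entry.name.casefold()
        if element.name.casefold() == wanted:
            return True
        return any(s.casefold() == wanted for s in element.synonyms)
    return False


def entry_matches_interaction(entry: OverlayEntry, interaction) -> bool:
    if entry.element_type is not None:
        return False
    if entry.identifier is not None:
        return any(
            a.namespace == entry.namespace and a.identifier == entry.identifier
            for a in interaction.annotations
        )
    return False


def match_entries(dataset: OverlayDataset, model: MapModel) -> OverlayBinding:
    """Match every entry against every element and interaction."""
    binding = OverlayBinding(dataset)
    for i, entry in enumerate(dataset.entries):
        elements = [
            eid
            for eid, el in model.elements.items()
            if entry_matches_element(entry, el)
        ]
        interactions = [
            iid
            for iid, inter in model.interactions.items()
            if entry_matches_interaction(entry, inter)
        ]
        binding.element_matches.append(elements)
        binding.interaction_matches.append(interactions)
        if not elements and not interactions:
            binding.unmatched.append(i)
    return binding


def combine_element_styles(bindings: list[OverlayBinding]) -> dict[str, str]:
    """Overlay several datasets in upload order; later datasets win on
    conflicting objects."""
    styles: dict[str, str] = {}
    for b in bindings:
        styles.update(b.element_styles())
    return styles
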