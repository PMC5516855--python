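"""In-memory representation of an SBGN-compliant molecular interaction map.

A :class:`MapModel` is the format-neutral container every reader produces and
every writer, renderer and exporter consumes.  Geometry uses a single
convention throughout the toolkit: continuous canvas units, origin at the
top-left corner, y increasing downward (the convention of raster tiling).

Element types follow the CellDesigner species-class vocabulary; species
classes outside it are mapped to ``UNKNOWN`` with a logged warning rather
than failing, so dialect drift in source files degrades gracefully.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Union

import networkx as nx

from .errors import TargetNotFound

log = logging.getLogger(__name__)

#: Geometric tolerance (canvas units) for bounds comparisons.
GEOM_TOL = 1e-6


class ElementType(str, Enum):
    PROTEIN = "PROTEIN"
    GENE = "GENE"
    RNA = "RNA"
    ANTISENSE_RNA = "ANTISENSE_RNA"
    SIMPLE_MOLECULE = "SIMPLE_MOLECULE"
    ION = "ION"
    DRUG = "DRUG"
    PHENOTYPE = "PHENOTYPE"
    UNKNOWN = "UNKNOWN"
    DEGRADED = "DEGRADED"
    COMPLEX = "COMPLEX"
    COMPARTMENT = "COMPARTMENT"
    TEXT_AREA = "TEXT_AREA"


#: Types that act as visual areas: candidates for semantic-zoom covers.
AREA_TYPES = frozenset(
    {ElementType.COMPARTMENT, ElementType.COMPLEX, ElementType.TEXT_AREA}
)


class InteractionType(str, Enum):
    STATE_TRANSITION = "STATE_TRANSITION"
    TRANSPORT = "TRANSPORT"
    HETERODIMER_ASSOCIATION = "HETERODIMER_ASSOCIATION"
    DISSOCIATION = "DISSOCIATION"
    CATALYSIS = "CATALYSIS"
    INHIBITION = "INHIBITION"
    TRIGGER = "TRIGGER"
    PHYSICAL_STIMULATION = "PHYSICAL_STIMULATION"
    MODULATION = "MODULATION"
    UNKNOWN = "UNKNOWN"


class ModifierRole(str, Enum):
    """Role a modifier species plays in a reaction (CellDesigner
    modification types / SBGN modulation arc classes)."""

    CATALYSIS = "CATALYSIS"
    INHIBITION = "INHIBITION"
    PHYSICAL_STIMULATION = "PHYSICAL_STIMULATION"
    TRIGGER = "TRIGGER"
    MODULATION = "MODULATION"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Bounds:
    """Axis-aligned rectangle in canvas units (top-left origin, y down)."""

    x: float
    y: float
    w: float
    h: float

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    def contains(self, other: "Bounds", tol: float = GEOM_TOL) -> bool:
        """True when ``other`` lies entirely inside this rectangle."""
        return (
            other.x >= self.x - tol
            and other.y >= self.y - tol
            and other.x2 <= self.x2 + tol
            and other.y2 <= self.y2 + tol
        )

    def strictly_contains(self, other: "Bounds", tol: float = GEOM_TOL) -> bool:
        """Containment that excludes (near-)identical rectangles, so two
        coincident areas are treated as siblings, never as nested."""
        if not self.contains(other, tol):
            return False
        return self.area > other.area + tol

    def intersects(self, other: "Bounds") -> bool:
        """True when the open interiors overlap (shared edges don't count)."""
        return (
            self.x < other.x2
            and other.x < self.x2
            and self.y < other.y2
            and other.y < self.y2
        )

    def intersection(self, other: "Bounds") -> Optional["Bounds"]:
        x1, y1 = max(self.x, other.x), max(self.y, other.y)
        x2, y2 = min(self.x2, other.x2), min(self.y2, other.y2)
        if x2 <= x1 or y2 <= y1:
            return None
        return Bounds(x1, y1, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class Annotation:
    """A MIRIAM cross-reference: (registry namespace, identifier) plus the
    BioModels qualifier relating it to its carrier (``is`` by default,
    ``isDescribedBy`` for literature)."""

    namespace: str
    identifier: str
    relation: str = "is"


@dataclass(frozen=True)
class Modifier:
    element_id: str
    role: ModifierRole = ModifierRole.CATALYSIS


@dataclass
class Element:
    element_id: str
    element_type: ElementType
    bounds: Bounds
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    compartment_ref: Optional[str] = None
    parent_complex: Optional[str] = None
    annotations: list[Annotation] = field(default_factory=list)
    notes: str = ""

    def annotation_set(self) -> set[Annotation]:
        return set(self.annotations)

    def has_namespace(self, namespaces: Iterable[str]) -> bool:
        wanted = set(namespaces)
        return any(a.namespace in wanted for a in self.annotations)


@dataclass
class Interaction:
    interaction_id: str
    interaction_type: InteractionType
    reactants: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    modifiers: list[Modifier] = field(default_factory=list)
    polyline: list[tuple[float, float]] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    notes: str = ""

    def annotation_set(self) -> set[Annotation]:
        return set(self.annotations)

    def has_namespace(self, namespaces: Iterable[str]) -> bool:
        wanted = set(namespaces)
        return any(a.namespace in wanted for a in self.annotations)

    def modifier_ids(self) -> list[str]:
        return [m.element_id for m in self.modifiers]


#: A comment target: an element id, an interaction id, or a canvas point.
CommentTarget = Union[str, tuple[float, float]]


@dataclass
class Comment:
    comment_id: str
    text: str
    target: CommentTarget
    visible: bool = True


@dataclass(frozen=True)
class SubmapLink:
    """An element acting as a cross-map hyperlink to another map."""

    source_element_id: str
    target_map_id: str


class ViolationKind(str, Enum):
    DANGLING_REF = "DANGLING_REF"
    DUPLICATE_ID = "DUPLICATE_ID"
    BAD_BOUNDS = "BAD_BOUNDS"
    OUT_OF_CANVAS = "OUT_OF_CANVAS"
    NOT_A_CONTAINER = "NOT_A_CONTAINER"
    OUTSIDE_CONTAINER = "OUTSIDE_CONTAINER"
    CONTAINMENT_CYCLE = "CONTAINMENT_CYCLE"
    MISSING_PARTICIPANT = "MISSING_PARTICIPANT"
    BAD_POLYLINE = "BAD_POLYLINE"


@dataclass(frozen=True)
class Violation:
    kind: ViolationKind
    object_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind.value}] {self.object_id}: {self.message}"


@dataclass
class MapModel:
    """One diagram: elements, interactions, canvas, submap links, comments.

    ``elements`` and ``interactions`` are insertion-ordered dicts keyed by
    id; source-file order is preserved by readers.
    """

    map_id: str
    name: str = ""
    width: float = 800.0
    height: float = 600.0
    elements: dict[str, Element] = field(default_factory=dict)
    interactions: dict[str, Interaction] = field(default_factory=dict)
    submap_links: list[SubmapLink] = field(default_factory=list)
    comments: list[Comment] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    def add_element(self, element: Element) -> Element:
        self.elements[element.element_id] = element
        return element

    def add_interaction(self, interaction: Interaction) -> Interaction:
        self.interactions[interaction.interaction_id] = interaction
        return interaction

    # -- lookup ---------------------------------------------------------------

    def element(self, element_id: str) -> Element:
        try:
            return self.elements[element_id]
        except KeyError:
            raise TargetNotFound(element_id) from None

    def interaction(self, interaction_id: str) -> Interaction:
        try:
            return self.interactions[interaction_id]
        except KeyError:
            raise TargetNotFound(interaction_id) from None

    def areas(self) -> list[Element]:
        """Elements of an area type (compartment/complex/text area)."""
        return [e for e in self.elements.values() if e.element_type in AREA_TYPES]

    def parent_of(self, element: Element) -> Optional[Element]:
        """The enclosing container per explicit refs: complex first, then
        compartment."""
        pid = element.parent_complex or element.compartment_ref
        return self.elements.get(pid) if pid else None

    def children_of(self, element_id: str) -> list[Element]:
        return [
            e
            for e in self.elements.values()
            if element_id in (e.parent_complex, e.compartment_ref)
        ]

    def complex_members(self, complex_id: str, recursive: bool = True) -> list[Element]:
        """Members of a complex; with ``recursive`` follows nested complexes."""
        out: list[Element] = []
        stack = [complex_id]
        while stack:
            cid = stack.pop()
            for e in self.elements.values():
                if e.parent_complex == cid:
                    out.append(e)
                    if recursive and e.element_type is ElementType.COMPLEX:
                        stack.append(e.element_id)
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def validate_model(model: MapModel) -> list[Violation]:
    """Check every structural invariant; return one :class:`Violation` per
    breach.  Never raises: a malformed model is data, not an exception.
    """
    violations: list[Violation] = []
    V = violations.append
    canvas = Bounds(0.0, 0.0, model.width, model.height)

    if model.width <= 0 or model.height <= 0:
        V(Violation(ViolationKind.BAD_BOUNDS, model.map_id,
                    f"canvas {model.width}x{model.height} must be positive"))
        canvas = None

    for eid, el in model.elements.items():
        if el.element_id != eid:
            V(Violation(ViolationKind.DUPLICATE_ID, eid,
                        f"element keyed {eid!r} carries id {el.element_id!r}"))
        b = el.bounds
        if b.w <= 0 or b.h <= 0:
            V(Violation(ViolationKind.BAD_BOUNDS, eid,
                        f"bounds {b.w}x{b.h} must be positive"))
        elif canvas is not None and not canvas.contains(b):
            V(Violation(ViolationKind.OUT_OF_CANVAS, eid,
                        f"bounds ({b.x},{b.y},{b.w},{b.h}) exceed canvas"))

        for ref, expected in (
            (el.compartment_ref, ElementType.COMPARTMENT),
            (el.parent_complex, ElementType.COMPLEX),
        ):
            if ref is None:
                continue
            container = model.elements.get(ref)
            if container is None:
                V(Violation(ViolationKind.DANGLING_REF, eid,
                            f"references missing container {ref!r}"))
            else:
                if container.element_type is not expected:
                    V(Violation(ViolationKind.NOT_A_CONTAINER, eid,
                                f"container {ref!r} is {container.element_type.value}, "
                                f"expected {expected.value}"))
                if (container.bounds.w > 0 and container.bounds.h > 0
                        and not container.bounds.contains(b)):
                    V(Violation(ViolationKind.OUTSIDE_CONTAINER, eid,
                                f"bounds extend outside container {ref!r}"))

    # containment cycles over the explicit parent refs
    g = nx.DiGraph()
    for el in model.elements.values():
        for ref in (el.compartment_ref, el.parent_complex):
            if ref is not None and ref in model.elements:
                g.add_edge(el.element_id, ref)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        members = "->".join(a for a, _ in cycle)
        V(Violation(ViolationKind.CONTAINMENT_CYCLE, cycle[0][0],
                    f"containment cycle {members}"))

    for iid, inter in model.interactions.items():
        if not inter.reactants:
            V(Violation(ViolationKind.MISSING_PARTICIPANT, iid,
                        "interaction has no reactants"))
        if not inter.products:
            V(Violation(ViolationKind.MISSING_PARTICIPANT, iid,
                        "interaction has no products"))
        for ref in [*inter.reactants, *inter.products, *inter.modifier_ids()]:
            if ref not in model.elements:
                V(Violation(ViolationKind.DANGLING_REF, iid,
                            f"interaction references missing element {ref!r}"))
        if len(inter.polyline) < 2:
            V(Violation(ViolationKind.BAD_POLYLINE, iid,
                        f"polyline has {len(inter.polyline)} point(s), need >= 2"))

    for link in model.submap_links:
        if link.source_element_id not in model.elements:
            V(Violation(ViolationKind.DANGLING_REF, link.source_element_id,
                        "submap link source element missing"))

    for comment in model.comments:
        t = comment.target
        if isinstance(t, str) and t not in model.elements and t not in model.interactions:
            V(Violation(ViolationKind.DANGLING_REF, comment.comment_id,
                        f"comment targets missing object {t!r}"))

    return violations


def attach_comment(model: MapModel, target: CommentTarget, text: str) -> Comment:
    """Pin a comment to an element, an interaction, or a canvas point.

    Ids follow the generated-id scheme ``cN``.
    """
    if isinstance(target, str):
        if target not in model.elements and target not in model.interactions:
            raise TargetNotFound(target)
    else:
        target = (float(target[0]), float(target[1]))
    existing = {c.comment_id for c in model.comments}
    n = len(model.comments) + 1
    while f"c{n}" in existing:
        n += 1
    comment = Comment(comment_id=f"c{n}", text=text, target=target, visible=True)
    model.comments.append(comment)
    return comment


def containment_depth(model: MapModel, element_id: str) -> int:
    """Nesting depth along explicit container refs: 1 for top-level
    elements, parent depth + 1 otherwise."""
    element = model.element(element_id)
    depth = 1
    seen = {element_id}
    parent = model.parent_of(element)
    while parent is not None:
        if parent.element_id in seen:  # cycle guard: treat as terminated
            break
        seen.add(parent.element_id)
        depth += 1
        parent = model.parent_of(parent)
    return depth


# ---------------------------------------------------------------------------
# Model equivalence (round-trip testing support)
# ---------------------------------------------------------------------------


def _points_close(p, q, tol):
    return len(p) == len(q) and all(
        math.isclose(a[0], b[0], abs_tol=tol) and math.isclose(a[1], b[1], abs_tol=tol)
        for a, b in zip(p, q)
    )


def model_diff(
    a: MapModel,
    b: MapModel,
    tol: float = GEOM_TOL,
    ignore: Iterable[str] = (),
) -> list[str]:
    """Field-by-field differences between two models.

    ``ignore`` names model fields excluded from comparison (the documented
    LOSSY set for cross-format trips): any of ``name``, ``synonyms``,
    ``notes``, ``polyline``, ``element_type``, ``interaction_type``,
    ``modifier_role``, ``canvas``.
    """
    ignore = set(ignore)
    diffs: list[str] = []

    if "canvas" not in ignore:
        if not (math.isclose(a.width, b.width, abs_tol=tol)
                and math.isclose(a.height, b.height, abs_tol=tol)):
            diffs.append(f"canvas {a.width}x{a.height} != {b.width}x{b.height}")
    if "name" not in ignore and a.name != b.name:
        diffs.append(f"map name {a.name!r} != {b.name!r}")

    if set(a.elements) != set(b.elements):
        diffs.append(f"element ids differ: {sorted(set(a.elements) ^ set(b.elements))}")
    else:
        for eid, ea in a.elements.items():
            eb = b.elements[eid]
            if "element_type" not in ignore and ea.element_type != eb.element_type:
                diffs.append(f"{eid}: type {ea.element_type} != {eb.element_type}")
            if "name" not in ignore and ea.name != eb.name:
                diffs.append(f"{eid}: name {ea.name!r} != {eb.name!r}")
            if "synonyms" not in ignore and ea.synonyms != eb.synonyms:
                diffs.append(f"{eid}: synonyms differ")
            if "notes" not in ignore and ea.notes.strip() != eb.notes.strip():
                diffs.append(f"{eid}: notes differ")
            if ea.compartment_ref != eb.compartment_ref:
                diffs.append(f"{eid}: compartment_ref {ea.compartment_ref} != {eb.compartment_ref}")
            if ea.parent_complex != eb.parent_complex:
                diffs.append(f"{eid}: parent_complex {ea.parent_complex} != {eb.parent_complex}")
            ba, bb = ea.bounds, eb.bounds
            if not all(
                math.isclose(u, v, abs_tol=tol)
                for u, v in ((ba.x, bb.x), (ba.y, bb.y), (ba.w, bb.w), (ba.h, bb.h))
            ):
                diffs.append(f"{eid}: bounds {ba} != {bb}")
            if ea.annotation_set() != eb.annotation_set():
                diffs.append(f"{eid}: annotations differ")

    if set(a.interactions) != set(b.interactions):
        diffs.append(
            f"interaction ids differ: {sorted(set(a.interactions) ^ set(b.interactions))}"
        )
    else:
        for iid, ia in a.interactions.items():
            ib = b.interactions[iid]
            if "interaction_type" not in ignore and ia.interaction_type != ib.interaction_type:
                diffs.append(f"{iid}: type {ia.interaction_type} != {ib.interaction_type}")
            if ia.reactants != ib.reactants:
                diffs.append(f"{iid}: reactants {ia.reactants} != {ib.reactants}")
            if ia.products != ib.products:
                diffs.append(f"{iid}: products {ia.products} != {ib.products}")
            if "modifier_role" in ignore:
                if set(ia.modifier_ids()) != set(ib.modifier_ids()):
                    diffs.append(f"{iid}: modifier ids differ")
            elif set(ia.modifiers) != set(ib.modifiers):
                diffs.append(f"{iid}: modifiers differ")
            if "polyline" not in ignore and not _points_close(ia.polyline, ib.polyline, tol):
                diffs.append(f"{iid}: polyline differs")
            if "notes" not in ignore and ia.notes.strip() != ib.notes.strip():
                diffs.append(f"{iid}: notes differ")
            if ia.annotation_set() != ib.annotation_set():
                diffs.append(f"{iid}: annotations differ")

    if [(l.source_element_id, l.target_map_id) for l in a.submap_links] != [
        (l.source_element_id, l.target_map_id) for l in b.submap_links
    ]:
        diffs.append("submap links differ")

    return diffs


def models_equivalent(
    a: MapModel, b: MapModel, tol: float = GEOM_TOL, ignore: Iterable[str] = ()
) -> bool:
    """True when :func:`model_diff` reports nothing."""
    return not model_diff(a, b, tol=tol, ignore=ignore)


def copy_model(model: MapModel) -> MapModel:
    """Deep-ish copy (shared immutable leaves)."""
    return MapModel(
        map_id=model.map_id,
        name=model.name,
        width=model.width,
        height=model.height,
        elements={
            eid: replace(e, synonyms=list(e.synonyms), annotations=list(e.annotations))
            for eid, e in model.elements.items()
        },
        interactions={
            iid: replace(
                i,
                reactants=list(i.reactants),
                products=list(i.products),
                modifiers=list(i.modifiers),
                polyline=list(i.polyline),
                annotations=list(i.annotations),
            )
            for iid, i in model.interactions.items()
        },
        submap_links=list(model.submap_links),
        comments=[replace(c) for c in model.comments],
    )
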