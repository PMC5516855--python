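"""Semantic-zoom level assignment and the quadtree tile coordinate system.

Semantic zoom emulates the behaviour of tiled pathway viewers: at low zoom,
large areas (compartments, complexes, text areas) are drawn as opaque covers
hiding their content; zooming in reveals progressively deeper nesting, so
"larger areas cover smaller ones" and the zoomed-out view shows only the
most generic areas.

"Size and coverage" is operationalized as:

* candidacy — area ≥ ``min_cover_fraction`` × map area (default 0.002);
* level — containment depth among candidate areas, tested geometrically by
  bounds inclusion with a 1e-6 tolerance (overlapping-but-not-nested areas
  are siblings);
* paint order — deeper covers first, larger on top within a level.

An area's cover is displayed at zoom levels strictly below its reveal level
and hidden from its reveal level on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .errors import TileOutOfRange
from .model import AREA_TYPES, Bounds, Element, MapModel

DEFAULT_MIN_COVER_FRACTION = 0.002
DEFAULT_TILE_PX = 256


@dataclass
class ZoomAssignment:
    """Reveal levels for cover areas: cover of area A is drawn at zoom
    z < reveal_level[A] and hidden at z >= reveal_level[A]."""

    n_levels: int = 1
    reveal_level: dict[str, int] = field(default_factory=dict)

    def visible_covers(self, zoom_level: int) -> list[str]:
        """Ids of areas whose cover is drawn at this zoom level."""
        return [eid for eid, lvl in self.reveal_level.items() if lvl > zoom_level]

    def to_json(self) -> str:
        return json.dumps(
            {"n_levels": self.n_levels, "reveal_level": self.reveal_level},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ZoomAssignment":
        data = json.loads(text)
        return cls(
            n_levels=int(data["n_levels"]),
            reveal_level={k: int(v) for k, v in data["reveal_level"].items()},
        )


def candidate_areas(
    model: MapModel, min_cover_fraction: float = DEFAULT_MIN_COVER_FRACTION
) -> list[Element]:
    """Compartment/complex/text-area elements large enough to cover."""
    threshold = min_cover_fraction * model.width * model.height
    return [
        e
        for e in model.elements.values()
        if e.element_type in AREA_TYPES and e.bounds.area >= threshold
    ]


def compute_semantic_zoom(
    model: MapModel, min_cover_fraction: float = DEFAULT_MIN_COVER_FRACTION
) -> ZoomAssignment:
    """Assign each candidate area the zoom level at which it uncovers.

    ``reveal_level`` is the area's geometric containment depth among the
    candidates (1 = top-level), so nested areas always satisfy
    reveal_level(outer) < reveal_level(inner) and zoom 0 shows only the
    most generic covers.  ``n_levels`` = max reveal level + 1.
    """
    candidates = candidate_areas(model, min_cover_fraction)
    # parent = smallest candidate strictly containing the area
    parents: dict[str, str | None] = {}
    for a in candidates:
        best: Element | None = None
        for b in candidates:
            if b.element_id == a.element_id:
                continue
            if b.bounds.strictly_contains(a.bounds):
                if best is None or b.bounds.area < best.bounds.area:
                    best = b
        parents[a.element_id] = best.element_id if best else None

    levels: dict[str, int] = {}

    def depth(eid: str) -> int:
        if eid in levels:
            return levels[eid]
        parent = parents[eid]
        levels[eid] = 1 if parent is None else depth(parent) + 1
        return levels[eid]

    for a in candidates:
        depth(a.element_id)

    n_levels = max(levels.values(), default=0) + 1
    return ZoomAssignment(n_levels=n_levels, reveal_level=levels)


def cover_paint_order(assignment: ZoomAssignment, model: MapModel) -> list[str]:
    """All assigned areas ordered for painting: deepest first, so shallower
    covers land on top; within a level larger areas paint later (on top),
    ids break remaining ties."""
    return sorted(
        assignment.reveal_level,
        key=lambda eid: (
            -assignment.reveal_level[eid],
            model.elements[eid].bounds.area,
            eid,
        ),
    )


# ---------------------------------------------------------------------------
# Tile pyramid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TileCoord:
    z: int
    tx: int
    ty: int

    def __post_init__(self):
        if self.z < 0 or not (0 <= self.tx < 2**self.z) or not (0 <= self.ty < 2**self.z):
            raise TileOutOfRange(f"tile ({self.z},{self.tx},{self.ty}) out of range")


def embedding_side(model: MapModel) -> float:
    """Side of the square the map is embedded into (top-left anchored)."""
    return max(model.width, model.height)


def tile_transform(model: MapModel, z: int, tx: int, ty: int) -> Bounds:
    """Canvas rectangle covered by tile (z, tx, ty) of the embedding square."""
    TileCoord(z, tx, ty)  # validates
    s = embedding_side(model) / 2**z
    return Bounds(tx * s, ty * s, s, s)


def max_native_zoom(model: MapModel, tile_px: int = DEFAULT_TILE_PX) -> int:
    """Deepest level at which one canvas unit still maps to >= one pixel:
    ceil(log2(S / tile_px)), clamped to >= 0."""
    s = embedding_side(model)
    if s <= tile_px:
        return 0
    return max(0, math.ceil(math.log2(s / tile_px)))
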