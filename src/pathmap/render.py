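"""Rasterization of maps, tiles and regions with Pillow.

Glyph shapes follow SBGN PD conventions (rounded-rectangle macromolecule,
ellipse simple chemical, cut-corner complex, …) with fixed geometry
constants in :class:`RenderStyle`; compartment covers take colors from the
compartment palette while complex/text-area covers use a neutral gray.

Determinism contract: rendering is pure integer/float raster drawing with a
built-in bitmap font — identical inputs produce byte-identical images, and
tile renders equal the matching crop of a full-region render pixel for
pixel (drawing coordinates differ between the two only by an exact integer
pixel translation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from PIL import Image, ImageChops, ImageDraw, ImageFont

from .errors import EmptyRegion
from .model import Bounds, Element, ElementType, MapModel
from .overlay import OverlayBinding
from .zoom import (
    DEFAULT_TILE_PX,
    TileCoord,
    ZoomAssignment,
    cover_paint_order,
    embedding_side,
    tile_transform,
)

_FONT = ImageFont.load_default()

NEUTRAL_COVER = "#C8C8C8"  # gray for pathway/text-area and complex covers

COMPARTMENT_PALETTE = [
    "#BFD8BF", "#BFCFE8", "#E8D8BF", "#D8BFD8", "#BFE8E0", "#E8BFC8",
]


def _default_fills() -> dict[ElementType, str]:
    return {
        ElementType.PROTEIN: "#CCFFCC",
        ElementType.GENE: "#FFFFCC",
        ElementType.RNA: "#FFE8CC",
        ElementType.ANTISENSE_RNA: "#FFD8CC",
        ElementType.SIMPLE_MOLECULE: "#CCE8FF",
        ElementType.ION: "#CCF0FF",
        ElementType.DRUG: "#FFCCE8",
        ElementType.PHENOTYPE: "#E8CCFF",
        ElementType.UNKNOWN: "#EEEEEE",
        ElementType.DEGRADED: "#E0E0E0",
        ElementType.COMPLEX: "#E8E8FF",
        ElementType.COMPARTMENT: "#F4F4E8",
        ElementType.TEXT_AREA: "#FFFFFF",
    }


@dataclass
class RenderStyle:
    fills: dict[ElementType, str] = field(default_factory=_default_fills)
    border_color: str = "#404040"
    text_color: str = "#000000"
    background: str = "#FFFFFF"
    interaction_color: str = "#303030"
    compartment_palette: list[str] = field(
        default_factory=lambda: list(COMPARTMENT_PALETTE)
    )
    cover_color: str = NEUTRAL_COVER
    line_width: int = 1
    corner_radius: float = 6.0
    arrow_size: float = 6.0

    def fill(self, element_type: ElementType) -> str:
        return self.fills[element_type]


def compartment_color(model: MapModel, style: RenderStyle, element_id: str) -> str:
    """Stable palette color per compartment (index in sorted-id order)."""
    comp_ids = sorted(
        eid
        for eid, el in model.elements.items()
        if el.element_type is ElementType.COMPARTMENT
    )
    idx = comp_ids.index(element_id)
    return style.compartment_palette[idx % len(style.compartment_palette)]


# ---------------------------------------------------------------------------
# Region rendering
# ---------------------------------------------------------------------------


def render_region(
    model: MapModel,
    bounds: Bounds,
    scale: float,
    zoom_level: Optional[int] = None,
    assignment: Optional[ZoomAssignment] = None,
    overlays: Optional[Sequence[OverlayBinding]] = None,
    style: Optional[RenderStyle] = None,
) -> Image.Image:
    """Rasterize the canvas rectangle ``bounds`` at ``scale`` px per canvas
    unit, honoring semantic zoom (covers of areas with reveal level above
    ``zoom_level`` are drawn opaque) and overlay colorings (applied last).
    """
    if bounds.w <= 0 or bounds.h <= 0:
        raise EmptyRegion(f"render bounds {bounds} have no extent")
    if scale <= 0:
        raise ValueError("scale must be positive")
    style = style or RenderStyle()

    width_px = math.ceil(bounds.w * scale)
    height_px = math.ceil(bounds.h * scale)
    img = Image.new("RGB", (width_px, height_px), style.background)
    draw = ImageDraw.Draw(img)

    ox, oy = bounds.x * scale, bounds.y * scale

    # Geometry is snapped to the device pixel grid before drawing: rounding
    # commutes with integer pixel translations, so a tile render equals the
    # matching crop of a larger render byte for byte.
    def tx(x: float) -> int:
        return round(x * scale - ox)

    def ty(y: float) -> int:
        return round(y * scale - oy)

    def rect(b: Bounds) -> tuple[int, int, int, int]:
        return (tx(b.x), ty(b.y), tx(b.x2), ty(b.y2))

    # paint order: compartments (outermost first), interactions, entities
    # (parents before children), then covers, then overlays
    elements = list(model.elements.values())
    compartments = [e for e in elements if e.element_type is ElementType.COMPARTMENT]
    compartments.sort(key=lambda e: (-e.bounds.area, e.element_id))
    entities = [e for e in elements if e.element_type is not ElementType.COMPARTMENT]
    entities.sort(key=lambda e: (-e.bounds.area, e.element_id))

    for comp in compartments:
        color = compartment_color(model, style, comp.element_id)
        draw.rounded_rectangle(
            rect(comp.bounds), radius=round(style.corner_radius * scale),
            fill=style.fill(ElementType.COMPARTMENT), outline=color,
            width=max(1, round(3 * scale)),
        )
        _draw_label(draw, comp, rect(comp.bounds), style, anchor_top=True)

    for inter in model.interactions.values():
        pts = [(tx(x), ty(y)) for x, y in inter.polyline]
        if len(pts) >= 2:
            draw.line(pts, fill=style.interaction_color,
                      width=max(1, round(style.line_width * scale)))
            _draw_arrowhead(draw, pts, style, scale,
                            inter.interaction_type.value)

    for el in entities:
        _draw_entity(draw, el, rect(el.bounds), style, scale)

    if assignment is not None and zoom_level is not None:
        for eid in cover_paint_order(assignment, model):
            if assignment.reveal_level[eid] <= zoom_level:
                continue
            area = model.elements[eid]
            if area.element_type is ElementType.COMPARTMENT:
                color = compartment_color(model, style, eid)
            else:
                color = style.cover_color
            draw.rectangle(rect(area.bounds), fill=color,
                           outline=style.border_color, width=1)
            _draw_label(draw, area, rect(area.bounds), style)

    if overlays:
        element_styles: dict[str, str] = {}
        interaction_styles: dict[str, tuple[Optional[str], Optional[float]]] = {}
        for binding in overlays:
            element_styles.update(binding.element_styles())
            interaction_styles.update(binding.interaction_styles())
        for iid, (color, line_width) in interaction_styles.items():
            inter = model.interactions.get(iid)
            if inter is None:
                continue
            pts = [(tx(x), ty(y)) for x, y in inter.polyline]
            if len(pts) >= 2:
                draw.line(
                    pts,
                    fill=color or style.interaction_color,
                    width=max(1, round((line_width or style.line_width) * scale)),
                )
        for eid, color in element_styles.items():
            el = model.elements.get(eid)
            if el is None:
                continue
            draw.rectangle(rect(el.bounds), fill=color,
                           outline=style.border_color, width=1)
            _draw_label(draw, el, rect(el.bounds), style)

    return img


def _draw_entity(draw, el: Element, box, style: RenderStyle, scale: float) -> None:
    fill = style.fill(el.element_type)
    outline = style.border_color
    t = el.element_type
    if t in (ElementType.PROTEIN, ElementType.DRUG):
        draw.rounded_rectangle(box, radius=round(style.corner_radius * scale),
                               fill=fill, outline=outline, width=1)
    elif t in (ElementType.SIMPLE_MOLECULE, ElementType.ION,
               ElementType.DEGRADED, ElementType.UNKNOWN):
        draw.ellipse(box, fill=fill, outline=outline, width=1)
        if t is ElementType.DEGRADED:
            draw.line([(box[0], box[3]), (box[2], box[1])], fill=outline, width=1)
    elif t is ElementType.COMPLEX:
        draw.rectangle(box, fill=fill, outline=outline, width=1)
    elif t is ElementType.PHENOTYPE:
        x1, y1, x2, y2 = box
        dx = round(min((x2 - x1) * 0.2, (y2 - y1) / 2))
        my = round((y1 + y2) / 2)
        draw.polygon(
            [(x1 + dx, y1), (x2 - dx, y1), (x2, my),
             (x2 - dx, y2), (x1 + dx, y2), (x1, my)],
            fill=fill, outline=outline,
        )
    elif t is ElementType.TEXT_AREA:
        draw.rectangle(box, outline="#A0A0A0", width=1)
    else:  # GENE / RNA / ANTISENSE_RNA
        draw.rectangle(box, fill=fill, outline=outline, width=1)
    _draw_label(draw, el, box, style)


def _draw_label(draw, el: Element, box, style: RenderStyle,
                anchor_top: bool = False) -> None:
    text = el.name
    if not text:
        return
    max_w = box[2] - box[0] - 4
    if max_w <= 0:
        return
    if draw.textlength(text, font=_FONT) > max_w:
        while text and draw.textlength(text + "...", font=_FONT) > max_w:
            text = text[:-1]
        if not text:
            return
        text = text + "..."
    w = draw.textlength(text, font=_FONT)
    x = round((box[0] + box[2] - w) / 2)
    y = box[1] + 2 if anchor_top else round((box[1] + box[3]) / 2 - 5)
    draw.text((x, y), text, fill=style.text_color, font=_FONT)


def _draw_arrowhead(draw, pts, style: RenderStyle, scale: float, kind: str) -> None:
    (x1, y1), (x2, y2) = pts[-2], pts[-1]
    dx, dy = x2 - x1, y2 - y1
    norm = math.hypot(dx, dy)
    if norm == 0:
        return
    ux, uy = dx / norm, dy / norm
    size = max(3.0, style.arrow_size * scale)
    if kind == "INHIBITION":
        # perpendicular bar
        px, py = -uy, ux
        draw.line(
            [(round(x2 - px * size), round(y2 - py * size)),
             (round(x2 + px * size), round(y2 + py * size))],
            fill=style.interaction_color, width=1,
        )
        return
    bx, by = x2 - ux * size, y2 - uy * size
    px, py = -uy * size / 2, ux * size / 2
    draw.polygon(
        [(x2, y2), (round(bx + px), round(by + py)), (round(bx - px), round(by - py))],
        fill=style.interaction_color,
    )


# ---------------------------------------------------------------------------
# Tile rendering
# ---------------------------------------------------------------------------


def render_tile(
    model: MapModel,
    tile: TileCoord,
    assignment: Optional[ZoomAssignment] = None,
    overlays: Optional[Sequence[OverlayBinding]] = None,
    tile_px: int = DEFAULT_TILE_PX,
    style: Optional[RenderStyle] = None,
) -> Image.Image:
    """One quadtree tile: ``render_region`` over the tile's canvas rectangle
    at scale ``tile_px * 2^z / S``, semantic zoom evaluated at level z."""
    bounds = tile_transform(model, tile.z, tile.tx, tile.ty)
    scale = tile_px * 2**tile.z / embedding_side(model)
    return render_region(
        model, bounds, scale,
        zoom_level=tile.z, assignment=assignment,
        overlays=overlays, style=style,
    )


def render_full_square(
    model: MapModel,
    z: int,
    assignment: Optional[ZoomAssignment] = None,
    overlays: Optional[Sequence[OverlayBinding]] = None,
    tile_px: int = DEFAULT_TILE_PX,
    style: Optional[RenderStyle] = None,
) -> Image.Image:
    """The whole embedding square at zoom z (size ``tile_px * 2^z`` px)."""
    s = embedding_side(model)
    scale = tile_px * 2**z / s
    return render_region(
        model, Bounds(0.0, 0.0, s, s), scale,
        zoom_level=z, assignment=assignment, overlays=overlays, style=style,
    )


def stitch_tiles(tiles: dict[tuple[int, int], Image.Image], z: int,
                 tile_px: int = DEFAULT_TILE_PX) -> Image.Image:
    """Assemble the 4^z tiles of a level into one image."""
    side = tile_px * 2**z
    out = Image.new("RGB", (side, side))
    for (txi, tyi), img in tiles.items():
        out.paste(img, (txi * tile_px, tyi * tile_px))
    return out


def max_pixel_difference(a: Image.Image, b: Image.Image) -> int:
    """Largest per-channel absolute difference between two images."""
    if a.size != b.size:
        raise ValueError(f"image sizes differ: {a.size} vs {b.size}")
    diff = ImageChops.difference(a.convert("RGB"), b.convert("RGB"))
    return max(hi for _lo, hi in diff.getextrema())
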