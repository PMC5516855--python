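"""Programmatic fixture maps: small, valid, deterministic diagrams standing
in for curated disease-map content, so nothing ever needs downloading.

Layout is slot-based so sibling bounds never overlap and nesting is always
proper, which lets the zoom, render and region-export oracles exercise real
geometry.  For a fixed seed the generated model — and hence its
serialization — is byte-identical between runs.

Generated ids follow the counter scheme: ``cN`` compartments, ``sN``
species (complexes and proteins), ``rN`` reactions, ``tN`` text areas.

Nesting: compartment 1 hosts a chain of nested compartments; when complexes
are requested they occupy the innermost chain area, so for
``nesting_depth >= 2`` the deepest candidate cover area sits at exactly
``nesting_depth``.  With ``nesting_depth == 1`` compartments are level 1
and any complexes level 2.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import (
    Annotation,
    Bounds,
    Element,
    ElementType,
    Interaction,
    InteractionType,
    MapModel,
    Modifier,
    ModifierRole,
)

#: (symbol, uniprot accession, entrez gene id, synonyms) — a small table of
#: neurodegeneration-relevant genes used to give fixtures plausible names
#: and MIRIAM annotations.
SYMBOLS: list[tuple[str, str, str, tuple[str, ...]]] = [
    ("TP53", "P04637", "7157", ("p53",)),
    ("MDM2", "Q00987", "4193", ()),
    ("SNCA", "P37840", "6622", ("alpha-synuclein",)),
    ("LRRK2", "Q5S007", "120892", ("dardarin",)),
    ("PINK1", "Q9BXM7", "65018", ()),
    ("PARK7", "Q99497", "11315", ("DJ-1",)),
    ("PRKN", "O60260", "5071", ("parkin", "PARK2")),
    ("TH", "P07101", "7054", ("tyrosine hydroxylase",)),
    ("DRD1", "P21728", "1812", ()),
    ("DRD2", "P14416", "1813", ()),
    ("DDC", "P20711", "1644", ("AADC",)),
    ("UCHL1", "P09936", "7345", ()),
    ("MAPT", "P10636", "4137", ("tau",)),
    ("GBA1", "P04062", "2629", ("GBA",)),
    ("VPS35", "Q96QK1", "55737", ()),
    ("ATP13A2", "Q9NQ11", "23400", ()),
]

COMPARTMENT_NAMES = [
    "cytosol", "nucleus", "mitochondrion", "endoplasmic reticulum",
    "extracellular space", "lysosome", "golgi apparatus", "synaptic vesicle",
]

TEXT_AREA_NAMES = [
    "dopamine metabolism", "oxidative stress response",
    "protein degradation", "synaptic signalling",
]

_SLOT_W, _SLOT_H = 118.0, 66.0


@dataclass
class _SlotGrid:
    """Row-major slot allocator inside a container rectangle."""

    container_id: str | None
    origin_x: float
    origin_y: float
    cols: int
    rows: int
    used: int = 0

    @classmethod
    def for_bounds(cls, container_id: str | None, b: Bounds) -> "_SlotGrid":
        inner_x, inner_y = b.x + 14.0, b.y + 30.0
        cols = max(1, int((b.w - 28.0) // _SLOT_W))
        rows = max(1, int((b.h - 44.0) // _SLOT_H))
        return cls(container_id, inner_x, inner_y, cols, rows)

    @property
    def free(self) -> int:
        return self.cols * self.rows - self.used

    def take(self) -> Bounds:
        if self.free <= 0:
            raise ValueError("fixture container out of placement slots")
        i = self.used
        self.used += 1
        col, row = i % self.cols, i // self.cols
        return Bounds(
            self.origin_x + col * _SLOT_W,
            self.origin_y + row * _SLOT_H,
            _SLOT_W, _SLOT_H,
        )


def _centered(slot: Bounds, w: float, h: float) -> Bounds:
    return Bounds(slot.x + (slot.w - w) / 2, slot.y + (slot.h - h) / 2, w, h)


def generate_fixture_map(
    n_compartments: int = 2,
    n_complexes: int = 1,
    n_proteins: int = 6,
    n_reactions: int = 3,
    nesting_depth: int = 1,
    seed: int = 0,
    n_text_areas: int = 0,
    width: float = 800.0,
    height: float = 600.0,
    map_id: str | None = None,
    name: str = "fixture map",
) -> MapModel:
    """Build a deterministic, valid fixture map.

    All counts must be >= 0; raises ``ValueError`` when the requested
    content does not fit the canvas.
    """
    if min(n_compartments, n_complexes, n_proteins, n_reactions,
           n_text_areas) < 0 or nesting_depth < 1:
        raise ValueError("fixture counts must be >= 0 and nesting_depth >= 1")
    rng = random.Random(seed)
    model = MapModel(
        map_id=map_id or f"fixture_{seed}",
        name=name,
        width=width,
        height=height,
    )

    strip_h = 90.0 if n_text_areas else 0.0
    region = Bounds(10.0, 10.0, width - 20.0, height - 20.0 - strip_h)

    # --- compartments --------------------------------------------------------
    comp_ids: list[str] = []
    if n_compartments:
        cols = max(1, round(n_compartments ** 0.5))
        rows = -(-n_compartments // cols)
        cell_w, cell_h = region.w / cols, region.h / rows
        comp_names = list(COMPARTMENT_NAMES)
        rng.shuffle(comp_names)
        for i in range(n_compartments):
            col, row = i % cols, i // cols
            b = Bounds(
                region.x + col * cell_w + 8.0,
                region.y + row * cell_h + 8.0,
                cell_w - 16.0,
                cell_h - 16.0,
            )
            cid = f"c{i + 1}"
            comp_ids.append(cid)
            model.add_element(Element(
                element_id=cid,
                element_type=ElementType.COMPARTMENT,
                name=comp_names[i % len(comp_names)],
                bounds=b,
            ))

    # --- nesting chain inside compartment 1 ----------------------------------
    chain_extra = max(0, nesting_depth - 1 - (1 if n_complexes else 0))
    innermost = comp_ids[0] if comp_ids else None
    for j in range(chain_extra if comp_ids else 0):
        parent = model.elements[innermost]
        pb = parent.bounds
        b = Bounds(pb.x + 30.0, pb.y + 34.0, pb.w - 60.0, pb.h - 52.0)
        if b.w < 2 * _SLOT_W or b.h < 2 * _SLOT_H:
            raise ValueError("nesting_depth too large for the canvas")
        cid = f"c{len(comp_ids) + 1}"
        comp_ids.append(cid)
        model.add_element(Element(
            element_id=cid,
            element_type=ElementType.COMPARTMENT,
            name=f"{parent.name} subdomain {j + 1}",
            bounds=b,
            compartment_ref=innermost,
        ))
        innermost = cid

    # containers available for entity placement: innermost chain area first,
    # then the other top-level compartments (never ancestors of the chain)
    chain_ancestors = set()
    cursor = innermost
    while cursor is not None:
        parent = model.elements[cursor].compartment_ref
        if parent is not None:
            chain_ancestors.add(parent)
        cursor = parent
    container_ids: list[str | None] = (
        [innermost] + [c for c in comp_ids if c != innermost and c not in chain_ancestors]
        if comp_ids
        else [None]
    )
    grids = {
        cid: _SlotGrid.for_bounds(
            cid, model.elements[cid].bounds if cid else region
        )
        for cid in container_ids
    }

    def next_grid(preferred: str | None = None) -> _SlotGrid:
        order = [preferred] if preferred in grids else []
        order += [c for c in container_ids if c != preferred]
        for cid in order:
            if grids[cid].free > 0:
                return grids[cid]
        raise ValueError("fixture spec does not fit the canvas; enlarge it")

    species_counter = 0

    def next_sid() -> str:
        nonlocal species_counter
        species_counter += 1
        return f"s{species_counter}"

    # --- complexes -----------------------------------------------------------
    complex_slots: list[tuple[str, Bounds]] = []  # (complex id, inner bounds)
    for k in range(n_complexes):
        grid = next_grid(innermost if nesting_depth > 1 else None)
        slot = grid.take()
        b = _centered(slot, _SLOT_W - 8.0, _SLOT_H - 8.0)
        sid = next_sid()
        model.add_element(Element(
            element_id=sid,
            element_type=ElementType.COMPLEX,
            name=f"complex {k + 1}",
            bounds=b,
            compartment_ref=grid.container_id,
        ))
        complex_slots.append((sid, b))

    # --- proteins ------------------------------------------------------------
    symbols = list(SYMBOLS)
    rng.shuffle(symbols)
    protein_ids: list[str] = []
    member_budget: list[tuple[str, Bounds, int]] = [
        (cid, b, 2) for cid, b in complex_slots
    ]
    for k in range(n_proteins):
        symbol, uniprot, entrez, synonyms = symbols[k % len(symbols)]
        suffix = "" if k < len(symbols) else f"_{k // len(symbols) + 1}"
        sid = next_sid()
        parent_complex = None
        compartment_ref = None
        if member_budget and member_budget[0][2] > 0:
            cid, cb, left = member_budget[0]
            parent_complex = cid
            compartment_ref = model.elements[cid].compartment_ref
            slot_w, pad = (cb.w - 12.0) / 2.0, 4.0
            b = Bounds(
                cb.x + pad + (2 - left) * (slot_w + pad),
                cb.y + (cb.h - 22.0) / 2.0,
                slot_w, 22.0,
            )
            member_budget[0] = (cid, cb, left - 1)
            if member_budget[0][2] == 0:
                member_budget.pop(0)
        else:
            grid = next_grid(None)
            compartment_ref = grid.container_id
            b = _centered(grid.take(), 90.0, 40.0)
        annotations = [
            Annotation("hgnc.symbol", symbol),
            Annotation("uniprot", uniprot),
            Annotation("entrez", entrez),
        ]
        model.add_element(Element(
            element_id=sid,
            element_type=ElementType.PROTEIN,
            name=symbol + suffix,
            bounds=b,
            compartment_ref=compartment_ref,
            parent_complex=parent_complex,
            synonyms=list(synonyms),
            annotations=annotations if not suffix else [],
        ))
        protein_ids.append(sid)

    # --- text areas ----------------------------------------------------------
    if n_text_areas:
        ta_w = (width - 20.0) / n_text_areas
        for k in range(n_text_areas):
            model.add_element(Element(
                element_id=f"t{k + 1}",
                element_type=ElementType.TEXT_AREA,
                name=TEXT_AREA_NAMES[k % len(TEXT_AREA_NAMES)],
                bounds=Bounds(
                    10.0 + k * ta_w, height - strip_h,
                    ta_w - 8.0, strip_h - 10.0,
                ),
            ))

    # --- reactions -----------------------------------------------------------
    if n_reactions and len(protein_ids) < 2:
        raise ValueError("reactions need at least two proteins")
    rtypes = [
        InteractionType.STATE_TRANSITION,
        InteractionType.STATE_TRANSITION,
        InteractionType.HETERODIMER_ASSOCIATION,
        InteractionType.TRANSPORT,
    ]
    for k in range(n_reactions):
        reactant, product = rng.sample(protein_ids, 2)
        modifiers = []
        if k % 2 == 1 and len(protein_ids) >= 3:
            pool = [p for p in protein_ids if p not in (reactant, product)]
            modifiers = [Modifier(rng.choice(pool), ModifierRole.CATALYSIS)]
        annotations = []
        if k % 2 == 0:
            pmid = str(rng.randrange(10_000_000, 35_000_000))
            annotations = [Annotation("pubmed", pmid, relation="isDescribedBy")]
        model.add_interaction(Interaction(
            interaction_id=f"r{k + 1}",
            interaction_type=rtypes[k % len(rtypes)],
            reactants=[reactant],
            products=[product],
            modifiers=modifiers,
            polyline=[
                model.elements[reactant].bounds.center,
                model.elements[product].bounds.center,
            ],
            annotations=annotations,
        ))

    return model
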