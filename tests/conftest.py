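"""Shared fixtures: small hand-built maps and random nested-area models."""

from __future__ import annotations

import random

import pytest

from pathmap.model import (
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


def make_element(eid, etype, x, y, w, h, name="", **kwargs):
    return Element(
        element_id=eid,
        element_type=etype,
        name=name or eid,
        bounds=Bounds(x, y, w, h),
        **kwargs,
    )


@pytest.fixture
def small_map() -> MapModel:
    """One compartment holding a complex of two proteins plus a free
    protein and a simple molecule, with one catalyzed reaction."""
    m = MapModel(map_id="m1", name="small", width=400.0, height=300.0)
    m.add_element(make_element("c1", ElementType.COMPARTMENT, 10, 10, 380, 280,
                               name="cytosol"))
    m.add_element(make_element("s1", ElementType.COMPLEX, 30, 40, 120, 70,
                               name="complex 1", compartment_ref="c1"))
    m.add_element(make_element(
        "s2", ElementType.PROTEIN, 36, 60, 50, 24, name="TP53",
        compartment_ref="c1", parent_complex="s1",
        synonyms=["p53"],
        annotations=[Annotation("uniprot", "P04637"),
                     Annotation("entrez", "7157")],
    ))
    m.add_element(make_element(
        "s3", ElementType.PROTEIN, 92, 60, 50, 24, name="MDM2",
        compartment_ref="c1", parent_complex="s1",
        annotations=[Annotation("uniprot", "Q00987")],
    ))
    m.add_element(make_element(
        "s4", ElementType.PROTEIN, 200, 50, 80, 36, name="SNCA",
        compartment_ref="c1",
        annotations=[Annotation("uniprot", "P37840")],
    ))
    m.add_element(make_element(
        "s5", ElementType.SIMPLE_MOLECULE, 200, 150, 70, 34, name="dopamine",
        compartment_ref="c1",
        annotations=[Annotation("chebi", "CHEBI:18243")],
    ))
    m.add_interaction(Interaction(
        interaction_id="r1",
        interaction_type=InteractionType.STATE_TRANSITION,
        reactants=["s4"],
        products=["s5"],
        modifiers=[Modifier("s2", ModifierRole.CATALYSIS)],
        polyline=[(240.0, 68.0), (235.0, 167.0)],
        annotations=[Annotation("pubmed", "12345678", "isDescribedBy")],
    ))
    return m


def random_nested_area_model(rng: random.Random, max_depth: int = 4) -> MapModel:
    """A model of randomly nested, properly contained area elements.

    Containment is purely geometric (no parent refs), so the semantic-zoom
    depth oracle is exercised on geometry alone.
    """
    m = MapModel(map_id="areas", width=1024.0, height=1024.0)
    counter = 0
    area_types = [ElementType.COMPARTMENT, ElementType.COMPLEX,
                  ElementType.TEXT_AREA]

    def subdivide(b: Bounds, depth: int):
        nonlocal counter
        if depth > max_depth:
            return
        # 2x2 subcells; each may host a child area, properly inset
        for i in range(2):
            for j in range(2):
                if rng.random() > 0.6:
                    continue
                cell = Bounds(b.x + i * b.w / 2, b.y + j * b.h / 2,
                              b.w / 2, b.h / 2)
                mx = cell.w * rng.uniform(0.05, 0.15)
                my = cell.h * rng.uniform(0.05, 0.15)
                child = Bounds(cell.x + mx, cell.y + my,
                               cell.w - 2 * mx, cell.h - 2 * my)
                counter += 1
                m.add_element(Element(
                    element_id=f"a{counter}",
                    element_type=rng.choice(area_types),
                    name=f"area {counter}",
                    bounds=child,
                ))
                subdivide(child, depth + 1)

    root = Bounds(12.0, 12.0, 1000.0, 1000.0)
    counter += 1
    m.add_element(Element(
        element_id=f"a{counter}",
        element_type=ElementType.COMPARTMENT,
        name="root",
        bounds=root,
    ))
    subdivide(root, 2)
    return m


def geometric_depth_oracle(model: MapModel) -> dict[str, int]:
    """Brute-force O(n^2) oracle: depth = 1 + number of areas strictly
    containing the area (valid for properly nested fixtures)."""
    areas = model.areas()
    depths = {}
    for a in areas:
        depths[a.element_id] = 1 + sum(
            1
            for b in areas
            if b.element_id != a.element_id
            and b.bounds.contains(a.bounds)
            and b.bounds.area > a.bounds.area
        )
    return depths
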