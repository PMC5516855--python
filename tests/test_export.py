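"""Region extraction, table export, SIF network export."""

import random

import pytest

from pathmap.errors import EmptyRegion
from pathmap.export import (
    export_network,
    export_table,
    extract_region,
    parse_table,
    region_element_ids,
    select_region,
)
from pathmap.fixtures import generate_fixture_map
from pathmap.io import read_celldesigner, read_sbgnml, write_celldesigner, write_sbgnml
from pathmap.model import (
    Bounds,
    ElementType,
    models_equivalent,
    validate_model,
)


def oracle_region_elements(model, bounds):
    """Independent re-application of the inclusion rules (set algebra over
    all elements, iterated to a fixed point)."""
    included = {
        eid for eid, el in model.elements.items() if el.bounds.intersects(bounds)
    }
    changed = True
    while changed:
        changed = False
        for eid, el in model.elements.items():
            if eid in included:
                continue
            # whole-complex rule: a complex joins when any member is in;
            # members join when their complex is in
            if el.element_type is ElementType.COMPLEX:
                members = {m.element_id for m in model.complex_members(eid)}
                if members & included:
                    included.add(eid)
                    changed = True
                    continue
            if el.parent_complex in included:
                included.add(eid)
                changed = True
                continue
            # container rule
            for other_id in list(included):
                other = model.elements[other_id]
                if eid in (other.compartment_ref, other.parent_complex):
                    included.add(eid)
                    changed = True
                    break
    return included


def oracle_region_interactions(model, included):
    return {
        iid
        for iid, inter in model.interactions.items()
        if inter.reactants and inter.products
        and all(p in included for p in [*inter.reactants, *inter.products])
    }


class TestSelectRegion:
    def test_full_canvas_selection_is_identity(self, small_map):
        sub = select_region(
            small_map, Bounds(0, 0, small_map.width, small_map.height)
        )
        assert models_equivalent(small_map, sub)

    def test_excluded_product_drops_the_reaction(self, small_map):
        # region holds s4's reactant side but excludes product s5
        sub, report = extract_region(small_map, Bounds(160, 30, 140, 70))
        assert "s4" in sub.elements
        assert "r1" not in sub.interactions
        assert "r1" in report.dropped_interactions

    def test_out_of_region_modifier_dropped_and_reported(self, small_map):
        # cover reactant s4 and product s5 but not modifier s2
        sub, report = extract_region(small_map, Bounds(160, 30, 200, 200))
        assert "r1" in sub.interactions
        assert sub.interactions["r1"].modifiers == []
        assert ("r1", "s2") in report.dropped_modifiers

    def test_complex_included_whole(self, small_map):
        # clip only the left half of the complex: both members + complex come
        sub = select_region(small_map, Bounds(20, 40, 30, 40))
        assert {"s1", "s2", "s3"} <= set(sub.elements)
        assert "c1" in sub.elements  # container rule

    def test_empty_selection_raises(self, small_map):
        with pytest.raises(EmptyRegion):
            select_region(small_map, Bounds(0, 0, 2, 2))
        with pytest.raises(EmptyRegion):
            select_region(small_map, Bounds(10, 10, -5, 5))

    @pytest.mark.parametrize("seed", range(4))
    def test_random_rectangles_match_oracle_and_validate(self, seed):
        model = generate_fixture_map(
            n_compartments=3, n_complexes=2, n_proteins=8, n_reactions=5,
            nesting_depth=2, n_text_areas=1, seed=seed,
        )
        rng = random.Random(1000 + seed)
        tested = 0
        while tested < 50:
            x = rng.uniform(0, model.width - 20)
            y = rng.uniform(0, model.height - 20)
            w = rng.uniform(20, model.width - x)
            h = rng.uniform(20, model.height - y)
            bounds = Bounds(x, y, w, h)
            expected_elements = oracle_region_elements(model, bounds)
            if not expected_elements:
                continue
            tested += 1
            sub = select_region(model, bounds)
            assert set(sub.elements) == expected_elements
            assert set(sub.interactions) == oracle_region_interactions(
                model, expected_elements
            )
            assert validate_model(sub) == []
            # idempotence
            again = select_region(sub, bounds)
            assert models_equivalent(sub, again)

    def test_monotone_in_selection(self, small_map):
        inner = Bounds(30, 40, 100, 60)
        outer = Bounds(20, 30, 250, 150)
        assert region_element_ids(small_map, inner) <= region_element_ids(
            small_map, outer
        )

    def test_annotations_preserved_verbatim(self, small_map):
        sub = select_region(small_map, Bounds(0, 0, 400, 300))
        assert (
            sub.elements["s2"].annotation_set()
            == small_map.elements["s2"].annotation_set()
        )
        assert sub.elements["s2"].synonyms == ["p53"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exported_region_reimports_through_both_dialects(self, seed):
        model = generate_fixture_map(
            n_compartments=2, n_complexes=1, n_proteins=6, n_reactions=3,
            seed=seed,
        )
        sub = select_region(model, Bounds(0, 0, model.width / 2, model.height))
        for write, read in ((write_celldesigner, read_celldesigner),
                            (write_sbgnml, read_sbgnml)):
            again = read(write(sub))
            assert validate_model(again) == []


class TestExportTable:
    def test_row_counts_and_header(self, small_map):
        lines = export_table(small_map).splitlines()
        assert lines[0].startswith("kind\tid\tname\ttype")
        assert len(lines) == 1 + 6 + 1  # header + elements + interactions

    def test_annotation_cell_sorted_and_joined(self, small_map):
        table = export_table(small_map)
        row = next(l for l in table.splitlines() if l.split("\t")[1] == "s2")
        assert row.split("\t")[8] == "entrez:7157;uniprot:P04637"

    def test_parse_back_recovers_ids_types_annotations(self, small_map):
        parsed = parse_table(export_table(small_map))
        assert set(parsed["elements"]) == set(small_map.elements)
        for eid, rec in parsed["elements"].items():
            el = small_map.elements[eid]
            assert rec["type"] == el.element_type.value
            assert rec["annotations"] == {
                (a.namespace, a.identifier) for a in el.annotations
            }
        for iid, rec in parsed["interactions"].items():
            inter = small_map.interactions[iid]
            assert rec["type"] == inter.interaction_type.value
            assert rec["reactants"] == inter.reactants
            assert rec["modifiers"] == [
                (m.element_id, m.role.value) for m in inter.modifiers
            ]


class TestExportNetwork:
    def test_reaction_with_catalyst_expands_to_two_edges(self, small_map):
        sif = export_network(small_map)
        assert sif.splitlines() == [
            "s4\tSTATE_TRANSITION\ts5",
            "s2\tCATALYSIS\ts5",
        ]

    def test_no_interactions_gives_empty_body(self):
        from pathmap.model import MapModel

        assert export_network(MapModel(map_id="m")) == ""

    @pytest.mark.parametrize("seed", range(3))
    def test_edge_count_matches_counting_oracle(self, seed):
        model = generate_fixture_map(
            n_compartments=2, n_complexes=1, n_proteins=7, n_reactions=6,
            seed=seed,
        )
        n_lines = len(export_network(model).splitlines())
        expected = sum(
            len(i.reactants) * len(i.products)
            + len(i.modifiers) * len(i.products)
            for i in model.interactions.values()
        )
        assert n_lines == expected
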