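"""Overlay parsing, value-to-color interpolation, entry matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathmap.errors import EmptyDataset, FormatError, ValueOutOfRange
from pathmap.overlay import (
    ColorScheme,
    OverlayDataset,
    OverlayEntry,
    _parse_hex,
    entry_matches_element,
    entry_matches_interaction,
    match_entries,
    parse_overlay,
    serialize_overlay,
    value_to_color,
)


class TestParseOverlay:
    def test_two_value_rows(self):
        ds = parse_overlay(
            "#name: my dataset\n"
            "name\tvalue\n"
            "TP53\t0.5\n"
            "MDM2\t-1\n"
        )
        assert ds.name == "my dataset"
        assert [e.name for e in ds.entries] == ["TP53", "MDM2"]
        assert [e.value for e in ds.entries] == [0.5, -1.0]

    def test_out_of_range_value_rejected_with_row_number(self):
        ds = parse_overlay("name\tvalue\nTP53\t0.5\nMDM2\t3\n")
        assert len(ds.entries) == 1
        assert ds.rejected[0].row_number == 3
        assert "out of [-1,1]" in ds.rejected[0].reason

    def test_color_only_rows(self):
        ds = parse_overlay("name\tcolor\nTP53\t#00FF00\n")
        e = ds.entries[0]
        assert e.color == "#00FF00" and e.value is None

    def test_unknown_header_column_raises(self):
        with pytest.raises(FormatError):
            parse_overlay("name\tfold_change\nTP53\t2\n")

    def test_no_valid_rows_raises_empty_dataset(self):
        with pytest.raises(EmptyDataset):
            parse_overlay("name\tvalue\nTP53\t9\n")

    def test_identifier_and_type_columns(self):
        ds = parse_overlay(
            "identifier\ttype\tvalue\n"
            "uniprot:P04637\tPROTEIN\t0.25\n"
            "CHEBI:18243\t\t-0.5\n"
        )
        assert (ds.entries[0].namespace, ds.entries[0].identifier) == (
            "uniprot", "P04637")
        assert ds.entries[0].element_type.value == "PROTEIN"
        assert (ds.entries[1].namespace, ds.entries[1].identifier) == (
            "chebi", "CHEBI:18243")

    def test_serialize_parse_identity(self):
        ds = parse_overlay(
            "#name: rt\n"
            "name\tidentifier\ttype\tvalue\tcolor\tline_width\n"
            "TP53\tuniprot:P04637\tPROTEIN\t0.5\t\t\n"
            "\tpubmed:12345678\t\t\t#00FF00\t2.5\n"
        )
        again = parse_overlay(serialize_overlay(ds))
        assert again.name == ds.name
        assert again.entries == ds.entries


class TestValueToColor:
    def test_fixed_point_and_endpoints(self):
        assert value_to_color(0.0) == "#FFFFFF"
        assert value_to_color(1.0) == "#FF0000"
        assert value_to_color(-1.0) == "#0000FF"

    def test_negative_half_interpolates_per_channel(self):
        # independent oracle: round(neutral + (pole - neutral) * |v|) per channel
        scheme = ColorScheme()
        v = -0.5
        expected = "#" + "".join(
            f"{int(n + (p - n) * abs(v) + 0.5):02X}"
            for n, p in zip(_parse_hex(scheme.neutral), _parse_hex(scheme.negative))
        )
        assert expected == "#8080FF"
        assert value_to_color(v, scheme) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueOutOfRange):
            value_to_color(1.5)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_per_channel_on_each_half(self, a, b):
        lo, hi = sorted([a, b])
        for sign in (1.0, -1.0):
            c_lo = _parse_hex(value_to_color(sign * lo))
            c_hi = _parse_hex(value_to_color(sign * hi))
            pole = _parse_hex(
                ColorScheme().positive if sign > 0 else ColorScheme().negative
            )
            neutral = _parse_hex(ColorScheme().neutral)
            for ch in range(3):
                if pole[ch] >= neutral[ch]:
                    assert c_hi[ch] >= c_lo[ch]
                else:
                    assert c_hi[ch] <= c_lo[ch]

    @settings(max_examples=40, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetric_scheme_mirrors(self, v):
        scheme = ColorScheme(negative="#00FF00", neutral="#000000",
                             positive="#00FF00")
        assert value_to_color(v, scheme) == value_to_color(-v, scheme)


class TestMatchEntries:
    def test_identifier_match(self, small_map):
        ds = OverlayDataset(entries=[
            OverlayEntry(namespace="uniprot", identifier="P04637", value=0.5),
        ])
        binding = match_entries(ds, small_map)
        assert binding.element_matches == [["s2"]]
        assert binding.unmatched == []

    def test_name_match_is_case_insensitive(self, small_map):
        ds = OverlayDataset(entries=[OverlayEntry(name="tp53", value=0.1)])
        assert match_entries(ds, small_map).element_matches == [["s2"]]

    def test_synonym_match(self, small_map):
        ds = OverlayDataset(entries=[OverlayEntry(name="P53", value=0.1)])
        assert match_entries(ds, small_map).element_matches == [["s2"]]

    def test_identifier_takes_precedence_over_name(self, small_map):
        # identifier resolves to MDM2 although the name says TP53
        ds = OverlayDataset(entries=[
            OverlayEntry(name="TP53", namespace="uniprot",
                         identifier="Q00987", value=0.1),
        ])
        assert match_entries(ds, small_map).element_matches == [["s3"]]

    def test_type_filter_applies(self, small_map):
        ds = OverlayDataset(entries=[
            OverlayEntry(name="dopamine",
                         element_type=small_map.elements["s2"].element_type,
                         value=0.2),
        ])
        binding = match_entries(ds, small_map)
        assert binding.element_matches == [[]]
        assert binding.unmatched == [0]

    def test_interaction_identifier_match(self, small_map):
        ds = OverlayDataset(entries=[
            OverlayEntry(namespace="pubmed", identifier="12345678",
                         value=0.9, line_width=3.0),
        ])
        binding = match_entries(ds, small_map)
        assert binding.interaction_matches == [["r1"]]
        color, width = binding.interaction_styles()["r1"]
        assert width == 3.0 and color is not None

    def test_binding_equals_brute_force_scan(self, small_map):
        ds = OverlayDataset(entries=[
            OverlayEntry(name="tp53", value=0.5),
            OverlayEntry(namespace="uniprot", identifier="P37840", value=-0.5),
            OverlayEntry(name="dopamine", value=1.0),
            OverlayEntry(namespace="pubmed", identifier="12345678", color="#123456"),
            OverlayEntry(name="absent", value=0.0),
        ])
        binding = match_entries(ds, small_map)
        for i, entry in enumerate(ds.entries):
            expected_el = [
                eid for eid, el in small_map.elements.items()
                if entry_matches_element(entry, el)
            ]
            expected_in = [
                iid for iid, inter in small_map.interactions.items()
                if entry_matches_interaction(entry, inter)
            ]
            assert binding.element_matches[i] == expected_el
            assert binding.interaction_matches[i] == expected_in
        assert binding.unmatched == [4]

    def test_later_dataset_wins_conflicts(self, small_map):
        from pathmap.overlay import combine_element_styles

        ds1 = OverlayDataset(entries=[OverlayEntry(name="TP53", color="#111111")])
        ds2 = OverlayDataset(entries=[OverlayEntry(name="TP53", color="#222222")])
        styles = combine_element_styles([
            match_entries(ds1, small_map), match_entries(ds2, small_map),
        ])
        assert styles["s2"] == "#222222"
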