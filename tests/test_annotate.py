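"""MIRIAM registry resolution, automatic annotation, verification rules."""

import pytest

from pathmap.annotate import (
    INTERACTION,
    AnnotatorSpec,
    BlockingClient,
    FixtureAnnotatorClient,
    MiriamRegistry,
    VerificationRule,
    annotate_model,
    default_annotator_specs,
    default_registry,
    parse_uri,
    resolve_uri,
    verify_annotations,
)
from pathmap.errors import InvalidIdentifier, UnknownNamespace
from pathmap.model import (
    Annotation,
    Bounds,
    Element,
    ElementType,
    Interaction,
    InteractionType,
    MapModel,
)

from conftest import make_element

#: one known-valid identifier per seeded namespace, for the URI round trip
SAMPLE_IDS = {
    "uniprot": "P04637",
    "chebi": "CHEBI:15355",
    "ensembl": "ENSG00000141510",
    "entrez": "7157",
    "go": "GO:0006915",
    "hgnc": "11998",
    "hgnc.symbol": "TP53",
    "pubmed": "9254694",
    "doi": "10.1093/nar/gkv1070",
    "drugbank": "DB01235",
    "chembl": "CHEMBL1009",
    "kegg.compound": "C00355",
    "kegg.pathway": "hsa05012",
    "taxonomy": "9606",
    "ec-code": "1.14.16.2",
    "interpro": "IPR002117",
    "pfam": "PF00870",
    "reactome": "R-HSA-209931",
    "mirbase": "MI0000060",
    "mesh": "D010300",
    "refseq": "NM_000546",
    "omim": "168600",
}


class TestRegistry:
    def test_resolve_uniprot(self):
        reg = default_registry()
        uri = resolve_uri(reg, Annotation("uniprot", "P04637"))
        assert uri == "https://identifiers.org/uniprot/P04637"

    def test_resolve_compact_chebi(self):
        uri = resolve_uri(default_registry(), Annotation("chebi", "CHEBI:15355"))
        assert "CHEBI:15355" in uri

    def test_invalid_identifier_rejected(self):
        with pytest.raises(InvalidIdentifier):
            resolve_uri(default_registry(), Annotation("uniprot", "not an id!"))

    def test_unknown_namespace_rejected(self):
        with pytest.raises(UnknownNamespace):
            resolve_uri(default_registry(), Annotation("nope", "1"))

    def test_uri_parse_back_is_identity_for_every_namespace(self):
        reg = default_registry()
        assert set(SAMPLE_IDS) == set(reg.entries), "sample table out of sync"
        for ns, ident in SAMPLE_IDS.items():
            ann = Annotation(ns, ident)
            back = parse_uri(reg, resolve_uri(reg, ann))
            assert (back.namespace, back.identifier) == (ns, ident)

    def test_config_file_extends_registry(self, tmp_path):
        cfg = tmp_path / "registry.yaml"
        cfg.write_text(
            "namespaces:\n"
            "  wikidata:\n"
            "    name: Wikidata\n"
            '    uri_pattern: "https://identifiers.org/wikidata/{id}"\n'
            '    id_regex: "^Q\\\\d+$"\n'
        )
        reg = MiriamRegistry.from_config(cfg)
        assert "wikidata" in reg and "uniprot" in reg
        assert resolve_uri(reg, Annotation("wikidata", "Q283350")).endswith("Q283350")


def _bare_model(n_proteins=2, n_interactions=1):
    m = MapModel(map_id="m", width=500, height=300)
    for i in range(n_proteins):
        m.add_element(make_element(
            f"s{i + 1}", ElementType.PROTEIN, 20 + 120 * i, 20, 80, 30,
            name=f"P{i + 1}",
        ))
    for k in range(n_interactions):
        m.add_interaction(Interaction(
            f"r{k + 1}", InteractionType.STATE_TRANSITION,
            reactants=["s1"], products=["s2"],
            polyline=[(0.0, 0.0), (1.0, 1.0)],
        ))
    return m


class TestAnnotateModel:
    def test_name_triggered_hgnc_adds_cross_references(self):
        m = _bare_model()
        m.elements["s1"].name = "TP53"
        report = annotate_model(m, default_annotator_specs())
        added = {(a.namespace, a.identifier)
                 for a in report.per_element["s1"].added}
        assert ("entrez", "7157") in added
        assert ("uniprot", "P04637") in added
        assert "p53" in m.elements["s1"].synonyms

    def test_existing_annotation_not_duplicated(self):
        m = _bare_model()
        m.elements["s1"].name = "TP53"
        m.elements["s1"].annotations.append(Annotation("entrez", "7157"))
        annotate_model(m, default_annotator_specs())
        identifiers = [
            (a.namespace, a.identifier) for a in m.elements["s1"].annotations
        ]
        assert identifiers.count(("entrez", "7157")) == 1

    def test_miriam_triggered_uniprot_fires_on_identifier(self):
        m = _bare_model()
        m.elements["s1"].annotations.append(Annotation("uniprot", "P04637"))
        annotate_model(m, default_annotator_specs())
        assert ("go", "GO:0006915") in {
            (a.namespace, a.identifier) for a in m.elements["s1"].annotations
        }

    def test_idempotent_and_monotone(self):
        m = _bare_model(n_proteins=3)
        m.elements["s1"].name = "TP53"
        m.elements["s2"].name = "SNCA"
        specs = default_annotator_specs()
        annotate_model(m, specs)
        before = {
            eid: (el.annotation_set(), list(el.synonyms))
            for eid, el in m.elements.items()
        }
        second = annotate_model(m, specs)
        assert second.n_added == 0
        for eid, el in m.elements.items():
            assert el.annotation_set() >= before[eid][0]  # monotone
            assert el.synonyms == before[eid][1]

    def test_client_failure_recorded_not_raised(self):
        m = _bare_model()
        m.elements["s1"].name = "TP53"
        specs = [
            AnnotatorSpec("broken", "NAME", BlockingClient()),
            AnnotatorSpec("hgnc", "NAME", FixtureAnnotatorClient("hgnc")),
        ]
        report = annotate_model(m, specs)
        assert report.n_failed >= 1
        assert report.per_element["s1"].added  # hgnc still ran


class TestVerifyAnnotations:
    def test_pubmed_rule_flags_unannotated_interactions(self):
        """Literature completeness: with 3 interactions of which 1 carries a
        PubMed reference, a pubmed-required rule warns on the other 2."""
        m = _bare_model(n_interactions=3)
        m.interactions["r2"].annotations.append(
            Annotation("pubmed", "9254694", "isDescribedBy")
        )
        rule = VerificationRule(INTERACTION, frozenset({"pubmed"}))
        warnings = verify_annotations(m, [rule])
        assert len(warnings) == 2
        assert {w.target_id for w in warnings} == {"r1", "r3"}

    def test_fully_annotated_model_yields_no_warnings(self):
        m = _bare_model(n_interactions=2)
        for inter in m.interactions.values():
            inter.annotations.append(Annotation("pubmed", "1", "isDescribedBy"))
        rule = VerificationRule(INTERACTION, frozenset({"pubmed"}))
        assert verify_annotations(m, [rule]) == []

    def test_multiple_rules_cross_product(self):
        m = _bare_model(n_proteins=2, n_interactions=1)  # all bare
        rules = [
            VerificationRule("PROTEIN", frozenset({"uniprot"})),
            VerificationRule(INTERACTION, frozenset({"pubmed"})),
        ]
        warnings = verify_annotations(m, rules)
        assert len(warnings) == 3  # 2 bare proteins + 1 bare interaction

    def test_warning_count_matches_exhaustive_oracle(self, small_map):
        rules = [
            VerificationRule("PROTEIN", frozenset({"uniprot"})),
            VerificationRule("SIMPLE_MOLECULE", frozenset({"chebi"})),
            VerificationRule(INTERACTION, frozenset({"pubmed", "doi"})),
        ]
        warnings = verify_annotations(small_map, rules)
        # brute force over every (rule, object) pair
        expected = 0
        for rule in rules:
            if rule.target == INTERACTION:
                objs = list(small_map.interactions.values())
            else:
                objs = [e for e in small_map.elements.values()
                        if e.element_type is ElementType(rule.target)]
            for obj in objs:
                namespaces = {a.namespace for a in obj.annotations}
                if not namespaces & rule.required_namespaces:
                    expected += 1
        assert len(warnings) == expected

    def test_at_least_one_of_required_set_suffices(self):
        m = _bare_model(n_interactions=1)
        m.interactions["r1"].annotations.append(Annotation("doi", "10.1000/x1"))
        rule = VerificationRule(INTERACTION, frozenset({"pubmed", "doi"}))
        assert verify_annotations(m, [rule]) == []
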