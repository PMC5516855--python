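"""Automatically annotate a map from the bundled offline annotator fixtures,
then run a literature-completeness verification rule."""

from pathmap import (
    VerificationRule, annotate_model, default_annotator_specs,
    generate_fixture_map, verify_annotations,
)
from pathmap.annotate import INTERACTION

model = generate_fixture_map(n_proteins=6, n_reactions=4, seed=3)
# strip two proteins down to bare names the NAME-triggered annotators know
proteins = [e for e in model.elements.values() if e.element_type.value == "PROTEIN"]
for el, name in zip(proteins, ("TP53", "SNCA")):
    el.name, el.annotations, el.synonyms = name, [], []

report = annotate_model(model, default_annotator_specs())
# each added entry is one new (namespace, identifier) cross-reference
print(f"annotation pass added {report.n_added} cross-references")
for el in proteins[:2]:
    refs = ", ".join(f"{a.namespace}:{a.identifier}" for a in el.annotations)
    print(f"  {el.name}: {refs}")
second = annotate_model(model, default_annotator_specs())
print(f"second pass added {second.n_added} (annotation is idempotent)")

rule = VerificationRule(INTERACTION, frozenset({"pubmed"}))
warnings = verify_annotations(model, [rule])
# one warning per interaction lacking any PubMed literature reference
print(f"{len(warnings)} of {len(model.interactions)} interactions lack a "
      "PubMed annotation")
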