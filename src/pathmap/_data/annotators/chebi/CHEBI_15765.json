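{
  "preferred_name": "L-dopa",
  "synonyms": ["levodopa", "3,4-dihydroxy-L-phenylalanine"],
  "cross_references": [["kegg.compound", "C00355"]],
  "description": "dopamine precursor amino acid"
}
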