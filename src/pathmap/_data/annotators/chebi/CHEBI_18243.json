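{
  "preferred_name": "dopamine",
  "synonyms": ["4-(2-aminoethyl)benzene-1,2-diol"],
  "cross_references": [["kegg.compound", "C03758"]],
  "description": "catecholamine neurotransmitter"
}
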