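{
  "preferred_name": "TH",
  "synonyms": ["tyrosine hydroxylase"],
  "cross_references": [["entrez", "7054"], ["uniprot", "P07101"]],
  "description": "tyrosine hydroxylase"
}
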