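{
  "preferred_name": "DDC",
  "synonyms": ["AADC", "aromatic L-amino acid decarboxylase"],
  "cross_references": [["entrez", "1644"], ["uniprot", "P20711"]],
  "description": "dopa decarboxylase"
}
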