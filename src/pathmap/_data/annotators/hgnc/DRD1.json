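{
  "preferred_name": "DRD1",
  "synonyms": ["dopamine receptor D1"],
  "cross_references": [["entrez", "1812"], ["uniprot", "P21728"]],
  "description": "dopamine receptor D1"
}
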