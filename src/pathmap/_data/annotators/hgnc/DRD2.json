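{
  "preferred_name": "DRD2",
  "synonyms": ["dopamine receptor D2"],
  "cross_references": [["entrez", "1813"], ["uniprot", "P14416"]],
  "description": "dopamine receptor D2"
}
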