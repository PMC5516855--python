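{
  "preferred_name": "MDM2",
  "synonyms": ["MDM2 proto-oncogene"],
  "cross_references": [["entrez", "4193"], ["uniprot", "Q00987"]],
  "description": "MDM2 proto-oncogene, E3 ubiquitin ligase"
}
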