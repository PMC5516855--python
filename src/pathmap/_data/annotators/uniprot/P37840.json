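{
  "preferred_name": "Alpha-synuclein",
  "synonyms": [],
  "cross_references": [["hgnc.symbol", "SNCA"], ["go", "GO:0042416"]],
  "description": "neuronal protein involved in synaptic vesicle trafficking"
}
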