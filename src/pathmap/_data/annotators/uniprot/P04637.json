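{
  "preferred_name": "Cellular tumor antigen p53",
  "synonyms": ["Antigen NY-CO-13"],
  "cross_references": [["hgnc.symbol", "TP53"], ["go", "GO:0006915"], ["interpro", "IPR002117"]],
  "description": "acts as a tumor suppressor; induces growth arrest or apoptosis"
}
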