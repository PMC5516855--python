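{
  "preferred_name": "TP53",
  "synonyms": ["BCC7", "LFS1"],
  "cross_references": [["ensembl", "ENSG00000141510"], ["hgnc.symbol", "TP53"]],
  "description": "tumor protein p53"
}
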