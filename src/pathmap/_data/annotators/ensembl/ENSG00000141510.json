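{
  "preferred_name": "TP53",
  "synonyms": [],
  "cross_references": [["entrez", "7157"]],
  "description": "tumor protein p53 [Ensembl gene]"
}
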