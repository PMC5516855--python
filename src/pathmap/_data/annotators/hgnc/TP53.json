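{
  "preferred_name": "TP53",
  "synonyms": ["p53", "tumor protein p53"],
  "cross_references": [["entrez", "7157"], ["uniprot", "P04637"], ["ensembl", "ENSG00000141510"]],
  "description": "tumor protein p53"
}
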