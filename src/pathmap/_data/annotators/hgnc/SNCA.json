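{
  "preferred_name": "SNCA",
  "synonyms": ["alpha-synuclein", "NACP"],
  "cross_references": [["entrez", "6622"], ["uniprot", "P37840"], ["ensembl", "ENSG00000145335"]],
  "description": "synuclein alpha"
}
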