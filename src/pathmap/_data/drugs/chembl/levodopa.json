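{
  "name": "LEVODOPA",
  "description": "CHEMBL1009; dopamine receptor agonist precursor.",
  "synonyms": ["CHEMBL1009"],
  "targets": [["uniprot", "P21728"], ["uniprot", "P14416"]],
  "target_symbols": ["DRD1", "DRD2"]
}
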