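{
  "name": "Levodopa",
  "description": "Dopamine precursor used in Parkinson's disease; crosses the blood-brain barrier and is decarboxylated to dopamine.",
  "synonyms": ["L-DOPA", "3,4-dihydroxy-L-phenylalanine"],
  "targets": [["uniprot", "P21728"], ["uniprot", "P14416"], ["uniprot", "P20711"]],
  "target_symbols": ["DRD1", "DRD2", "DDC"]
}
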