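{
  "name": "Carbidopa",
  "description": "Peripheral aromatic L-amino acid decarboxylase inhibitor co-administered with levodopa.",
  "synonyms": ["Lodosyn"],
  "targets": [["uniprot", "P20711"]],
  "target_symbols": ["DDC"]
}
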