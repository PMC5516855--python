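{
  "name": "CARBIDOPA",
  "description": "CHEMBL1200748; DDC inhibitor.",
  "synonyms": ["CHEMBL1200748"],
  "targets": [["uniprot", "P20711"]],
  "target_symbols": ["DDC"]
}
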