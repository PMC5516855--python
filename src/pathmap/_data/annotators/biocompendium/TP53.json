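{
  "preferred_name": "TP53",
  "synonyms": ["cellular tumor antigen p53"],
  "cross_references": [],
  "description": "transcription factor integrating stress signals; induces cell-cycle arrest and apoptosis"
}
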