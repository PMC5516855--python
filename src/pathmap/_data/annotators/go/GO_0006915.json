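{
  "preferred_name": "apoptotic process",
  "synonyms": ["apoptosis"],
  "cross_references": [],
  "description": "programmed cell death"
}
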