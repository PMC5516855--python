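{
  "preferred_name": "SNCA",
  "synonyms": ["non-A beta component of AD amyloid"],
  "cross_references": [],
  "description": "presynaptic protein aggregating in Lewy bodies"
}
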