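{
  "tracers": {
    "HRP": "retrograde",
    "PHAL": "anterograde"
  },
  "density_map": {
    "no label": "none",
    "very sparse label": "weak",
    "sparse label": "weak",
    "sparse/moderate label": "moderate",
    "moderate label": "moderate",
    "moderate/dense label": "strong",
    "dense label": "strong",
    "present-unknown": "weak"
  }
}
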