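{
  "type": "oracle1d",
  "name": "reference",
  "k": 300.0,
  "x1": 0.0,
  "x2": 1.0,
  "c2": 0.0,
  "domain": [-0.3, 1.3],
  "mass": 12.0,
  "coupling": {"delta_alpha": 0.0, "h12": 8.0}
}
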