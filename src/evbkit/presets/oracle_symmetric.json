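{
  "type": "oracle1d",
  "name": "symmetric",
  "k": 300.0,
  "x1": -0.5,
  "x2": 0.5,
  "c2": 0.0,
  "domain": [-0.8, 0.8],
  "mass": 12.0,
  "coupling": {"delta_alpha": 0.0, "h12": 6.0}
}
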