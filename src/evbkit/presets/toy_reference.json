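{
  "type": "toy_reaction",
  "seed": 0,
  "spec": {
    "n_solvent": 10,
    "restraint_radius": 6.5,
    "restraint_k": 10.0,
    "catalyst": false,
    "catalyst_charge": 0.9,
    "catalyst_distance": 2.8
  },
  "coupling": {
    "delta_alpha": -14.0,
    "h12": 6.0
  }
}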