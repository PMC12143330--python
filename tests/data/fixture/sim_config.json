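{
  "class_proportions": {
    "balanced": 1.0
  },
  "depth_nb_p": 0.16666666666666666,
  "depth_nb_r": 10.0,
  "effect_high": 0.9,
  "effect_low": 0.7,
  "het_prob": 0.6,
  "n_animals": 2,
  "n_genes": 5,
  "phase_block_split_prob": 0.0,
  "ref_bias": 0.5,
  "rho": 0.001,
  "seed": 0,
  "snv_floor": 1,
  "snv_nb_p": 0.25,
  "snv_nb_r": 4.0,
  "tissues": [
    "kidney",
    "liver",
    "spleen"
  ]
}
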