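{
  "seed": 2024,
  "phenotype_model": "BM",
  "phenotype_params": {
    "sigma2": 0.02
  },
  "shape_env_beta": 0.1,
  "env_blocks": {
    "vegetation": {
      "n_axes": 3,
      "sigma2": 0.5
    },
    "temperature": {
      "n_axes": 2,
      "sigma2": 0.5
    },
    "precipitation": {
      "n_axes": 2,
      "sigma2": 0.5
    },
    "elevation": {
      "n_axes": 1,
      "sigma2": 0.5
    }
  },
  "group_sizes": {
    "north": 17,
    "south": 9
  },
  "base_height": 5.000000000000001
}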