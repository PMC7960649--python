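{
  "model": {
    "backend": "classical",
    "algorithm": "smlr",
    "lambda": 0.01,
    "max_iter": 500
  },
  "data": {
    "loader": "generic",
    "path": "benchmark_small.npz",
    "data_var": "data",
    "attr_vars": ["condition"],
    "target_attr": "condition",
    "rescale": {"method": "standardize"}
  },
  "analysis": {
    "scheme": "single",
    "fractions": [0.95, 0.0, 0.05],
    "n_iterations": 10,
    "seed": 0
  },
  "output": {
    "directory": "results",
    "prefix": "classical_smlr",
    "kinds": "all"
  }
}
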