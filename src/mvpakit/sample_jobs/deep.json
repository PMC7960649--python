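{
  "model": {
    "backend": "deep",
    "layers": [
      {"kind": "conv", "filters": 8, "kernel": [10], "activation": "leaky_relu"},
      {"kind": "flatten"},
      {"kind": "dense", "units": 32, "activation": "leaky_relu"},
      {"kind": "dropout", "rate": 0.3},
      {"kind": "dense", "units": 3, "activation": "softmax"}
    ],
    "optimizer": {"kind": "sgd", "lr": 0.01, "momentum": 0.9, "nesterov": true},
    "training": {"epochs": 30, "batch_size": 32}
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
    "fractions": [0.70, 0.15, 0.15],
    "n_iterations": 20,
    "seed": 0
  },
  "output": {
    "directory": "results",
    "prefix": "deep",
    "kinds": "all"
  }
}
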