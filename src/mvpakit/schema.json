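{
  "description": "Allowed keys per job-file section. Unknown keys inside a section are warnings (forward compatibility); unknown top-level sections are errors.",
  "sections": {
    "model": {
      "keys": ["backend", "algorithm", "C", "lambda", "lam", "max_iter", "tol",
               "layers", "optimizer", "training"]
    },
    "data": {
      "keys": ["loader", "path", "loader_path", "loader_func", "data_var",
               "attr_vars", "target_attr", "rescale", "params"]
    },
    "analysis": {
      "keys": ["scheme", "fractions", "n_iterations", "seed", "loop_attr",
               "loop_mode"]
    },
    "output": {
      "keys": ["directory", "prefix", "kinds"]
    }
  },
  "schemes": ["single", "loop_over_sa"],
  "rescale_methods": ["percentile", "standardize", "mean_center", "map_range"],
  "backends": ["classical", "deep"],
  "classical_algorithms": ["svm", "smlr"],
  "layer_kinds": ["dense", "conv", "recurrent", "dropout", "flatten",
                  "activation", "pool"],
  "output_kinds": ["test_accuracy", "train_accuracy", "val_accuracy", "scores",
                   "labels", "timestamps", "metadata", "model", "job_copy"]
}
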