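{
  "description": "Study conditions of the end-to-end recovery experiment and the medians measured in the recorded pilot run (single CPU). Both 1D strands use the same 3-layer hidden-32 architecture; the 2D network is larger (hidden 48) because it processes both strands' information.",
  "conditions": {
    "seed": 1,
    "genome_length": 20000,
    "n_reads": 60,
    "n_train": 45,
    "read_length": [150, 300],
    "hidden_template": [32, 32, 32],
    "epochs_template": 90,
    "hidden_complement": [32, 32, 32],
    "epochs_complement": 90,
    "hidden_2d": [48, 48, 48],
    "epochs_2d": 90,
    "learning_rate": 0.03,
    "realign_every": 15,
    "sim": {"k": 6, "p_skip": 0.05, "p_split": 0.05,
            "noise_mean": 1.0, "noise_stdev": 0.3,
            "scale": [0.9, 1.1], "shift": [-15.0, 15.0]}
  },
  "pilot": {
    "median_template_1d_accuracy_noisy": 0.5204,
    "median_template_1d_accuracy_noiseless": 0.5243,
    "median_complement_1d_accuracy_noisy": 0.5219,
    "median_2d_accuracy_noisy": 0.5263,
    "unrelated_sequence_identity_floor": 0.5,
    "runtime_s": 229
  }
}
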