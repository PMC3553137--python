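{
  "n_subjects": 15,
  "trials_per_condition": 50,
  "sampling_rate": 250.0,
  "epoch_start": -100.0,
  "epoch_end": 1000.0,
  "channels": ["Fz", "Cz", "Pz"],
  "noise_sd": 10.0,
  "noise_model": "one_over_f",
  "alpha_amp": 2.0,
  "channel_noise_correlation": 0.7,
  "distractor_pool_size": 240,
  "subject_amp_sd": 0.15,
  "subject_latency_sd": 20.0,
  "seed": null,
  "components": {
    "Probe": [
      {
        "channel_weights": {"Fz": 1.0, "Cz": 0.9, "Pz": 0.2},
        "shape": "biphasic",
        "pos_peak": 240.0,
        "pos_width": 40.0,
        "pos_amp": 8.0,
        "neg_peak": 400.0,
        "neg_width": 60.0,
        "neg_amp": -6.0,
        "latency_jitter_sd": 20.0
      },
      {
        "channel_weights": {"Fz": 0.1, "Cz": 0.4, "Pz": 1.0},
        "shape": "monophasic",
        "pos_peak": 500.0,
        "pos_width": 120.0,
        "pos_amp": 10.0,
        "neg_peak": 800.0,
        "neg_width": 100.0,
        "neg_amp": 0.0,
        "latency_jitter_sd": 30.0
      }
    ],
    "Fake": [
      {
        "channel_weights": {"Fz": 1.0, "Cz": 0.9, "Pz": 0.2},
        "shape": "biphasic",
        "pos_peak": 280.0,
        "pos_width": 40.0,
        "pos_amp": 7.0,
        "neg_peak": 440.0,
        "neg_width": 60.0,
        "neg_amp": -5.0,
        "latency_jitter_sd": 20.0
      },
      {
        "channel_weights": {"Fz": 0.1, "Cz": 0.4, "Pz": 1.0},
        "shape": "monophasic",
        "pos_peak": 560.0,
        "pos_width": 120.0,
        "pos_amp": 10.0,
        "neg_peak": 860.0,
        "neg_width": 100.0,
        "neg_amp": 0.0,
        "latency_jitter_sd": 30.0
      }
    ]
  }
}
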