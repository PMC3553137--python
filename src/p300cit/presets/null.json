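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
  "components": {}
}
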