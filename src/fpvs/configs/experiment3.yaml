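# Duty cycle: face oddballs (1 Hz) among objects under three presentation
# regimes -- 10 Hz at 100% duty, 10 Hz at 50% duty, 20 Hz at 100% duty.
# 90 s sequences, 3 s ramps, window anchored at onset.
experiment_id: 3
fs_raw: 1024
n_trials_per_condition: 4
roi: [PO7, PO8, P7, P8, P9, P10]
conditions:
  - {name: 10hz_full, base_freq: 10, oddball_freq: 1, sequence_s: 90, ramp_s: 3, steady_samples: 23041, duty_cycle: 1.0, anchor: onset}
  - {name: 10hz_half, base_freq: 10, oddball_freq: 1, sequence_s: 90, ramp_s: 3, steady_samples: 23041, duty_cycle: 0.5, anchor: onset}
  - {name: 20hz_full, base_freq: 20, oddball_freq: 1, sequence_s: 90, ramp_s: 3, steady_samples: 23041, duty_cycle: 1.0, anchor: onset}
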