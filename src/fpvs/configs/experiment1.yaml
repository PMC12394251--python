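# Identity discrimination: face streams at four presentation rates with a
# 1 Hz identity oddball.  60 s sequences, 2 s contrast ramps; the retained
# steady-state window starts at the end of the ramp-up.
experiment_id: 1
fs_raw: 1024
n_trials_per_condition: 4
roi: [PO7, PO8, P7, P8, P9, P10]
conditions:
  - {name: base3,  base_freq: 3,  oddball_freq: 1, sequence_s: 60, ramp_s: 2, steady_samples: 14337, anchor: ramp_end}
  - {name: base6,  base_freq: 6,  oddball_freq: 1, sequence_s: 60, ramp_s: 2, steady_samples: 14337, anchor: ramp_end}
  - {name: base9,  base_freq: 9,  oddball_freq: 1, sequence_s: 60, ramp_s: 2, steady_samples: 14337, anchor: ramp_end}
  - {name: base12, base_freq: 12, oddball_freq: 1, sequence_s: 60, ramp_s: 2, steady_samples: 14337, anchor: ramp_end}
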