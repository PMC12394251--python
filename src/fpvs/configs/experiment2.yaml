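# Category selectivity: object streams at 6 Hz with a 1 Hz face or house
# oddball.  60 s sequences, 5 s contrast ramps; the retained window is
# anchored at sequence onset so the printed sample count fits.
experiment_id: 2
fs_raw: 1024
n_trials_per_condition: 4
roi: [PO7, PO8, P7, P8, P9, P10]
conditions:
  - {name: face_oddball,  base_freq: 6, oddball_freq: 1, sequence_s: 60, ramp_s: 5, steady_samples: 14337, anchor: onset}
  - {name: house_oddball, base_freq: 6, oddball_freq: 1, sequence_s: 60, ramp_s: 5, steady_samples: 14337, anchor: onset}
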