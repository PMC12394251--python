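#!/usr/bin/env python
"""Preprocess every simulated trial to its steady-state segment.

Reads the BDFs from scratch/sim/raw/, applies the full chain (downsample
1024->256 Hz, 50/100 Hz notch, 0.05-100 Hz band-pass, ocular regression,
common average reference, steady-state trim) and stores each segment under
scratch/sim/segments/.
"""

import sys
import time
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import N_TRIALS, SUBJECTS, config, segment_path, trial_path

from fpvs.io import read_bdf
from fpvs.preprocessing import preprocess


def main() -> None:
    cfg = config()
    t0 = time.time()
    n_done = 0
    for group, subject in SUBJECTS:
        for cond in cfg.conditions:
            for trial in range(N_TRIALS):
                rec = read_bdf(trial_path(subject, cond.name, trial))
                seg = preprocess(rec, cond, subject=subject, group=group)
                out = segment_path(subject, cond.name, trial)
                out.parent.mkdir(parents=True, exist_ok=True)
                np.savez_compressed(
                    out,
                    data=seg.data.astype(np.float32),
                    fs=seg.fs,
                    labels=np.array(seg.channel_labels),
                    roles=np.array(seg.channel_roles),
                    condition=cond.name,
                    subject=subject,
                    group=group,
                )
                n_done += 1
    print(f"preprocessed {n_done} trials "
          f"({seg.data.shape[1]} samples at {seg.fs:g} Hz each) "
          f"in {time.time() - t0:.0f} s")


if __name__ == "__main__":
    main()
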