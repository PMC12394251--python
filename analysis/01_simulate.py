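#!/usr/bin/env python
"""Simulate the demonstration cohort and write raw recordings as BDF.

Writes one 24-bit BDF per trial under scratch/sim/raw/ plus a JSON
ground-truth sidecar per subject under results/, and verifies one
write/read round trip against the in-memory recording.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import (
    MASTER_SEED,
    N_TRIALS,
    RESULTS,
    SCRATCH,
    SUBJECTS,
    config,
    subject_truths,
    trial_path,
)

from fpvs.io import read_bdf, write_bdf
from fpvs.simulate import simulate_trial


def main() -> None:
    cfg = config()
    rng = np.random.default_rng(MASTER_SEED)
    RESULTS.mkdir(parents=True, exist_ok=True)
    truth_record = {}

    n_written = 0
    for s_idx, (group, subject) in enumerate(SUBJECTS):
        truths = subject_truths(s_idx, rng)
        truth_record[subject] = {
            "group": group,
            "conditions": {name: t.to_dict() for name, t in truths.items()},
        }
        for cond in cfg.conditions:
            for trial in range(N_TRIALS):
                seed = int(rng.integers(2**31))
                rec = simulate_trial(cond, truths[cond.name], seed=seed)
                path = trial_path(subject, cond.name, trial)
                path.parent.mkdir(parents=True, exist_ok=True)
                write_bdf(rec, path)
                n_written += 1
                if n_written == 1:
                    back = read_bdf(path)
                    err = np.abs(back.data - rec.data).max()
                    assert err < 5e-4, f"BDF round trip error {err} uV"
                    print(f"BDF round trip check: max error {err:.2e} uV")

    full_truth = SCRATCH / "ground_truth.json"
    full_truth.parent.mkdir(parents=True, exist_ok=True)
    full_truth.write_text(json.dumps(truth_record, indent=2))

    # compact summary (totals only) kept alongside the result tables
    summary = {
        subject: {
            "group": rec["group"],
            "conditions": {
                name: {
                    "total_base_amp_uv": round(sum(t["base_amps"]), 4),
                    "total_oddball_amp_uv": round(sum(t["oddball_amps"]), 4),
                    "noise_scale_uv": t["noise_scale"],
                    "seed": t["seed"],
                }
                for name, t in rec["conditions"].items()
            },
        }
        for subject, rec in truth_record.items()
    }
    summary_file = RESULTS / "simulation_truth_summary.json"
    summary_file.write_text(json.dumps(summary, indent=2))
    print(f"wrote {n_written} trials for {len(SUBJECTS)} subjects "
          f"({len(cfg.conditions)} conditions x {N_TRIALS} trials)")
    print(f"full ground truth -> {full_truth}")
    print(f"summary -> {summary_file}")


if __name__ == "__main__":
    main()
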