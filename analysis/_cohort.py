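"""Shared cohort definition for the demonstration analysis.

A reduced identity-discrimination cohort: 3 controls and 3 super-recognizer
(SR) subjects, 2 trials per condition, all four presentation rates.  Injected
structure mirrors the qualitative group-level picture the analysis is built
to detect: the base response falls with presentation rate and reaches a
floor by 9 Hz, the oddball response is identical across rates and groups.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from fpvs import default_config
from fpvs.simulate import default_ground_truth

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

EXPERIMENT = 1
N_TRIALS = 2
SUBJECTS = [("control", f"ctl{i}") for i in range(3)] + [
    ("sr", f"sr{i}") for i in range(3)
]

#: Fundamental base amplitude (uV) per presentation rate: decreasing with
#: rate, floor from 9 Hz on.
BASE_AMP_BY_RATE = {3.0: 1.4, 6.0: 1.0, 9.0: 0.8, 12.0: 0.78}
ODDBALL_AMP = 0.5

MASTER_SEED = 20260930


def config():
    return default_config(EXPERIMENT)


def subject_truths(subject_index: int, rng: np.random.Generator):
    """Per-condition ground truths for one subject.

    Subjects share the condition structure but differ by a multiplicative
    responsiveness factor and their own noise realisations.
    """
    gain = float(np.clip(rng.normal(1.0, 0.15), 0.6, 1.4))
    truths = {}
    for cond in config().conditions:
        truths[cond.name] = default_ground_truth(
            cond,
            seed=int(rng.integers(2**31)),
            base_amp=gain * BASE_AMP_BY_RATE[cond.base_freq],
            oddball_amp=gain * ODDBALL_AMP,
            noise_scale=10.0,
            white_scale=1.0,
            line_amp=2.0,
            blink_rate=6.0,
        )
    return truths


def trial_path(subject: str, condition: str, trial: int) -> Path:
    return SCRATCH / "raw" / f"{subject}_{condition}_t{trial}.bdf"


def segment_path(subject: str, condition: str, trial: int) -> Path:
    return SCRATCH / "segments" / f"{subject}_{condition}_t{trial}.npz"


def load_segment(path: Path):
    """Load a preprocessed steady-state segment saved by 02_preprocess."""
    from fpvs.preprocessing import TrialSegment

    with np.load(path) as z:
        return TrialSegment(
            data=z["data"].astype(float),
            fs=float(z["fs"]),
            channel_labels=[str(x) for x in z["labels"]],
            channel_roles=[str(x) for x in z["roles"]],
            condition=str(z["condition"]),
            subject=str(z["subject"]),
            group=str(z["group"]),
        )
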