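"""Experiment configuration: stimulation parameters for each design.

Three frequency-tagging designs are bundled as packaged YAML defaults:

1. Identity discrimination — faces at 3/6/9/12 Hz, identity oddball at 1 Hz,
   60 s sequences, 2 s contrast ramps.
2. Category selectivity — objects at 6 Hz, face vs. house oddball at 1 Hz,
   60 s sequences, 5 s ramps.
3. Duty cycle — 10 Hz/100%, 10 Hz/50%, 20 Hz/100% presentation, face oddball
   at 1 Hz, 90 s sequences, 3 s ramps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .montage import DEFAULT_ROI, SCALP_64

FS_PROCESSED = 256.0

#: Where the retained steady-state window starts relative to the trial-onset
#: event: at the end of the contrast ramp-up, or at onset itself.
ANCHORS = ("ramp_end", "onset")


@dataclass(frozen=True)
class ConditionSpec:
    """One stimulation condition of a frequency-tagging experiment."""

    name: str
    base_freq: float          # image-presentation rate, Hz
    oddball_freq: float       # embedded-deviant rate, Hz
    sequence_s: float         # full stimulation sequence duration, s
    ramp_s: float             # linear contrast ramp at both ends, s
    steady_samples: int       # samples retained for analysis at 256 Hz
    duty_cycle: float = 1.0   # fraction of the cycle the image is on screen
    anchor: str = "onset"

    def __post_init__(self) -> None:
        if self.base_freq <= 0 or self.oddball_freq <= 0:
            raise ValueError("rates must be positive")
        if self.base_freq <= self.oddball_freq:
            raise ValueError("base_freq must exceed oddball_freq")
        ratio = self.base_freq / self.oddball_freq
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"base_freq {self.base_freq} is not an integer multiple of "
                f"oddball_freq {self.oddball_freq}"
            )
        if self.duty_cycle not in (0.5, 1.0):
            raise ValueError("duty_cycle must be 0.5 or 1.0")
        if self.anchor not in ANCHORS:
            raise ValueError(f"anchor must be one of {ANCHORS}")
        if self.steady_samples <= 0:
            raise ValueError("steady_samples must be positive")
        if self.steady_samples > self.sequence_s * FS_PROCESSED + 1:
            raise ValueError(
                f"steady_samples {self.steady_samples} exceeds the sequence "
                f"({self.sequence_s} s at {FS_PROCESSED:g} Hz)"
            )

    @property
    def cycles_per_second(self) -> int:
        return round(self.base_freq / self.oddball_freq)


@dataclass(frozen=True)
class ExperimentConfig:
    experiment_id: int
    conditions: tuple[ConditionSpec, ...]
    fs_raw: float = 1024.0
    n_trials_per_condition: int = 4
    roi: tuple[str, ...] = DEFAULT_ROI

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        unknown = set(self.roi) - set(SCALP_64)
        if unknown:
            raise ValueError(f"ROI labels not in the scalp montage: {sorted(unknown)}")
        if self.fs_raw <= 0 or self.fs_raw % FS_PROCESSED:
            raise ValueError("fs_raw must be a positive multiple of 256 Hz")

    def condition(self, name: str) -> ConditionSpec:
        for cond in self.conditions:
            if cond.name == name:
                return cond
        raise KeyError(f"no condition named {name!r}")


_REQUIRED_KEYS = {"experiment_id", "conditions"}
_REQUIRED_COND_KEYS = {
    "name", "base_freq", "oddball_freq", "sequence_s", "ramp_s", "steady_samples",
}


def _config_from_mapping(doc: dict) -> ExperimentConfig:
    missing = _REQUIRED_KEYS - doc.keys()
    if missing:
        raise ValueError(f"config missing keys: {sorted(missing)}")
    conditions = []
    for raw in doc["conditions"]:
        missing = _REQUIRED_COND_KEYS - raw.keys()
        if missing:
            raise ValueError(f"condition missing keys: {sorted(missing)}")
        conditions.append(ConditionSpec(**raw))
    kwargs = {}
    for key in ("fs_raw", "n_trials_per_condition"):
        if key in doc:
            kwargs[key] = doc[key]
    if "roi" in doc:
        kwargs["roi"] = tuple(doc["roi"])
    return ExperimentConfig(
        experiment_id=int(doc["experiment_id"]),
        conditions=tuple(conditions),
        **kwargs,
    )


def load_config(path: str | os.PathLike) -> ExperimentConfig:
    """Load and validate an experiment configuration from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    return _config_from_mapping(doc)


def save_config(config: ExperimentConfig, path: str | os.PathLike) -> None:
    doc = {
        "experiment_id": config.experiment_id,
        "fs_raw": config.fs_raw,
        "n_trials_per_condition": config.n_trials_per_condition,
        "roi": list(config.roi),
        "conditions": [
            {
                "name": c.name,
                "base_freq": c.base_freq,
                "oddball_freq": c.oddball_freq,
                "sequence_s": c.sequence_s,
                "ramp_s": c.ramp_s,
                "steady_samples": c.steady_samples,
                "duty_cycle": c.duty_cycle,
                "anchor": c.anchor,
            }
            for c in config.conditions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_config(experiment_id: int) -> ExperimentConfig:
    """The packaged default configuration for experiment 1, 2 or 3."""
    if experiment_id not in (1, 2, 3):
        raise ValueError("experiment_id must be 1, 2 or 3")
    ref = resources.files("fpvs") / "configs" / f"experiment{experiment_id}.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)
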