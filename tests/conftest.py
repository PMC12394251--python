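"""Shared fixtures: small recordings, oracle helpers, simulated group tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fpvs.config import ConditionSpec
from fpvs.montage import OCULAR_4, SCALP_64
from fpvs.recording import OCULAR, SCALP, Recording

ALL_LABELS = list(SCALP_64) + list(OCULAR_4)
ALL_ROLES = [SCALP] * 64 + [OCULAR] * 4


def make_recording(
    data: np.ndarray,
    fs: float = 1024.0,
    events: list[tuple[int, int]] | None = None,
) -> Recording:
    """Wrap a 68 x n matrix in a Recording with the default montage."""
    return Recording(
        data=data,
        fs=fs,
        channel_labels=list(ALL_LABELS),
        channel_roles=list(ALL_ROLES),
        events=events or [],
    )


def zeros_recording(n_seconds: float = 4.0, fs: float = 1024.0) -> Recording:
    return make_recording(np.zeros((68, round(n_seconds * fs))), fs=fs)


@pytest.fixture
def short_condition() -> ConditionSpec:
    """A compact stimulation condition for fast preprocessing tests."""
    return ConditionSpec(
        name="short6",
        base_freq=6.0,
        oddball_freq=1.0,
        sequence_s=8.0,
        ramp_s=1.0,
        steady_samples=1537,
        anchor="ramp_end",
    )


def brute_force_baseline(amps: np.ndarray) -> np.ndarray:
    """Independent re-implementation of neighbour-bin baseline subtraction.

    Plain per-bin loops over offsets +-2..+-11 with edge truncation; kept
    deliberately naive so it shares no code with the vectorised path.
    """
    amps = np.atleast_2d(amps)
    n = amps.shape[1]
    out = np.empty_like(amps)
    for ch in range(amps.shape[0]):
        for i in range(n):
            window = []
            for off in range(-11, 12):
                if abs(off) < 2:
                    continue
                j = i + off
                if 0 <= j < n:
                    window.append(amps[ch, j])
            out[ch, i] = amps[ch, i] - np.mean(window)
    return out


def brute_force_harmonic_bins(
    df: float, base: float, oddball: float = 1.0, fmax: float = 48.0
) -> tuple[set[int], set[int]]:
    """Exhaustive enumeration oracle for harmonic bin sets."""
    base_centers = []
    f = base
    while f <= fmax + 1e-9:
        base_centers.append(round(f / df))
        f += base
    odd_centers = []
    f = oddball
    while f <= fmax + 1e-9:
        if not np.isclose(f / base, round(f / base)):
            odd_centers.append(round(f / df))
        f += oddball
    base_bins = {b for c in base_centers for b in (c - 1, c, c + 1) if b >= 0}
    odd_bins = {
        b
        for c in odd_centers
        if c not in base_centers
        for b in (c - 1, c, c + 1)
        if b >= 0
    } - base_bins
    return base_bins, odd_bins


def simulate_group_table(
    rng: np.random.Generator,
    n_ctrl: int = 8,
    n_sr: int = 7,
    n_cond: int = 4,
    cond_effect: float = 0.0,
    group_effect: float = 0.0,
    subject_sd: float = 1.0,
    resid_sd: float = 1.0,
) -> pd.DataFrame:
    """Mixed-design table with known group/condition effects for BF checks."""
    rows = []
    cond_means = cond_effect * np.arange(n_cond)
    for group, n in (("control", n_ctrl), ("sr", n_sr)):
        for s in range(n):
            subject = f"{group}{s}"
            intercept = rng.normal(0.0, subject_sd)
            shift = group_effect if group == "sr" else 0.0
            for ci in range(n_cond):
                rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "condition": f"c{ci}",
                        "dv": intercept + cond_means[ci] + shift
                        + rng.normal(0.0, resid_sd),
                    }
                )
    return pd.DataFrame(rows)
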