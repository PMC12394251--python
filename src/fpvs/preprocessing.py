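"""Preprocessing chain from a raw recording to steady-state segments.

Order of operations (applied by :func:`preprocess`): interpolate listed
noisy channels -> downsample 1024 to 256 Hz -> notch the 50 Hz line and its
first two harmonics -> 0.05-100 Hz fourth-order Butterworth band-pass ->
regression-based ocular correction from the four EOG electrodes -> common
average reference over the 64 scalp channels -> trim to the steady-state
stimulation window.  All filters are applied forward-backward (zero phase),
so the effective magnitude response is the square of the single-pass
response; amplitude analyses are insensitive to the resulting sharper
roll-off because every quantified harmonic sits well inside the passband.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import ConditionSpec
from .montage import OCULAR_4, nearest_neighbors
from .recording import SCALP, Recording

logger = logging.getLogger(__name__)


@dataclass
class TrialSegment:
    """Steady-state window of one trial: channels x samples at 256 Hz."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]
    condition: str = ""
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))


@dataclass
class EpochSet:
    """Non-overlapping one-second epochs: n_epochs x channels x 256 samples."""

    epochs: np.ndarray
    labels: list[str]
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x channels x samples")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("one label per epoch required")


def interpolate_channel(rec: Recording, label: str) -> Recording:
    """Replace a noisy scalp channel by the mean of its 3 nearest neighbours."""
    idx = rec.index(label)
    if rec.channel_roles[idx] != SCALP:
        raise ValueError(f"{label!r} is not a scalp channel")
    neighbors = nearest_neighbors(label, k=3)
    data = rec.data.copy()
    data[idx] = np.mean([rec.data[rec.index(n)] for n in neighbors], axis=0)
    return rec.with_data(data)


def downsample(rec: Recording, factor: int = 4) -> Recording:
    """Anti-alias low-pass then decimate by ``factor``.

    The guard filter is an 8th-order Butterworth at 0.8x the new Nyquist
    (102.4 Hz for 1024 -> 256 Hz), zero-phase, so the 0.05-100 Hz analysis
    band passes essentially untouched while content above the new Nyquist
    is suppressed.  Event indices are divided by ``factor`` (floor).
    """
    if factor < 1 or rec.fs % factor:
        raise ValueError(f"sampling rate {rec.fs} not divisible by {factor}")
    if factor == 1:
        return rec.copy()
    new_fs = rec.fs / factor
    sos = signal.butter(8, 0.8 * (new_fs / 2), btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    events = [(s // factor, code) for s, code in rec.events]
    return rec.with_data(filtered[:, ::factor], fs=new_fs, events=events)


def notch(
    rec: Recording, centers: tuple[float, ...] = (50.0, 100.0, 150.0),
    width: float = 2.0,
) -> Recording:
    """Zero-phase band-stop at each line-noise frequency (2 Hz wide)."""
    nyq = rec.fs / 2
    data = rec.data
    applied = False
    for center in centers:
        if center >= nyq:
            raise ValueError(f"notch center {center} Hz at or above Nyquist {nyq} Hz")
        band = (center - width / 2, center + width / 2)
        sos = signal.butter(2, band, btype="bandstop", fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
        applied = True
    return rec.with_data(data if applied else data.copy())


def bandpass(
    rec: Recording, low: float = 0.05, high: float = 100.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (defaults 0.05-100 Hz, 4th order)."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(
            f"cutoffs must satisfy 0 < {low} < {high} < Nyquist {rec.fs / 2}"
        )
    sos = signal.butter(order, (low, high), btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def eog_correct(rec: Recording) -> Recording:
    """Regression-based ocular artifact removal from the 4 EOG electrodes.

    Bipolar regressors HEOG = HEOG_L - HEOG_R and VEOG = VEOG_U - VEOG_L are
    demeaned; per-scalp-channel propagation coefficients are estimated by
    least squares over the whole recording and the weighted regressors are
    subtracted.  A zero-variance regressor is skipped with a warning.
    """
    missing = [label for label in OCULAR_4 if label not in rec.channel_labels]
    if missing:
        raise ValueError(f"ocular channels missing: {missing}")
    heog = rec.data[rec.index("HEOG_L")] - rec.data[rec.index("HEOG_R")]
    veog = rec.data[rec.index("VEOG_U")] - rec.data[rec.index("VEOG_L")]
    regressors = []
    for name, series in (("HEOG", heog), ("VEOG", veog)):
        centered = series - series.mean()
        if np.allclose(centered, 0):
            logger.warning("EOG regressor %s has zero variance; skipped", name)
            continue
        regressors.append(centered)
    data = rec.data.copy()
    if regressors:
        design = np.column_stack(regressors)
        scalp = rec.scalp_indices
        demeaned = rec.data[scalp] - rec.data[scalp].mean(axis=1, keepdims=True)
        coeffs, *_ = np.linalg.lstsq(design, demeaned.T, rcond=None)
        data[scalp] = rec.data[scalp] - (design @ coeffs).T
    return rec.with_data(data)


def rereference_average(rec: Recording) -> Recording:
    """Common average reference: subtract the scalp mean at every sample.

    Ocular channels are excluded from the reference and left untouched.
    """
    scalp = rec.scalp_indices
    if scalp.size < 2:
        raise ValueError("average reference requires at least 2 scalp channels")
    data = rec.data.copy()
    data[scalp] -= rec.data[scalp].mean(axis=0, keepdims=True)
    return rec.with_data(data)


def segment_trial(
    rec: Recording,
    cond: ConditionSpec,
    *,
    subject: str = "",
    group: str = "",
) -> TrialSegment:
    """Trim the recording to the condition's steady-state window.

    The window starts at the trial-onset event, offset by the contrast ramp
    duration when the condition is anchored at ``ramp_end``, and spans
    exactly ``cond.steady_samples`` samples.
    """
    if not rec.events:
        raise ValueError("no trial-onset event in recording")
    onset = rec.events[0][0]
    anchor = onset
    if cond.anchor == "ramp_end":
        anchor += round(cond.ramp_s * rec.fs)
    end = anchor + cond.steady_samples
    if end > rec.n_samples:
        raise ValueError(
            f"recording too short: needs {end} samples from onset, "
            f"has {rec.n_samples} (deficit {end - rec.n_samples})"
        )
    return TrialSegment(
        data=rec.data[:, anchor:end].copy(),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        channel_roles=list(rec.channel_roles),
        condition=cond.name,
        subject=subject,
        group=group,
    )


def segment_epochs(seg: TrialSegment) -> EpochSet:
    """Cut a steady-state segment into consecutive 1 s (256-sample) epochs.

    The trailing remainder shorter than one second is discarded.
    """
    epoch_len = round(seg.fs)
    n_samples = seg.data.shape[1]
    if n_samples < epoch_len:
        raise ValueError(f"segment shorter than one epoch ({n_samples} samples)")
    n_epochs = n_samples // epoch_len
    usable = seg.data[:, : n_epochs * epoch_len]
    epochs = usable.reshape(seg.data.shape[0], n_epochs, epoch_len)
    epochs = np.transpose(epochs, (1, 0, 2)).copy()
    return EpochSet(
        epochs=epochs,
        labels=[seg.condition] * n_epochs,
        fs=seg.fs,
        channel_labels=list(seg.channel_labels),
        channel_roles=list(seg.channel_roles),
        subject=seg.subject,
        group=seg.group,
    )


def preprocess(
    rec: Recording,
    cond: ConditionSpec,
    *,
    interpolate: tuple[str, ...] = (),
    target_fs: float = 256.0,
    subject: str = "",
    group: str = "",
) -> TrialSegment:
    """The full chain from a raw trial recording to its steady-state segment."""
    for label in interpolate:
        rec = interpolate_channel(rec, label)
    factor = int(round(rec.fs / target_fs))
    rec = downsample(rec, factor)
    # At 256 Hz the 150 Hz line harmonic is above Nyquist (and cannot alias
    # in: the anti-alias filter removed it); only representable centers are
    # notched.
    centers = tuple(c for c in (50.0, 100.0, 150.0) if c < rec.fs / 2)
    rec = notch(rec, centers=centers)
    rec = bandpass(rec)
    rec = eog_correct(rec)
    rec = rereference_average(rec)
    return segment_trial(rec, cond, subject=subject, group=group)
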