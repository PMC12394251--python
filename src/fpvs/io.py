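"""Reading and writing recordings (BioSemi BDF) and long-format result tables.

Reading goes through MNE's BDF reader.  Writing is a minimal 24-bit BDF
writer (one-second data records, a trigger ``Status`` channel carrying event
codes) — sufficient for round-tripping synthetic recordings and for feeding
any BDF-aware toolchain.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import OCULAR_4
from .recording import OCULAR, SCALP, Recording

# Fixed physical range of the writer, in microvolts.  24-bit resolution over
# this range is ~0.0004 uV per digital step, far below EEG noise.
_PHYS_MIN = -3276.8
_PHYS_MAX = 3276.8
_DIG_MIN = -8388608
_DIG_MAX = 8388607
_STATUS = "Status"
# Trigger pulses are held this many samples so edge detection cannot miss them.
_PULSE_SAMPLES = 8


def _role_for(label: str) -> str:
    return OCULAR if label in OCULAR_4 else SCALP


def write_bdf(rec: Recording, path: str | os.PathLike) -> None:
    """Write ``rec`` as a 24-bit BioSemi BDF file with a Status channel.

    The recording length must be an integer number of seconds (one-second
    data records).  Amplitudes outside +-3276.8 uV are clipped.
    """
    fs = int(rec.fs)
    if fs != rec.fs:
        raise ValueError("BDF writer requires an integer sampling rate")
    if rec.n_samples % fs != 0:
        raise ValueError(
            f"recording length ({rec.n_samples} samples) must be a whole "
            f"number of seconds at {fs} Hz"
        )
    n_rec = rec.n_samples // fs
    status = np.zeros(rec.n_samples, dtype=np.int64)
    for sample, code in rec.events:
        if not 1 <= code <= 0xFFFF:
            raise ValueError(f"event code {code} outside 1..65535")
        status[sample : sample + _PULSE_SAMPLES] = code

    channels = list(rec.channel_labels) + [_STATUS]
    n_ch = len(channels)

    def field(values: list[str], width: int) -> bytes:
        out = b""
        for v in values:
            enc = str(v).encode("ascii")
            if len(enc) > width:
                raise ValueError(f"header field {v!r} exceeds {width} bytes")
            out += enc.ljust(width)
        return out

    header = bytearray()
    header += b"\xffBIOSEMI"
    header += b" " * 80 + b" " * 80          # subject / recording id
    header += b"01.01.00" + b"00.00.00"      # date / time (unused)
    header += field([str((n_ch + 1) * 256)], 8)
    header += b"24BIT".ljust(44)
    header += field([str(n_rec)], 8)
    header += field(["1"], 8)                # record duration, seconds
    header += field([str(n_ch)], 4)
    header += field(channels, 16)
    header += field([""] * n_ch, 80)         # transducer
    header += field(["uV"] * (n_ch - 1) + [""], 8)
    header += field([f"{_PHYS_MIN:g}"] * (n_ch - 1) + [str(_DIG_MIN)], 8)
    header += field([f"{_PHYS_MAX:g}"] * (n_ch - 1) + [str(_DIG_MAX)], 8)
    header += field([str(_DIG_MIN)] * n_ch, 8)
    header += field([str(_DIG_MAX)] * n_ch, 8)
    header += field([""] * n_ch, 80)         # prefiltering
    header += field([str(fs)] * n_ch, 8)     # samples per record
    header += field([""] * n_ch, 32)
    assert len(header) == (n_ch + 1) * 256

    scale = (_PHYS_MAX - _PHYS_MIN) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.data - _PHYS_MIN) / scale + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype(np.int64)
    all_ch = np.vstack([digital, status[None, :]])

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = all_ch[:, r * fs : (r + 1) * fs].astype("<i4")
            as_bytes = np.frombuffer(block.tobytes(), dtype=np.uint8)
            fh.write(as_bytes.reshape(n_ch, fs, 4)[:, :, :3].tobytes())


def read_bdf(path: str | os.PathLike) -> Recording:
    """Read a 24-bit BDF file into a :class:`Recording` (amplitudes in uV).

    Channel roles are assigned by label: the four ocular labels become
    ``ocular``, everything else ``scalp``.  Events are decoded from the
    ``Status`` trigger channel when present.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such BDF file: {path}")
    try:
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    except Exception as exc:  # malformed header or truncated records
        raise ValueError(f"not a readable BDF file ({path.name}): {exc}") from exc

    labels = [name for name in raw.ch_names if name != _STATUS]
    data = raw.get_data(picks=labels) * 1e6  # volts -> microvolts

    events: list[tuple[int, int]] = []
    if _STATUS in raw.ch_names:
        found = mne.find_events(
            raw, stim_channel=_STATUS, shortest_event=1, verbose="error"
        )
        events = [(int(sample), int(code)) for sample, _, code in found]

    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        channel_roles=[_role_for(label) for label in labels],
        events=events,
    )


def write_table(records, path: str | os.PathLike) -> None:
    """Write a long-format result table as tab-separated text with a header.

    ``records`` may be a DataFrame or anything ``pd.DataFrame`` accepts
    (list of dicts, list of tuples with named columns, ...).  Finite values
    round-trip losslessly through :func:`read_table`.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    return pd.read_csv(path, sep="\t")
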