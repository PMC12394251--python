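"""In-memory container for a multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SCALP = "scalp"
OCULAR = "ocular"


@dataclass
class Recording:
    """Channels x samples amplitude matrix with channel metadata and events.

    Amplitudes are microvolts throughout.  Events are ``(sample_index, code)``
    pairs with 0-based sample indices; by convention the first event of a
    trial marks the first stimulation frame (start of the contrast ramp-up).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch or len(self.channel_roles) != n_ch:
            raise ValueError("labels/roles length must match channel count")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        bad = set(self.channel_roles) - {SCALP, OCULAR}
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")
        for sample, _ in self.events:
            if not 0 <= sample < self.n_samples:
                raise ValueError(f"event sample {sample} outside [0, {self.n_samples})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def indices_by_role(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.channel_roles) if r == role], dtype=int
        )

    @property
    def scalp_indices(self) -> np.ndarray:
        return self.indices_by_role(SCALP)

    @property
    def ocular_indices(self) -> np.ndarray:
        return self.indices_by_role(OCULAR)

    def with_data(self, data: np.ndarray, *, fs: float | None = None,
                  events: list[tuple[int, int]] | None = None) -> "Recording":
        """Copy of this recording with ``data`` (and optionally fs/events) swapped."""
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            fs=self.fs if fs is None else fs,
            channel_labels=list(self.channel_labels),
            channel_roles=list(self.channel_roles),
            events=list(self.events) if events is None else events,
        )

    def copy(self) -> "Recording":
        return self.with_data(self.data.copy())
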