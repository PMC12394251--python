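"""Electrode montage: the 64-channel 10-20 extended scalp layout plus oculars.

The scalp labels follow the conventional 64-electrode extended 10-20 set used
by BioSemi caps when relabelled to 10-20 names.  Three-dimensional positions
come from MNE's built-in idealized-head montage and are used only for
relative (nearest-neighbour) geometry, so the head-model scale is irrelevant.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np

#: Scalp channels, left hemisphere front-to-back, midline, then right.
SCALP_64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: Ocular channels: horizontal pair at the canthi, vertical pair around the
#: right eye (upper = frontal bone, lower = maxilla).
OCULAR_4: tuple[str, ...] = ("HEOG_L", "HEOG_R", "VEOG_U", "VEOG_L")

#: Bilateral parieto-occipital region of interest used to summarise
#: face-selective periodic responses.
DEFAULT_ROI: tuple[str, ...] = ("PO7", "PO8", "P7", "P8", "P9", "P10")


@functools.lru_cache(maxsize=1)
def scalp_positions() -> dict[str, np.ndarray]:
    """3-D positions (meters, head frame) for every label in ``SCALP_64``."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    return {label: np.asarray(pos[label], dtype=float) for label in SCALP_64}


def nearest_neighbors(label: str, k: int = 3) -> list[str]:
    """The ``k`` scalp channels closest to ``label`` by Euclidean distance."""
    if label not in SCALP_64:
        raise ValueError(f"{label!r} is not a scalp channel")
    pos = scalp_positions()
    origin = pos[label]
    others = [name for name in SCALP_64 if name != label]
    dists = np.array([np.linalg.norm(pos[name] - origin) for name in others])
    order = np.argsort(dists, kind="stable")[:k]
    return [others[i] for i in order]
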