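"""Synthetic frequency-tagged EEG with known injected harmonic structure.

A simulated trial contains, on the 64 scalp channels, a sum of sinusoids at
the base-rate harmonics and at the oddball-rate harmonics (each with its own
posterior-weighted scalp topography), multiplied by the linear contrast-ramp
envelope of the stimulation sequence; on top of that, 1/f^alpha background
noise, broadband white noise, 50 Hz line noise on every channel, and
stereotyped blink transients mixed into the vertical EOG and, with
per-channel propagation fractions, into the (mostly frontal) scalp.  The
injected parameters are the ground truth against which every later stage of
the pipeline can be checked by parameter recovery.

Defaults express a realistic regime: ~1 uV stimulus-locked components
against ~10 uV of pink background noise (per-bin SNR well below 1 before
trial averaging and harmonic summation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .config import ConditionSpec
from .montage import OCULAR_4, SCALP_64, scalp_positions
from .recording import OCULAR, SCALP, Recording
from .spectral import harmonic_frequencies

TRIAL_ONSET_CODE = 1
#: Width of the stereotyped blink kernel, seconds.
BLINK_WIDTH_S = 0.3


@dataclass
class SimulationGroundTruth:
    """Injected signal, noise and artifact parameters for one trial."""

    base_amps: np.ndarray          # uV per base harmonic k*f_b <= 48 Hz
    oddball_amps: np.ndarray       # uV per oddball harmonic (base excluded)
    base_topo: np.ndarray          # per-scalp-channel weight in [0, 1]
    oddball_topo: np.ndarray
    blink_propagation: np.ndarray  # per-scalp-channel fraction of the VEOG deflection
    noise_alpha: float = 1.0
    noise_scale: float = 10.0      # uV, std of the pink background
    white_scale: float = 1.0       # uV
    line_amp: float = 2.0          # uV at 50 Hz
    blink_rate: float = 6.0        # events per minute
    blink_amp: float = 100.0       # uV peak on the vertical EOG
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_amps", "oddball_amps", "base_topo", "oddball_topo",
                     "blink_propagation"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.base_amps < 0) or np.any(self.oddball_amps < 0):
            raise ValueError("harmonic amplitudes must be non-negative")
        for name in ("base_topo", "oddball_topo"):
            topo = getattr(self, name)
            if topo.shape != (len(SCALP_64),):
                raise ValueError(f"{name} must have one weight per scalp channel")
            if np.any(topo < 0) or np.any(topo > 1):
                raise ValueError(f"{name} weights must lie in [0, 1]")
        if self.blink_propagation.shape != (len(SCALP_64),):
            raise ValueError("blink_propagation must have one entry per scalp channel")
        for name in ("noise_scale", "white_scale", "line_amp", "blink_rate",
                     "blink_amp", "noise_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        out = {}
        for name, value in self.__dict__.items():
            out[name] = value.tolist() if isinstance(value, np.ndarray) else value
        return out

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "SimulationGroundTruth":
        return cls(**doc)

    @property
    def total_oddball_amplitude(self) -> float:
        return float(self.oddball_amps.sum())

    @property
    def total_base_amplitude(self) -> float:
        return float(self.base_amps.sum())


def _gaussian_topo(centers: list[str], width: float = 0.07) -> np.ndarray:
    """Scalp weight map: max of Gaussians around the given electrodes."""
    pos = scalp_positions()
    points = np.array([pos[label] for label in SCALP_64])
    weight = np.zeros(len(SCALP_64))
    for center in centers:
        d = np.linalg.norm(points - pos[center], axis=1)
        weight = np.maximum(weight, np.exp(-(d ** 2) / (2 * width ** 2)))
    return np.clip(weight, 0.0, 1.0)


def frontal_gradient(max_fraction: float = 0.4) -> np.ndarray:
    """Blink propagation fractions: strongest frontally, fading posteriorly."""
    pos = scalp_positions()
    y = np.array([pos[label][1] for label in SCALP_64])
    frac = (y - y.min()) / (y.max() - y.min())
    return max_fraction * frac ** 2


def geometric_profile(amp1: float, n: int, decay: float = 0.7) -> np.ndarray:
    """Decaying harmonic series amp_k = amp1 * decay^(k-1), typical of SSVEPs."""
    return amp1 * decay ** np.arange(n)


def default_ground_truth(
    cond: ConditionSpec,
    seed: int = 0,
    *,
    base_amp: float = 1.0,
    oddball_amp: float = 0.5,
    decay: float = 0.7,
    noise_scale: float = 10.0,
    noise_alpha: float = 1.0,
    white_scale: float = 1.0,
    line_amp: float = 2.0,
    blink_rate: float = 6.0,
    blink_amp: float = 100.0,
    half_duty_attenuation: float = 0.65,
    double_rate_attenuation: float = 0.45,
    double_rate_oddball_attenuation: float = 0.6,
) -> SimulationGroundTruth:
    """Plausible ground truth for a condition.

    ``base_amp``/``oddball_amp`` are the fundamental amplitudes of geometric
    harmonic series.  The duty-cycle design's empirical effects are emulated
    by attenuation factors: halving the duty cycle attenuates the base
    response, doubling the presentation rate attenuates base further and the
    oddball response as well.  Topographies: base response medial-occipital,
    oddball response bilateral occipito-temporal.
    """
    base_f, oddball_f = harmonic_frequencies(cond.base_freq, cond.oddball_freq)
    base_scale, oddball_scale = 1.0, 1.0
    if cond.duty_cycle == 0.5:
        base_scale *= half_duty_attenuation
    if cond.base_freq >= 20:
        base_scale *= double_rate_attenuation
        oddball_scale *= double_rate_oddball_attenuation
    return SimulationGroundTruth(
        base_amps=geometric_profile(base_amp * base_scale, len(base_f), decay),
        oddball_amps=geometric_profile(oddball_amp * oddball_scale, len(oddball_f), decay),
        base_topo=_gaussian_topo(["Oz", "POz"]),
        oddball_topo=_gaussian_topo(["PO7", "PO8"]),
        blink_propagation=frontal_gradient(),
        noise_alpha=noise_alpha,
        noise_scale=noise_scale,
        white_scale=white_scale,
        line_amp=line_amp,
        blink_rate=blink_rate,
        blink_amp=blink_amp,
        seed=seed,
    )


def pink_noise(n: int, alpha: float, scale: float, seed: int | np.random.Generator) -> np.ndarray:
    """Zero-mean noise with power spectral density proportional to 1/f^alpha.

    Gaussian white noise is shaped in the frequency domain by f^(-alpha/2)
    (DC removed) and rescaled so the sample standard deviation equals
    ``scale`` exactly.  ``alpha = 0`` reduces to white noise.
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _pink_matrix(rng, 1, n, alpha, scale)[0]


def _pink_matrix(
    rng: np.random.Generator, n_ch: int, n: int, alpha: float, scale: float
) -> np.ndarray:
    white = rng.standard_normal((n_ch, n))
    if scale == 0:
        return np.zeros((n_ch, n))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** (-alpha / 2)
    series = np.fft.irfft(spectrum * weights, n=n, axis=1)
    series -= series.mean(axis=1, keepdims=True)
    std = series.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return scale * series / std


def _blink_kernel(fs: float) -> np.ndarray:
    """Stereotyped biphasic blink, ~300 ms wide, positive peak 1."""
    t = np.arange(round(BLINK_WIDTH_S * fs)) / fs
    up_end = 0.6 * BLINK_WIDTH_S
    kernel = np.where(
        t < up_end,
        np.sin(np.pi * t / up_end),
        -0.3 * np.sin(np.pi * (t - up_end) / (BLINK_WIDTH_S - up_end)),
    )
    return kernel


def blink_train(
    duration_s: float,
    rate: float,
    amp: float,
    seed: int | np.random.Generator,
    fs: float = 1024.0,
) -> np.ndarray:
    """Sum of stereotyped blink transients at Poisson-distributed onsets.

    The expected event count is ``rate * duration_s / 60``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = round(duration_s * fs)
    series = np.zeros(n)
    if rate == 0 or amp == 0:
        return series
    count = rng.poisson(rate * duration_s / 60.0)
    kernel = amp * _blink_kernel(fs)
    max_onset = max(n - len(kernel), 1)
    for onset in rng.integers(0, max_onset, size=count):
        end = min(onset + len(kernel), n)
        series[onset:end] += kernel[: end - onset]
    return series


def simulate_trial(
    cond: ConditionSpec,
    truth: SimulationGroundTruth,
    fs_raw: float = 1024.0,
    seed: int | None = None,
    *,
    pre_s: float = 2.0,
    post_s: float = 2.0,
) -> Recording:
    """One synthetic trial: pre-margin, ramped stimulation sequence, post-margin.

    The trial-onset event marks the first stimulation frame (start of the
    contrast ramp-up).  The contrast ramp multiplies the injected signal
    only, never the noise.  Identical ``(cond, truth, seed)`` give
    bit-identical output.
    """
    if fs_raw <= 0 or fs_raw % 256:
        raise ValueError("fs_raw must be a positive multiple of 256 Hz")
    base_f, oddball_f = harmonic_frequencies(cond.base_freq, cond.oddball_freq)
    if len(truth.base_amps) != len(base_f):
        raise ValueError(
            f"expected {len(base_f)} base amplitudes, got {len(truth.base_amps)}"
        )
    if len(truth.oddball_amps) != len(oddball_f):
        raise ValueError(
            f"expected {len(oddball_f)} oddball amplitudes, got {len(truth.oddball_amps)}"
        )
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    n_scalp, n_ocular = len(SCALP_64), len(OCULAR_4)
    n_total = round((pre_s + cond.sequence_s + post_s) * fs_raw)
    t = np.arange(n_total) / fs_raw
    onset = round(pre_s * fs_raw)
    seq_end = onset + round(cond.sequence_s * fs_raw)

    # Linear contrast ramp over the first/last ramp_s of the sequence.
    envelope = np.zeros(n_total)
    ramp_n = round(cond.ramp_s * fs_raw)
    envelope[onset:seq_end] = 1.0
    if ramp_n:
        envelope[onset : onset + ramp_n] = np.linspace(0, 1, ramp_n, endpoint=False)
        envelope[seq_end - ramp_n : seq_end] = np.linspace(0, 1, ramp_n, endpoint=False)[::-1]

    phases = rng.uniform(0, 2 * np.pi, size=len(base_f) + len(oddball_f))
    base_wave = np.zeros(n_total)
    for amp, f, phi in zip(truth.base_amps, base_f, phases[: len(base_f)]):
        base_wave += amp * np.sin(2 * np.pi * f * t + phi)
    oddball_wave = np.zeros(n_total)
    for amp, f, phi in zip(truth.oddball_amps, oddball_f, phases[len(base_f):]):
        oddball_wave += amp * np.sin(2 * np.pi * f * t + phi)

    scalp = (
        np.outer(truth.base_topo, base_wave * envelope)
        + np.outer(truth.oddball_topo, oddball_wave * envelope)
    )

    n_ch = n_scalp + n_ocular
    data = np.zeros((n_ch, n_total))
    data[:n_scalp] = scalp
    if truth.noise_scale > 0:
        data += _pink_matrix(rng, n_ch, n_total, truth.noise_alpha, truth.noise_scale)
    if truth.white_scale > 0:
        data += truth.white_scale * rng.standard_normal((n_ch, n_total))
    if truth.line_amp > 0:
        line_phase = rng.uniform(0, 2 * np.pi, size=n_ch)
        data += truth.line_amp * np.sin(
            2 * np.pi * 50.0 * t[None, :] + line_phase[:, None]
        )
    if truth.blink_rate > 0 and truth.blink_amp > 0:
        blinks = blink_train(
            n_total / fs_raw, truth.blink_rate, truth.blink_amp, rng, fs=fs_raw
        )
        veog_u = n_scalp + OCULAR_4.index("VEOG_U")
        data[veog_u] += blinks
        data[:n_scalp] += truth.blink_propagation[:, None] * blinks[None, :]

    return Recording(
        data=data,
        fs=fs_raw,
        channel_labels=list(SCALP_64) + list(OCULAR_4),
        channel_roles=[SCALP] * n_scalp + [OCULAR] * n_ocular,
        events=[(onset, TRIAL_ONSET_CODE)],
    )
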