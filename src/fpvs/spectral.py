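"""Frequency-domain quantification of periodic EEG responses.

A steady-state trial is Fourier-transformed to a one-sided amplitude
spectrum (unit sinusoid -> amplitude 1 at its bin), trial spectra are
averaged per condition *before* baseline correction, each bin is then
baseline-corrected by subtracting the mean of its 20 surrounding noise bins
(offsets +-2..+-11, i.e. excluding the two immediately adjacent bins), and
the stimulus-locked response is quantified as the sum of corrected
amplitudes over harmonic bins:

* base response — bins at integer multiples of the presentation rate up to
  48 Hz, each with its two adjacent bins (the effective stimulation
  frequency can drift by up to one bin width between recording sessions);
* oddball response — bins at integer multiples of the oddball rate up to
  48 Hz, likewise expanded by one adjacent bin, excluding every bin already
  claimed by the base response.

Per-channel sums are averaged over a bilateral parieto-occipital ROI.
One-second epochs get the same treatment at 1 Hz resolution, individually
and without ROI averaging, for per-frequency decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import EpochSet, TrialSegment

FMAX_DEFAULT = 48.0
#: Baseline window: 10 bins on each side, skipping the adjacent bin.
BASELINE_OFFSETS = tuple(o for o in range(-11, 12) if abs(o) >= 2)


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum per channel (uV per frequency bin)."""

    amps: np.ndarray          # channels x bins
    df: float                 # bin spacing, Hz
    n_samples: int            # length of the source segment
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]
    baseline_corrected: bool = False
    condition: str = ""

    def __post_init__(self) -> None:
        self.amps = np.asarray(self.amps, dtype=float)
        expected = self.n_samples // 2 + 1
        if self.amps.shape[1] != expected:
            raise ValueError(
                f"expected {expected} bins for {self.n_samples} samples, "
                f"got {self.amps.shape[1]}"
            )
        if not np.all(np.isfinite(self.amps)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_bins(self) -> int:
        return self.amps.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.df

    def channel(self, label: str) -> np.ndarray:
        return self.amps[self.channel_labels.index(label)]


@dataclass(frozen=True)
class HarmonicSet:
    """Resolved DFT bin indices for the base and oddball responses."""

    base_bins: tuple[int, ...]
    oddball_bins: tuple[int, ...]
    base_centers: tuple[int, ...]
    oddball_centers: tuple[int, ...]
    base_freq: float
    oddball_freq: float
    fmax: float
    df: float

    def __post_init__(self) -> None:
        if set(self.base_bins) & set(self.oddball_bins):
            raise ValueError("base and oddball bin sets must be disjoint")


@dataclass
class HarmonicSummary:
    """Per-channel (and optionally ROI-averaged) harmonic response sums."""

    base_sum: np.ndarray       # uV, per channel
    oddball_sum: np.ndarray
    channel_labels: list[str]
    subject: str = ""
    group: str = ""
    condition: str = ""
    roi_base: float | None = None
    roi_oddball: float | None = None


def amplitude_spectrum(seg: TrialSegment) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of a steady-state segment.

    Normalisation is 2|X_k|/N for interior bins and |X_k|/N at DC (and at
    the Nyquist bin for even N), so a unit sinusoid at an exact bin center
    reads 1 uV.
    """
    if seg.data.size == 0:
        raise ValueError("empty segment")
    n = seg.data.shape[1]
    spec = np.abs(np.fft.rfft(seg.data, axis=1)) / n
    spec[:, 1:] *= 2.0
    if n % 2 == 0:
        spec[:, -1] /= 2.0
    return AmplitudeSpectrum(
        amps=spec,
        df=seg.fs / n,
        n_samples=n,
        fs=seg.fs,
        channel_labels=list(seg.channel_labels),
        channel_roles=list(seg.channel_roles),
        condition=seg.condition,
    )


def average_spectra(spectra: list[AmplitudeSpectrum]) -> AmplitudeSpectrum:
    """Element-wise mean of raw (uncorrected) spectra from one condition.

    Averaging precedes baseline correction by contract: correcting first
    and averaging after is not the same computation on noisy data.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for spec in spectra:
        if spec.baseline_corrected:
            raise ValueError("average_spectra expects uncorrected spectra")
        if spec.n_samples != first.n_samples or spec.df != first.df:
            raise ValueError("spectra have mismatched bin structure")
        if spec.amps.shape != first.amps.shape:
            raise ValueError("spectra have mismatched channel counts")
    mean = np.mean([spec.amps for spec in spectra], axis=0)
    return replace(first, amps=mean,
                   channel_labels=list(first.channel_labels),
                   channel_roles=list(first.channel_roles))


def baseline_correct(spec: AmplitudeSpectrum) -> AmplitudeSpectrum:
    """Subtract from every bin the mean of its 20 surrounding noise bins.

    The window spans offsets +-2..+-11; the two adjacent bins (+-1) are
    excluded because signal can leak into them.  Near the spectrum edges
    the window truncates to the offsets that exist (exclusions preserved).
    Corrected amplitudes may be negative; in pure noise they are zero-mean.
    """
    if spec.baseline_corrected:
        raise ValueError("spectrum is already baseline-corrected")
    if spec.n_bins < 5:
        raise ValueError("too few bins to estimate a noise baseline")
    amps = spec.amps
    n = spec.n_bins
    acc = np.zeros_like(amps)
    count = np.zeros(n)
    for off in BASELINE_OFFSETS:
        lo = max(0, -off)
        hi = min(n, n - off)
        if hi <= lo:  # |offset| >= n_bins: no bin has this neighbour
            continue
        acc[:, lo:hi] += amps[:, lo + off : hi + off]
        count[lo:hi] += 1
    corrected = amps - acc / count
    return replace(spec, amps=corrected, baseline_corrected=True,
                   channel_labels=list(spec.channel_labels),
                   channel_roles=list(spec.channel_roles))


def harmonic_frequencies(
    base_freq: float, oddball_freq: float = 1.0, fmax: float = FMAX_DEFAULT
) -> tuple[list[float], list[float]]:
    """Harmonic frequencies (Hz) of the base and oddball responses.

    Base: k*base_freq <= fmax.  Oddball: m*oddball_freq <= fmax excluding
    frequencies that are also base harmonics.  The cap is inclusive.
    """
    eps = 1e-9
    base = []
    k = 1
    while k * base_freq <= fmax + eps:
        base.append(k * base_freq)
        k += 1
    oddball = []
    m = 1
    while m * oddball_freq <= fmax + eps:
        f = m * oddball_freq
        ratio = f / base_freq
        if abs(ratio - round(ratio)) > eps:
            oddball.append(f)
        m += 1
    return base, oddball


def build_harmonic_set(
    df: float,
    base_freq: float,
    oddball_freq: float = 1.0,
    fmax: float = FMAX_DEFAULT,
    n_bins: int | None = None,
) -> HarmonicSet:
    """Resolve base/oddball harmonics to DFT bin indices at spacing ``df``.

    Each harmonic claims its nearest bin plus the two adjacent bins.  Bins
    claimed by the base response are removed from the oddball set (base
    takes precedence on overlap).
    """
    if df <= 0:
        raise ValueError("df must be positive")
    if base_freq > fmax:
        raise ValueError(f"base_freq {base_freq} exceeds fmax {fmax}")
    base_f, oddball_f = harmonic_frequencies(base_freq, oddball_freq, fmax)

    def centers(freqs: list[float]) -> list[int]:
        return [int(round(f / df)) for f in freqs]

    def expand(cents: list[int]) -> set[int]:
        bins: set[int] = set()
        for c in cents:
            bins.update(b for b in (c - 1, c, c + 1) if b >= 0)
        return bins

    base_centers = centers(base_f)
    oddball_centers = [c for c in centers(oddball_f) if c not in set(base_centers)]
    base_bins = expand(base_centers)
    oddball_bins = expand(oddball_centers) - base_bins
    if n_bins is not None:
        if max(base_bins | oddball_bins) >= n_bins:
            raise ValueError("harmonic bins exceed the available spectrum")
    return HarmonicSet(
        base_bins=tuple(sorted(base_bins)),
        oddball_bins=tuple(sorted(oddball_bins)),
        base_centers=tuple(base_centers),
        oddball_centers=tuple(oddball_centers),
        base_freq=base_freq,
        oddball_freq=oddball_freq,
        fmax=fmax,
        df=df,
    )


def sum_harmonics(
    spec: AmplitudeSpectrum,
    hset: HarmonicSet,
    *,
    subject: str = "",
    group: str = "",
    condition: str = "",
) -> HarmonicSummary:
    """Per-channel base and oddball response sums over corrected amplitudes."""
    if not spec.baseline_corrected:
        raise ValueError("sum_harmonics requires a baseline-corrected spectrum")
    base_idx = np.array(hset.base_bins, dtype=int)
    odd_idx = np.array(hset.oddball_bins, dtype=int)
    if (base_idx.size and base_idx.max() >= spec.n_bins) or (
        odd_idx.size and odd_idx.max() >= spec.n_bins
    ):
        raise ValueError("harmonic set exceeds the spectrum's bin range")
    return HarmonicSummary(
        base_sum=spec.amps[:, base_idx].sum(axis=1),
        oddball_sum=spec.amps[:, odd_idx].sum(axis=1),
        channel_labels=list(spec.channel_labels),
        subject=subject,
        group=group,
        condition=condition,
    )


def roi_average(summary: HarmonicSummary, roi: tuple[str, ...]) -> HarmonicSummary:
    """Fill ``roi_base``/``roi_oddball`` with the mean over the ROI channels."""
    missing = [label for label in roi if label not in summary.channel_labels]
    if missing:
        raise ValueError(f"ROI channels absent from summary: {missing}")
    idx = [summary.channel_labels.index(label) for label in roi]
    return HarmonicSummary(
        base_sum=summary.base_sum,
        oddball_sum=summary.oddball_sum,
        channel_labels=list(summary.channel_labels),
        subject=summary.subject,
        group=summary.group,
        condition=summary.condition,
        roi_base=float(summary.base_sum[idx].mean()),
        roi_oddball=float(summary.oddball_sum[idx].mean()),
    )


def epoch_spectra(epochs: EpochSet) -> list[AmplitudeSpectrum]:
    """Individually baseline-corrected 1 Hz-resolution spectra per epoch.

    Epoch spectra are never averaged: each feeds the per-frequency decoder
    as one observation.
    """
    if epochs.epochs.shape[2] != round(epochs.fs):
        raise ValueError(
            f"epochs must be exactly 1 s ({round(epochs.fs)} samples), "
            f"got {epochs.epochs.shape[2]}"
        )
    out = []
    for i in range(epochs.epochs.shape[0]):
        seg = TrialSegment(
            data=epochs.epochs[i],
            fs=epochs.fs,
            channel_labels=list(epochs.channel_labels),
            channel_roles=list(epochs.channel_roles),
            condition=epochs.labels[i],
        )
        out.append(baseline_correct(amplitude_spectrum(seg)))
    return out
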