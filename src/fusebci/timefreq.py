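"""STFT time-frequency analysis and band-energy traces for ERD profiling.

During unilateral motor imagery the contralateral sensorimotor cortex shows
event-related desynchronization (ERD): a drop of alpha (8-12 Hz) and beta
(12-27 Hz) oscillatory power relative to baseline.  This module computes
short-time Fourier spectrograms, per-band energy traces and task/baseline
power ratios used to characterize ERD and to verify the synthetic
generator's planted contrast.

The STFT is the standard discrete one: frames of length ``n_window`` fully
inside the signal, hop ``hop`` samples, window ``w``, one-sided
magnitude-squared coefficients scaled so that with a rectangular window and
non-overlapping frames the total spectrogram power equals the total signal
energy (Parseval-consistent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import TrialSet

__all__ = [
    "STFTSpec",
    "Spectrogram",
    "BANDS",
    "stft",
    "band_energy",
    "trial_averaged_spectrogram",
    "band_power_ratio",
]

#: Canonical EEG frequency bands (Hz).  Alpha and beta as used for ERD;
#: delta/theta/gamma take conventional edges.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 27.0),
    "gamma": (27.0, 45.0),
}


@dataclass(frozen=True)
class STFTSpec:
    """Window/hop grid of the short-time Fourier transform."""

    fs: float
    n_window: int
    hop: int
    window: str = "hann"  # "hann" | "rect"

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.n_window:
            raise ValueError("require 0 < hop <= n_window")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @classmethod
    def default(cls, fs: float) -> "STFTSpec":
        """Hann window of 1 s with 50% overlap: ~1 Hz resolution, enough to
        resolve the 8-12 Hz alpha band over a 10 s trial."""
        n = int(round(fs))
        return cls(fs=fs, n_window=n, hop=max(1, n // 2))

    def taper(self) -> np.ndarray:
        if self.window == "hann":
            return np.hanning(self.n_window)
        if self.window == "rect":
            return np.ones(self.n_window)
        raise ValueError(f"unknown window {self.window!r}")


@dataclass
class Spectrogram:
    """Non-negative power on a frequency x time grid."""

    power: np.ndarray  # (n_freqs, n_frames)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s, frame centers

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        mask = (self.freqs >= lo) & (self.freqs <= hi)
        if not mask.any():
            raise ValueError(f"band {band} Hz contains no frequency bins")
        return mask


def stft(x: np.ndarray, spec: STFTSpec) -> Spectrogram:
    """One-sided power STFT of a 1-D signal on the grid of ``spec``."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("stft expects a 1-D signal")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    n = spec.n_window
    if x.size < n:
        raise ValueError(f"signal of {x.size} samples shorter than window {n}")
    frames = np.lib.stride_tricks.sliding_window_view(x, n)[:: spec.hop]
    w = spec.taper()
    X = np.fft.rfft(frames * w, axis=-1)
    # Scale so sum over one-sided bins = windowed-frame energy.
    scale = np.full(X.shape[-1], 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    power = (np.abs(X) ** 2 * scale).T  # (freqs, frames)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    times = (np.arange(frames.shape[0]) * spec.hop + n / 2) / spec.fs
    return Spectrogram(power=power, freqs=freqs, times=times)


def band_energy(spec: Spectrogram, band: tuple[float, float]) -> np.ndarray:
    """Per-frame sum of power over the bins inside ``band`` (inclusive)."""
    return spec.power[spec.band_slice(band)].sum(axis=0)


def trial_averaged_spectrogram(
    ts: TrialSet, channel: str | int, spec: STFTSpec
) -> Spectrogram:
    """Elementwise mean of the per-trial spectrograms of one channel."""
    if ts.n_trials < 1:
        raise ValueError("need at least one trial")
    if isinstance(channel, str):
        try:
            ch = ts.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in {ts.channel_names}"
            ) from None
    else:
        ch = int(channel)
        if not 0 <= ch < ts.n_channels:
            raise KeyError(f"channel index {ch} out of range")
    first = stft(ts.data[0, ch], spec)
    acc = first.power.copy()
    for i in range(1, ts.n_trials):
        acc += stft(ts.data[i, ch], spec).power
    return Spectrogram(power=acc / ts.n_trials, freqs=first.freqs, times=first.times)


def band_power_ratio(
    sg: Spectrogram,
    band: tuple[float, float],
    task_window_s: tuple[float, float],
    baseline_window_s: tuple[float, float],
) -> float:
    """Mean band power in the task window / mean band power in the baseline
    window — the ERD power ratio ((1 - depth)^2 for an amplitude scaling of
    ``1 - depth``)."""
    trace = band_energy(sg, band)

    def mean_in(win):
        m = (sg.times >= win[0]) & (sg.times <= win[1])
        if not m.any():
            raise ValueError(f"no STFT frames inside window {win} s")
        return trace[m].mean()

    return float(mean_in(task_window_s) / mean_in(baseline_window_s))
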