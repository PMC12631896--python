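"""Raw-recording conditioning: filtering, epoching, Beer-Lambert conversion.

EEG path: down-sample to 200 Hz (anti-aliased), zero-phase band-pass
0.5-50 Hz, cut trials over the task window and subtract the per-channel mean
of a 3 s pre-stimulus interval.  fNIRS path: optional modified Beer-Lambert
conversion of two-wavelength optical density into dHbO/dHbR, zero-phase
band-pass 0.01-0.1 Hz, epoching and the same 3 s baseline correction.

Filtering is forward-backward (phase-free) so that the latency of
event-related desynchronization and of the hemodynamic response is not
shifted by the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data_model import ParadigmSpec, TrialSet

__all__ = [
    "ContinuousRecording",
    "FilterSpec",
    "preprocess_eeg",
    "preprocess_fnirs",
    "beer_lambert",
    "EXTINCTION_GRATZER",
    "DPF_DEFAULTS",
]


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with event markers.

    ``events`` is a list of ``(sample_index, label)`` pairs marking task
    onsets (label = integer class index).  For fNIRS optical-density data,
    ``wavelengths`` names the two laser wavelengths (nm) and the channel
    axis is blocked: first all sites at ``wavelengths[0]``, then the same
    sites at ``wavelengths[1]``.
    """

    data: np.ndarray  # channels x samples
    fs: float
    events: list[tuple[int, int]]
    channel_names: list[str] = field(default_factory=list)
    wavelengths: tuple[float, float] | None = None
    source_detector_distance_cm: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        samples = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        for s, _ in self.events:
            if not 0 <= s < self.data.shape[1]:
                raise ValueError(f"event at sample {s} outside record "
                                 f"of {self.data.shape[1]} samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification, applied zero-phase (filtfilt)."""

    band: tuple[float, float]
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0 <= low < high:
            raise ValueError(f"band edges must satisfy 0 <= low < high, got {self.band}")
        if high >= fs / 2:
            raise ValueError(
                f"band edge {high} Hz at or above Nyquist ({fs / 2} Hz)"
            )

    def apply(self, data: np.ndarray, fs: float) -> np.ndarray:
        self.validate(fs)
        low, high = self.band
        if low <= 0:
            sos = signal.butter(self.order, high, btype="low", fs=fs, output="sos")
        else:
            sos = signal.butter(self.order, [low, high], btype="band", fs=fs,
                                output="sos")
        if self.zero_phase:
            return signal.sosfiltfilt(sos, data, axis=-1)
        return signal.sosfilt(sos, data, axis=-1)


def _downsample(data: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float, float]:
    """Anti-aliased decimation; returns (data, new_fs, sample-index ratio)."""
    if target_fs > fs:
        raise ValueError(f"cannot up-sample: target {target_fs} Hz > record {fs} Hz")
    if target_fs == fs:
        return data, fs, 1.0
    factor = fs / target_fs
    if abs(factor - round(factor)) < 1e-9:
        out = signal.decimate(data, int(round(factor)), axis=-1, ftype="fir",
                              zero_phase=True)
    else:
        n_out = int(data.shape[-1] * target_fs / fs)
        out = signal.resample_poly(data, up=int(round(target_fs)),
                                   down=int(round(fs)), axis=-1)[..., :n_out]
    return out, target_fs, fs / target_fs


def _epoch(
    data: np.ndarray,
    fs: float,
    events_samples: np.ndarray,
    labels: np.ndarray,
    window_s: tuple[float, float],
    baseline_s: float,
    baseline_end_offset_s: float,
) -> np.ndarray:
    """Cut trials over ``window_s`` (relative to task onset) and subtract the
    per-channel mean of the ``baseline_s`` interval ending at
    ``baseline_end_offset_s`` before the onset.  Never reads outside the
    recorded samples."""
    start_off = int(round(window_s[0] * fs))
    n_len = int(np.floor((window_s[1] - window_s[0]) * fs))
    base_n = int(round(baseline_s * fs))
    base_end_off = int(round(baseline_end_offset_s * fs))
    trials = []
    for onset in events_samples:
        a = onset + start_off
        b = a + n_len
        ba = onset - base_end_off - base_n
        bb = onset - base_end_off
        if ba < 0:
            raise ValueError(
                f"event at sample {onset}: record too short for a "
                f"{baseline_s}-s baseline window"
            )
        if a < 0 or b > data.shape[-1]:
            raise ValueError(
                f"event at sample {onset}: trial window [{a}, {b}) outside record"
            )
        epoch = data[:, a:b] - data[:, ba:bb].mean(axis=-1, keepdims=True)
        trials.append(epoch)
    return np.stack(trials)


def preprocess_eeg(
    rec: ContinuousRecording,
    paradigm: ParadigmSpec,
    subject_id: str = "unknown",
    target_fs: float = 200.0,
    band: tuple[float, float] = (0.5, 50.0),
    baseline_s: float = 3.0,
    include_cue: bool = False,
    epoch_window_s: tuple[float, float] | None = None,
    filter_order: int = 4,
) -> TrialSet:
    """EEG protocol: down-sample to ``target_fs``, band-pass, epoch, baseline.

    The trial window is task onset -> onset + task duration (10 s at 200 Hz
    gives 2000 samples); the baseline is the 3 s immediately preceding cue
    onset.  ``include_cue`` shifts the window start to cue onset instead;
    ``epoch_window_s`` overrides the window entirely (seconds relative to
    task onset), e.g. ``(-5, 10)`` for ERD visualisation epochs that include
    the pre-stimulus interval.
    """
    if rec.fs < 2 * band[1]:
        raise ValueError(f"sampling rate {rec.fs} Hz below Nyquist for band {band}")
    data, fs, ratio = _downsample(rec.data, rec.fs, target_fs)
    data = FilterSpec(band, order=filter_order).apply(data, fs)
    ev = np.array([int(round(s / ratio)) for s, _ in rec.events])
    labels = np.array([l for _, l in rec.events], dtype=np.int64)
    if epoch_window_s is not None:
        window = epoch_window_s
    elif include_cue:
        window = (-paradigm.cue_duration_s,
                  paradigm.task_duration_s)
    else:
        window = (0.0, paradigm.task_duration_s)
    trials = _epoch(data, fs, ev, labels, window, baseline_s,
                    baseline_end_offset_s=paradigm.cue_duration_s)
    return TrialSet(subject_id=subject_id, modality="eeg", data=trials,
                    labels=labels, fs=fs, channel_names=list(rec.channel_names))


# ---------------------------------------------------------------------------
# Modified Beer-Lambert conversion.

#: Molar extinction coefficients [1/(cm*mM)] at the two common CW-NIRS laser
#: wavelengths, columns (HbO, HbR).  Literature values (Gratzer compilation).
EXTINCTION_GRATZER: dict[float, tuple[float, float]] = {
    760.0: (0.5863, 1.5485),
    850.0: (1.0580, 0.6913),
}

#: Differential pathlength factors (adult head, literature values).
DPF_DEFAULTS: dict[float, float] = {760.0: 6.4, 850.0: 5.75}


def beer_lambert(
    rec: ContinuousRecording,
    extinction: dict[float, tuple[float, float]] | None = None,
    dpf: dict[float, float] | None = None,
) -> ContinuousRecording:
    """Convert two-wavelength optical density to dHbO / dHbR concentrations.

    Solves, per optode channel and sample, the modified Beer-Lambert system

        dOD(lambda) = (eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR) * d * DPF(lambda)

    where ``d`` is the source-detector distance.  Input channels are blocked
    by wavelength (all sites at wavelengths[0], then wavelengths[1]); output
    channels double to all-sites dHbO followed by all-sites dHbR, in mM
    (with the default extinction table in 1/(cm*mM)).
    """
    if rec.wavelengths is None or len(rec.wavelengths) != 2:
        raise ValueError("beer_lambert requires a recording with exactly 2 wavelengths")
    extinction = EXTINCTION_GRATZER if extinction is None else extinction
    dpf = DPF_DEFAULTS if dpf is None else dpf
    lam = rec.wavelengths
    for w in lam:
        if w not in extinction:
            raise ValueError(f"no extinction coefficients for wavelength {w} nm")
        if w not in dpf:
            raise ValueError(f"no differential pathlength factor for {w} nm")
    if rec.n_channels % 2:
        raise ValueError("expected an even channel count (two wavelength blocks)")
    n_sites = rec.n_channels // 2
    d = rec.source_detector_distance_cm
    # 2x2 system per sample: rows = wavelengths, cols = (HbO, HbR)
    A = np.array([
        [extinction[lam[0]][0] * d * dpf[lam[0]], extinction[lam[0]][1] * d * dpf[lam[0]]],
        [extinction[lam[1]][0] * d * dpf[lam[1]], extinction[lam[1]][1] * d * dpf[lam[1]]],
    ])
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("extinction matrix is singular; chromophores not separable")
    Ainv = np.linalg.inv(A)
    od = np.stack([rec.data[:n_sites], rec.data[n_sites:]])  # (2, sites, samples)
    conc = np.einsum("ij,jcs->ics", Ainv, od)  # (2=HbO/HbR, sites, samples)
    names = rec.channel_names[:n_sites]
    out_names = [f"{n}:HbO" for n in names] + [f"{n}:HbR" for n in names]
    return ContinuousRecording(
        data=np.concatenate([conc[0], conc[1]], axis=0),
        fs=rec.fs,
        events=list(rec.events),
        channel_names=out_names,
        wavelengths=None,
        source_detector_distance_cm=rec.source_detector_distance_cm,
    )


def preprocess_fnirs(
    rec: ContinuousRecording,
    paradigm: ParadigmSpec,
    subject_id: str = "unknown",
    band: tuple[float, float] = (0.01, 0.1),
    baseline_s: float = 3.0,
    filter_order: int = 3,
    resample_to: int | None = None,
    epoch_window_s: tuple[float, float] | None = None,
) -> TrialSet:
    """fNIRS protocol: band-pass 0.01-0.1 Hz, epoch, 3 s baseline correction.

    The recording must already be in concentration units (run
    :func:`beer_lambert` first on optical-density data).  Trials are cut at
    the native fNIRS rate with floor rounding of ``fs x duration``;
    ``resample_to`` optionally resamples every trial to an exact sample
    count (e.g. 100 for the printed fNIRS network input length).
    """
    if rec.wavelengths is not None:
        raise ValueError("recording still in optical density; run beer_lambert first")
    data = FilterSpec(band, order=filter_order).apply(rec.data, rec.fs)
    ev = np.array([s for s, _ in rec.events])
    labels = np.array([l for _, l in rec.events], dtype=np.int64)
    window = (0.0, paradigm.task_duration_s) if epoch_window_s is None else epoch_window_s
    trials = _epoch(data, rec.fs, ev, labels, window, baseline_s,
                    baseline_end_offset_s=0.0)
    fs = rec.fs
    if resample_to is not None and resample_to != trials.shape[-1]:
        fs = rec.fs * resample_to / trials.shape[-1]
        trials = signal.resample(trials, resample_to, axis=-1)
    return TrialSet(subject_id=subject_id, modality="fnirs", data=trials,
                    labels=labels, fs=fs, channel_names=list(rec.channel_names))
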