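"""Synthetic paired EEG+fNIRS motor-imagery populations.

The generator emulates the statistical structure the decoding framework
assumes, without any biophysical forward modeling:

* EEG: per-channel 1/f (pink) background noise plus alpha (10 Hz) and beta
  (20 Hz) oscillations on "sensorimotor" channels.  During the task window
  the oscillation amplitude on the hemisphere contralateral to the imagined
  hand is multiplied by ``1 - erd_depth`` (event-related desynchronization)
  with a 0.5 s ramp; the ipsilateral hemisphere desynchronizes by a quarter
  of that depth.  Patient-like subjects have the ERD of their impaired
  hemisphere attenuated (x0.2 by default), mimicking the reduced alpha/beta
  desynchronization seen after intracerebral hemorrhage.
* fNIRS: task-locked dHbO responses from a double-gamma hemodynamic kernel
  convolved with the task boxcar (stronger contralaterally), dHbR as a
  sign-flipped scaled copy (-0.3 x), plus a ~0.1 Hz physiological
  oscillation, slow drift and white noise.

Inter-subject variability enters through per-subject draws of ERD depth,
hemodynamic gain and delay, noise level, overall signal gain and small
spatial-pattern jitter.  All stochasticity flows from named seeds; the same
seed reproduces a subject bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .data_model import ParadigmSpec, SubjectDataset, TrialSet
from .preprocessing import ContinuousRecording, preprocess_eeg, preprocess_fnirs
from . import timefreq

__all__ = [
    "SubjectProfile",
    "GenParams",
    "PopulationSpec",
    "generate_subject",
    "generate_population",
    "generate_erd_epochs",
    "planted_truth",
    "estimate_erd_ratio",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject signal parameters planted by the generator."""

    erd_depth: float = 0.5          # fractional amplitude reduction in [0, 1]
    erd_band: tuple[float, float] = (8.0, 12.0)
    alpha_freq: float = 10.0        # Hz, inside erd_band
    beta_freq: float = 20.0
    alpha_amp: float = 4.0          # microvolt, sensorimotor alpha amplitude
    beta_amp: float = 2.0
    snr: float = 0.25               # background-noise std / alpha amplitude
    hemo_gain: float = 1.0          # micromolar peak dHbO response
    hemo_delay: float = 1.0         # s, response onset lag
    ipsi_fraction: float = 0.25     # ipsilateral ERD depth fraction
    laterality: str = "normal"      # normal | left_impaired | right_impaired
    impaired_scale: float = 0.2     # ERD multiplier on the impaired side
    gain: float = 1.0               # overall subject amplitude scale
    pattern_jitter: float = 0.1     # relative spatial-pattern perturbation
    scramble_pattern: bool = False  # permute channel weights (control)

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.laterality not in ("normal", "left_impaired", "right_impaired"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


@dataclass(frozen=True)
class GenParams:
    """Channel counts, rates and preprocessing targets of one study scale."""

    n_eeg: int = 30
    n_fnirs: int = 36               # dHbO channels fed to the network
    fs_eeg: float = 250.0
    fs_fnirs: float = 10.0
    target_fs_eeg: float = 200.0
    eeg_band: tuple[float, float] = (0.5, 50.0)
    fnirs_band: tuple[float, float] = (0.01, 0.1)
    fnirs_resample_to: int | None = 100
    lead_in_s: float = 10.0
    chromophore: str = "hbo"        # hbo | hbr
    # fNIRS nuisance components, relative to the subject's hemo_gain
    fnirs_noise: float = 0.1
    fnirs_mayer: float = 0.15
    fnirs_drift: float = 0.3

    @classmethod
    def default(cls) -> "GenParams":
        """Full-scale shapes: 30 x 2000 EEG, 36 x 100 fNIRS trials."""
        return cls()

    @classmethod
    def compact(cls) -> "GenParams":
        """Scaled-down shapes (8 x 500 EEG at 50 Hz, 12 x 100 fNIRS) for
        CPU-budget training studies."""
        return cls(n_eeg=8, n_fnirs=12, target_fs_eeg=50.0,
                   eeg_band=(0.5, 22.0))


def _hemisphere_weights(n_channels: int, rng: np.random.Generator,
                        jitter: float, scramble: bool) -> np.ndarray:
    """(2, n_channels) weights: row 0 = left hemisphere, row 1 = right.

    Channels split into two hemisphere halves; within each half a smooth
    bump centred on the middle ("sensorimotor") channels.
    """
    half = n_channels // 2
    w = np.zeros((2, n_channels))
    for h, sl in enumerate((slice(0, half), slice(half, n_channels))):
        m = sl.stop - sl.start
        x = np.linspace(-1, 1, m)
        w[h, sl] = np.exp(-(x**2) / 0.18)
    w *= 1.0 + jitter * rng.standard_normal(w.shape)
    w = np.clip(w, 0.0, None)
    if scramble:
        w = w[:, rng.permutation(n_channels)]
    return w


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                fs: float, std: float) -> np.ndarray:
    """Spectrally 1/f-shaped Gaussian noise, per-row std ``std``."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    coef = (rng.standard_normal((shape[0], freqs.size))
            + 1j * rng.standard_normal((shape[0], freqs.size))) * amp
    x = np.fft.irfft(coef, n=n, axis=1)
    x_std = x.std(axis=1, keepdims=True)
    x_std[x_std == 0] = 1.0
    return std * x / x_std


def _double_gamma(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic kernel (peak ~5 s), unit peak."""
    h = sps.gamma.pdf(t, 6.0) - sps.gamma.pdf(t, 16.0) / 6.0
    peak = h.max()
    return h / peak if peak > 0 else h


def hemodynamic_peak_lag_s(fs: float | None = None,
                           task_duration_s: float = 10.0) -> float:
    """Post-onset lag of the response peak for a boxcar stimulus convolved
    with the double-gamma kernel, on a grid of rate ``fs`` (default: fine
    10 ms grid)."""
    dt = 1.0 / fs if fs else 0.01
    t = np.arange(0, 30, dt)
    box = (t < task_duration_s).astype(float)
    resp = np.convolve(box, _double_gamma(t))[: t.size]
    return float(t[np.argmax(resp)])


def _trial_schedule(paradigm: ParadigmSpec, fs: float, lead_in_s: float):
    """(task-onset sample indices, labels, total samples).  Labels alternate
    left/right through the session schedule."""
    n = paradigm.n_trials
    labels = np.array([i % 2 for i in range(n)], dtype=np.int64)
    onsets = []
    t = lead_in_s + paradigm.cue_duration_s
    for _ in range(n):
        onsets.append(int(round(t * fs)))
        t += paradigm.task_duration_s + paradigm.rest_duration_s + paradigm.cue_duration_s
    total = int(round((t - paradigm.cue_duration_s + lead_in_s) * fs))
    return np.array(onsets), labels, total


def _erd_envelope(n_samples: int, fs: float, onsets, labels,
                  task_s: float, profile: SubjectProfile) -> np.ndarray:
    """(2, n_samples) oscillation amplitude envelope per hemisphere."""
    env = np.ones((2, n_samples))
    ramp_n = max(1, int(round(0.5 * fs)))
    ramp = np.linspace(0.0, 1.0, ramp_n)
    task_n = int(round(task_s * fs))
    for onset, lab in zip(onsets, labels):
        contra = 1 if lab == 0 else 0  # left-hand MI -> right hemisphere
        for hemi in (0, 1):
            depth = profile.erd_depth * (1.0 if hemi == contra else profile.ipsi_fraction)
            impaired = (
                (profile.laterality == "left_impaired" and lab == 0)
                or (profile.laterality == "right_impaired" and lab == 1)
            )
            if impaired and hemi == contra:
                depth *= profile.impaired_scale
            if depth <= 0:
                continue
            a, b = onset, min(onset + task_n, n_samples)
            shape = np.ones(b - a)
            m = min(ramp_n, shape.size)
            shape[:m] = ramp[:m]
            shape[-m:] = np.minimum(shape[-m:], ramp[::-1][-m:])
            env[hemi, a:b] -= depth * shape
    return env


def _continuous_eeg(profile: SubjectProfile, paradigm: ParadigmSpec,
                    gp: GenParams, rng: np.random.Generator) -> ContinuousRecording:
    onsets, labels, total = _trial_schedule(paradigm, gp.fs_eeg, gp.lead_in_s)
    w = _hemisphere_weights(gp.n_eeg, rng, profile.pattern_jitter,
                            profile.scramble_pattern)
    env = _erd_envelope(total, gp.fs_eeg, onsets, labels,
                        paradigm.task_duration_s, profile)
    t = np.arange(total) / gp.fs_eeg
    data = _pink_noise(rng, (gp.n_eeg, total), gp.fs_eeg,
                       std=profile.snr * profile.alpha_amp)
    for freq, amp in ((profile.alpha_freq, profile.alpha_amp),
                      (profile.beta_freq, profile.beta_amp)):
        phase = rng.uniform(0, 2 * np.pi, size=gp.n_eeg)
        carrier = np.sin(2 * np.pi * freq * t[None, :] + phase[:, None])
        hemi_env = w[0][:, None] * env[0][None, :] + w[1][:, None] * env[1][None, :]
        data += amp * hemi_env * carrier
    data *= profile.gain
    names = [f"L{i}" for i in range(gp.n_eeg // 2)] + \
            [f"R{i}" for i in range(gp.n_eeg - gp.n_eeg // 2)]
    return ContinuousRecording(data=data, fs=gp.fs_eeg,
                               events=[(int(s), int(l)) for s, l in zip(onsets, labels)],
                               channel_names=names)


def _continuous_fnirs(profile: SubjectProfile, paradigm: ParadigmSpec,
                      gp: GenParams, rng: np.random.Generator) -> ContinuousRecording:
    onsets, labels, total = _trial_schedule(paradigm, gp.fs_fnirs, gp.lead_in_s)
    w = _hemisphere_weights(gp.n_fnirs, rng, profile.pattern_jitter,
                            profile.scramble_pattern)
    t = np.arange(total) / gp.fs_fnirs
    kern_t = np.arange(0, 30.0, 1.0 / gp.fs_fnirs)
    kernel = _double_gamma(kern_t)
    task_n = int(round(paradigm.task_duration_s * gp.fs_fnirs))
    delay_n = int(round(profile.hemo_delay * gp.fs_fnirs))
    stim = np.zeros((2, total))  # per-hemisphere boxcar
    for onset, lab in zip(onsets, labels):
        contra = 1 if lab == 0 else 0
        a = min(onset + delay_n, total)
        b = min(a + task_n, total)
        stim[contra, a:b] += 1.0
        stim[1 - contra, a:b] += 0.3
    resp = np.stack([np.convolve(stim[h], kernel)[:total] for h in (0, 1)])
    peak = np.abs(resp).max()
    if peak > 0:  # planted contralateral peak amplitude = hemo_gain
        resp *= profile.hemo_gain / peak
    hbo = w[0][:, None] * resp[0][None, :] + w[1][:, None] * resp[1][None, :]
    mayer = gp.fnirs_mayer * profile.hemo_gain * np.sin(
        2 * np.pi * 0.095 * t[None, :] + rng.uniform(0, 2 * np.pi, (gp.n_fnirs, 1)))
    drift = np.linspace(0, 1, total)[None, :] * rng.normal(
        0, gp.fnirs_drift * profile.hemo_gain, (gp.n_fnirs, 1))
    noise = rng.normal(0, gp.fnirs_noise * profile.hemo_gain, (gp.n_fnirs, total))
    hbo = (hbo + mayer + drift + noise) * profile.gain
    if gp.chromophore == "hbr":
        data = -0.3 * hbo
        names = [f"F{i}:HbR" for i in range(gp.n_fnirs)]
    else:
        data = hbo
        names = [f"F{i}:HbO" for i in range(gp.n_fnirs)]
    return ContinuousRecording(data=data, fs=gp.fs_fnirs,
                               events=[(int(s), int(l)) for s, l in zip(onsets, labels)],
                               channel_names=names)


def generate_subject(profile: SubjectProfile, paradigm: ParadigmSpec | None = None,
                     gp: GenParams | None = None, seed: int = 0,
                     subject_id: str = "S00",
                     cohort_tag: str = "unspecified") -> SubjectDataset:
    """One subject's preprocessed, paired EEG + fNIRS trials.

    The continuous recordings pass through the standard preprocessing
    chains (EEG: down-sample + band-pass + epoch + baseline; fNIRS:
    band-pass + epoch + baseline + resample-to-length), so trial shapes
    match the configured network inputs.  Deterministic per seed; the
    planted parameters are recorded for :func:`planted_truth`.
    """
    paradigm = paradigm or ParadigmSpec()
    gp = gp or GenParams.default()
    if gp.n_eeg < 2 or gp.n_fnirs < 2:
        raise ValueError("need at least one channel per hemisphere")
    rng_eeg = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rng_fnirs = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    rec_eeg = _continuous_eeg(profile, paradigm, gp, rng_eeg)
    labels = np.array([l for _, l in rec_eeg.events])
    rec_fnirs = _continuous_fnirs(profile, paradigm, gp, rng_fnirs)
    eeg = preprocess_eeg(rec_eeg, paradigm, subject_id=subject_id,
                         target_fs=gp.target_fs_eeg, band=gp.eeg_band)
    fnirs = preprocess_fnirs(rec_fnirs, paradigm, subject_id=subject_id,
                             band=gp.fnirs_band,
                             resample_to=gp.fnirs_resample_to)
    sd = SubjectDataset(subject_id=subject_id, eeg=eeg, fnirs=fnirs,
                        cohort_tag=cohort_tag)
    sd.attrs["planted_truth"] = {
        "generator": "fusebci.synthetic_data",
        "seed": seed,
        "profile": profile,
        "paradigm": paradigm,
        "gen_params": gp,
        "labels": labels.copy(),
        "expected_alpha_power_ratio": (1.0 - profile.erd_depth) ** 2,
        "expected_hbo_peak_lag_s": profile.hemo_delay + hemodynamic_peak_lag_s(),
    }
    return sd


def planted_truth(sd: SubjectDataset) -> dict:
    """Exact planted parameters of a generator-produced subject."""
    truth = sd.attrs.get("planted_truth")
    if truth is None or truth.get("generator") != "fusebci.synthetic_data":
        raise ValueError(
            f"subject {sd.subject_id!r} was not produced by the synthetic generator"
        )
    return truth


def generate_erd_epochs(sd: SubjectDataset, pre_s: float = 3.0) -> TrialSet:
    """Re-epoch the subject's EEG with a window that includes the
    pre-stimulus baseline (for ERD task/baseline power analysis).

    Window: ``[-(cue + pre_s), task_duration]`` seconds around task onset;
    regenerated deterministically from the subject's recorded seed.
    """
    truth = planted_truth(sd)
    paradigm: ParadigmSpec = truth["paradigm"]
    gp: GenParams = truth["gen_params"]
    rng = np.random.default_rng(np.random.SeedSequence([truth["seed"], 1]))
    rec = _continuous_eeg(truth["profile"], paradigm, gp, rng)
    return preprocess_eeg(
        rec, paradigm, subject_id=sd.subject_id, target_fs=gp.target_fs_eeg,
        band=gp.eeg_band,
        epoch_window_s=(-(paradigm.cue_duration_s + pre_s),
                        paradigm.task_duration_s),
    )


def estimate_erd_ratio(sd: SubjectDataset, hand: str = "left",
                       band: tuple[float, float] | None = None,
                       pre_s: float = 3.0) -> float:
    """Alpha-band task/baseline power ratio on the hemisphere contralateral
    to ``hand``, averaged over that hand's trials.

    For a planted fractional ERD depth ``d`` the expected value is
    ``(1 - d)^2`` (power of an amplitude-scaled oscillation), plus the
    in-band noise floor.
    """
    truth = planted_truth(sd)
    profile: SubjectProfile = truth["profile"]
    paradigm: ParadigmSpec = truth["paradigm"]
    gp: GenParams = truth["gen_params"]
    band = band or profile.erd_band
    epochs = generate_erd_epochs(sd, pre_s=pre_s)
    lab = 0 if hand == "left" else 1
    idx = np.flatnonzero(epochs.labels == lab)
    from .data_model import subset_trials

    epochs = subset_trials(epochs, idx)
    # contralateral hemisphere: left hand -> right hemisphere channels
    half = gp.n_eeg // 2
    ch = (half + half // 2) if hand == "left" else half // 2
    spec = timefreq.STFTSpec.default(epochs.fs)
    sg = timefreq.trial_averaged_spectrogram(epochs, ch, spec)
    offset = paradigm.cue_duration_s + pre_s  # epoch time of task onset
    return timefreq.band_power_ratio(
        sg, band,
        task_window_s=(offset + 1.0, offset + paradigm.task_duration_s - 1.0),
        baseline_window_s=(0.0, pre_s),
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Population-level draw: cohort mix and per-subject parameter spread."""

    n_subjects: int = 6
    fraction_patient: float = 0.0
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    gen_params: GenParams = field(default_factory=GenParams.default)
    master_seed: int = 0
    erd_depth_mean: float = 0.5
    erd_depth_sd: float = 0.08
    hemo_gain_mean: float = 1.0
    hemo_gain_sd: float = 0.2
    hemo_delay_mean: float = 1.0
    hemo_delay_sd: float = 0.3
    snr_mean: float = 0.25
    snr_sd: float = 0.05
    gain_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("population needs >= 2 subjects")
        if not 0 <= self.fraction_patient <= 1:
            raise ValueError("fraction_patient must be in [0, 1]")


def generate_population(spec: PopulationSpec) -> list[SubjectDataset]:
    """Subjects drawn i.i.d. from the profile distributions; per-subject
    seeds derive deterministically from the master seed."""
    ss = np.random.SeedSequence(spec.master_seed)
    child_seeds = ss.generate_state(2 * spec.n_subjects) % (2**31)
    n_patient = int(round(spec.fraction_patient * spec.n_subjects))
    out = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(child_seeds[2 * i])
        is_patient = i >= spec.n_subjects - n_patient
        laterality = "normal"
        if is_patient:
            laterality = rng.choice(["left_impaired", "right_impaired"])
        profile = SubjectProfile(
            erd_depth=float(np.clip(
                rng.normal(spec.erd_depth_mean, spec.erd_depth_sd), 0.0, 1.0)),
            hemo_gain=float(np.clip(
                rng.normal(spec.hemo_gain_mean, spec.hemo_gain_sd), 0.2, None)),
            hemo_delay=float(np.clip(
                rng.normal(spec.hemo_delay_mean, spec.hemo_delay_sd), 0.0, None)),
            snr=float(np.clip(rng.normal(spec.snr_mean, spec.snr_sd), 0.05, None)),
            gain=float(np.clip(rng.normal(1.0, spec.gain_sd), 0.5, None)),
            laterality=str(laterality),
        )
        out.append(generate_subject(
            profile, spec.paradigm, spec.gen_params,
            seed=int(child_seeds[2 * i + 1]),
            subject_id=f"S{i:02d}",
            cohort_tag="patient" if is_patient else "normal",
        ))
    return out
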