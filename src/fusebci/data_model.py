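"""Core domain types shared by every stage of the hybrid EEG-fNIRS pipeline.

The unit of data flowing through the framework is the :class:`TrialSet` — a
labeled ``trials x channels x samples`` array for one subject and one
modality.  A :class:`SubjectDataset` pairs the EEG and fNIRS trial sets of a
subject; trials are time-locked, so both modalities carry the same label
sequence.  Labels are stored as integers ``{0, 1}`` with a class-name map;
class order is fixed as ``("left", "right")`` throughout so that confusion
matrices are comparable across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "CLASSES",
    "ParadigmSpec",
    "TrialSet",
    "SubjectDataset",
    "EvalReport",
    "validate_subject",
    "save_subject",
    "load_subject",
    "SchemaError",
]

#: Fixed binary class order (left hand, right hand motor imagery).
CLASSES = ("left", "right")

_SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    """Raised when a subject container file cannot be interpreted."""


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and trial-count structure of a motor-imagery block paradigm.

    The default values reproduce a cue-task-rest MI paradigm with a 2 s
    directional cue, a 10 s imagery period and a 15 s rest, 15 trials per
    hand per session over two sessions (60 trials in total).
    """

    cue_duration_s: float = 2.0
    task_duration_s: float = 10.0
    rest_duration_s: float = 15.0
    trials_per_class_per_session: int = 15
    n_sessions: int = 2
    classes: tuple[str, str] = CLASSES

    def __post_init__(self) -> None:
        if min(self.cue_duration_s, self.task_duration_s, self.rest_duration_s) <= 0:
            raise ValueError("all paradigm durations must be > 0")
        if self.trials_per_class_per_session < 1:
            raise ValueError("trials_per_class_per_session must be >= 1")
        if len(self.classes) != 2:
            raise ValueError("framework is a binary classifier: exactly 2 classes")

    @property
    def n_trials(self) -> int:
        """Total trials = sessions x trials-per-class x classes."""
        return self.n_sessions * self.trials_per_class_per_session * len(self.classes)

    @property
    def trial_duration_s(self) -> float:
        return self.cue_duration_s + self.task_duration_s + self.rest_duration_s


@dataclass
class TrialSet:
    """Labeled multichannel single-modality trials for one subject.

    ``data`` is ``(n_trials, n_channels, n_samples)``; EEG in microvolt,
    fNIRS in concentration change (micromolar).  ``labels`` are integer class
    indices into :data:`CLASSES`.
    """

    subject_id: str
    modality: str  # "eeg" | "fnirs"
    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("TrialSet.data must be trials x channels x samples")
        if self.modality not in ("eeg", "fnirs"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def violations(self) -> list[str]:
        out = []
        if self.data.shape[0] != self.labels.shape[0]:
            out.append(
                f"{self.modality}: trial count {self.data.shape[0]} != "
                f"label count {self.labels.shape[0]}"
            )
        if not np.isfinite(self.data).all():
            out.append(f"{self.modality}: non-finite values in trial data")
        if self.fs <= 0:
            out.append(f"{self.modality}: sampling rate must be > 0 (got {self.fs})")
        if len(self.channel_names) != self.data.shape[1]:
            out.append(
                f"{self.modality}: {len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if not np.isin(self.labels, [0, 1]).all():
            out.append(f"{self.modality}: labels outside {{0,1}}")
        return out


@dataclass
class SubjectDataset:
    """Time-locked EEG + fNIRS trial sets of one subject.

    ``cohort_tag`` distinguishes normal-like from patient-like subjects in
    synthetic populations; ``attrs`` carries generator-side metadata (e.g.
    the planted ground truth) and is not serialized.
    """

    subject_id: str
    eeg: TrialSet
    fnirs: TrialSet
    cohort_tag: str = "unspecified"
    attrs: dict = field(default_factory=dict, repr=False, compare=False)

    def violations(self) -> list[str]:
        out = self.eeg.violations() + self.fnirs.violations()
        if self.eeg.n_trials != self.fnirs.n_trials:
            out.append(
                f"trial-count mismatch: eeg has {self.eeg.n_trials}, "
                f"fnirs has {self.fnirs.n_trials}"
            )
        elif not np.array_equal(self.eeg.labels, self.fnirs.labels):
            out.append("label sequences differ between eeg and fnirs")
        if self.cohort_tag not in ("normal", "patient", "unspecified"):
            out.append(f"unknown cohort_tag {self.cohort_tag!r}")
        return out


def validate_subject(sd: SubjectDataset) -> list[str]:
    """Return a list of invariant violations (empty iff the dataset is valid)."""
    return sd.violations()


@dataclass
class EvalReport:
    """Cross-validated classification metrics for one subject and method.

    Metric arrays are per-fold fractions; the summary properties report
    percent mean +- SD.  The confusion matrix is summed over folds with rows
    = true class, columns = predicted class, in :data:`CLASSES` order.
    """

    method_label: str
    subject_id: str
    fold_accuracy: np.ndarray
    fold_precision: np.ndarray
    fold_recall: np.ndarray
    fold_f1: np.ndarray
    confusion_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.confusion_matrix = np.asarray(self.confusion_matrix, dtype=np.int64)
        if self.confusion_matrix.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if (self.confusion_matrix < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n_evaluated(self) -> int:
        return int(self.confusion_matrix.sum())

    @property
    def accuracy(self) -> float:
        """Mean per-fold accuracy (fraction)."""
        return float(np.mean(self.fold_accuracy))

    @property
    def pooled_accuracy(self) -> float:
        """trace / sum of the fold-aggregated confusion matrix."""
        return float(np.trace(self.confusion_matrix) / self.confusion_matrix.sum())

    def summary_percent(self) -> dict[str, str]:
        def fmt(x):
            return f"{100 * np.mean(x):.2f} ± {100 * np.std(x, ddof=1):.2f}"

        return {
            "Method": self.method_label,
            "Accuracy": fmt(self.fold_accuracy),
            "Precision": fmt(self.fold_precision),
            "Recall": fmt(self.fold_recall),
            "F1-Score": fmt(self.fold_f1),
        }


# ---------------------------------------------------------------------------
# (De)serialization: one HDF5 container per subject.


def _write_trialset(grp: h5py.Group, ts: TrialSet) -> None:
    grp.create_dataset("data", data=ts.data)
    grp.create_dataset("labels", data=ts.labels)
    grp.attrs["fs"] = ts.fs
    grp.attrs["modality"] = ts.modality
    grp.attrs["channel_names"] = [str(c) for c in ts.channel_names]


def _read_trialset(grp: h5py.Group, subject_id: str) -> TrialSet:
    return TrialSet(
        subject_id=subject_id,
        modality=str(grp.attrs["modality"]),
        data=grp["data"][()],
        labels=grp["labels"][()],
        fs=float(grp.attrs["fs"]),
        channel_names=[str(c) for c in grp.attrs["channel_names"]],
    )


def save_subject(sd: SubjectDataset, path) -> None:
    """Write a subject to a self-contained HDF5 container (schema-versioned)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["subject_id"] = sd.subject_id
        f.attrs["cohort_tag"] = sd.cohort_tag
        f.attrs["classes"] = list(CLASSES)
        _write_trialset(f.create_group("eeg"), sd.eeg)
        _write_trialset(f.create_group("fnirs"), sd.fnirs)


def load_subject(path) -> SubjectDataset:
    """Load a subject container written by :func:`save_subject`.

    Raises :class:`SchemaError` (naming the file) on unreadable files or on a
    schema-version mismatch.
    """
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("schema_version", -1))
            if version != _SCHEMA_VERSION:
                raise SchemaError(
                    f"{path}: schema version {version} != expected {_SCHEMA_VERSION}"
                )
            subject_id = str(f.attrs["subject_id"])
            return SubjectDataset(
                subject_id=subject_id,
                eeg=_read_trialset(f["eeg"], subject_id),
                fnirs=_read_trialset(f["fnirs"], subject_id),
                cohort_tag=str(f.attrs["cohort_tag"]),
            )
    except (OSError, KeyError) as exc:
        raise SchemaError(f"{path}: not a readable subject container ({exc})") from exc


def subset_trials(ts: TrialSet, idx: np.ndarray) -> TrialSet:
    """A new TrialSet restricted to the given trial indices (copying)."""
    return replace(ts, data=ts.data[idx].copy(), labels=ts.labels[idx].copy())
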