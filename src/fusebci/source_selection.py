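"""Wasserstein-distance similarity and trusted-score source-domain ranking.

Cross-subject transfer works best from a source subject whose signal
distribution is close to everyone else's and whose own decoder is accurate.
This module quantifies both: the order-1 Wasserstein (Earth-Mover's)
distance between subjects' preprocessed signal distributions, and the
trusted score

    T_k = Acc_k * (1 - Norm(sum_i W(k, i)))

where ``Acc_k`` is subject k's validation accuracy and ``Norm`` min-max
normalizes the mean distance to all other subjects across the roster.  The
subject with the highest trusted score per modality is the optimal source
domain; an aggregated two-modality variant supports the shared-source
ablation arm.

A multichannel, multi-trial subject is turned into distributions channel by
channel: all preprocessed trial samples of one channel pool into one
empirical 1-D distribution, and the subject distance is the mean over
channels of the channelwise W1 (sorted-quantile coupling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TrialSet

__all__ = [
    "DistanceMatrix",
    "TrustedScoreTable",
    "wasserstein_1d",
    "subject_distance",
    "distance_matrix",
    "trusted_scores",
    "select_source",
    "joint_trusted_selection",
]


def wasserstein_1d(p_samples: np.ndarray, q_samples: np.ndarray) -> float:
    """Order-1 Wasserstein distance between two equal-weight empirical
    distributions (sorted-quantile coupling)."""
    p = np.asarray(p_samples, dtype=np.float64).ravel()
    q = np.asarray(q_samples, dtype=np.float64).ravel()
    if p.size == 0 or q.size == 0:
        raise ValueError("wasserstein_1d requires non-empty sample sets")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("wasserstein_1d requires finite samples")
    return float(stats.wasserstein_distance(p, q))


def subject_distance(a: TrialSet, b: TrialSet) -> float:
    """Mean over channels of the channelwise W1 between two subjects'
    pooled preprocessed sample distributions.  Symmetric by construction."""
    if a.modality != b.modality:
        raise ValueError(f"modality mismatch: {a.modality} vs {b.modality}")
    if a.n_channels != b.n_channels:
        raise ValueError(
            f"channel mismatch: {a.n_channels} vs {b.n_channels} channels"
        )
    da = a.data.transpose(1, 0, 2).reshape(a.n_channels, -1)
    db = b.data.transpose(1, 0, 2).reshape(b.n_channels, -1)
    return float(np.mean([wasserstein_1d(da[c], db[c])
                          for c in range(a.n_channels)]))


@dataclass
class DistanceMatrix:
    """Symmetric inter-subject Wasserstein distance matrix for one modality."""

    values: np.ndarray
    subject_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match subject roster")

    @property
    def mean_distances(self) -> np.ndarray:
        """Per-subject mean distance to all others (self-term excluded)."""
        n = self.values.shape[0]
        return (self.values.sum(axis=1) - np.diag(self.values)) / (n - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.subject_ids)


def distance_matrix(subjects: list[TrialSet]) -> DistanceMatrix:
    """Full pairwise subject-distance matrix (the heatmap of the source-
    selection workflow)."""
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a distance matrix")
    modality = subjects[0].modality
    n = len(subjects)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = subject_distance(subjects[i], subjects[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values=values,
                          subject_ids=[s.subject_id for s in subjects],
                          modality=modality)


@dataclass
class TrustedScoreTable:
    """Per-subject accuracy, mean distance, normalized distance and trusted
    score, in roster order."""

    subject_ids: list[str]
    accuracy: np.ndarray
    mean_distance: np.ndarray
    normalized_distance: np.ndarray
    trusted_score: np.ndarray
    modality: str = "unspecified"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "accuracy": self.accuracy,
            "mean_distance": self.mean_distance,
            "normalized_distance": self.normalized_distance,
            "trusted_score": self.trusted_score,
        }).sort_values("trusted_score", ascending=False, ignore_index=True)


def trusted_scores(acc: np.ndarray | list[float] | dict[str, float],
                   dm: DistanceMatrix) -> TrustedScoreTable:
    """Trusted scores ``T_k = Acc_k * (1 - Norm(mean distance))``.

    ``Norm`` is min-max over the roster.  If all mean distances are equal
    the normalization is degenerate; ``Norm`` is then defined as 0 so that
    ``T_k = Acc_k``.
    """
    if isinstance(acc, dict):
        acc = np.array([acc[s] for s in dm.subject_ids], dtype=np.float64)
    else:
        acc = np.asarray(acc, dtype=np.float64)
    if acc.shape[0] != len(dm.subject_ids):
        raise ValueError("accuracy vector not aligned with distance matrix roster")
    if ((acc < 0) | (acc > 1)).any():
        raise ValueError("accuracies must be fractions in [0, 1]")
    md = dm.mean_distances
    span = md.max() - md.min()
    norm = np.zeros_like(md) if span == 0 else (md - md.min()) / span
    return TrustedScoreTable(
        subject_ids=list(dm.subject_ids),
        accuracy=acc,
        mean_distance=md,
        normalized_distance=norm,
        trusted_score=acc * (1.0 - norm),
        modality=dm.modality,
    )


def select_source(table: TrustedScoreTable) -> str:
    """Subject id with the highest trusted score.

    Deterministic tie-breaks: higher accuracy, then lower mean distance,
    then lexicographically smaller id.
    """
    if len(table.subject_ids) == 0:
        raise ValueError("empty trusted-score table")
    order = sorted(
        range(len(table.subject_ids)),
        key=lambda i: (-table.trusted_score[i], -table.accuracy[i],
                       table.mean_distance[i], table.subject_ids[i]),
    )
    return table.subject_ids[order[0]]


def joint_trusted_selection(eeg_table: TrustedScoreTable,
                            fnirs_table: TrustedScoreTable) -> str:
    """Shared-source ablation arm: argmax of the per-subject sum of the two
    modality trusted scores."""
    if eeg_table.subject_ids != fnirs_table.subject_ids:
        raise ValueError("subject rosters differ between modality tables")
    total = eeg_table.trusted_score + fnirs_table.trusted_score
    acc = eeg_table.accuracy + fnirs_table.accuracy
    md = eeg_table.mean_distance + fnirs_table.mean_distance
    order = sorted(
        range(len(eeg_table.subject_ids)),
        key=lambda i: (-total[i], -acc[i], md[i], eeg_table.subject_ids[i]),
    )
    return eeg_table.subject_ids[order[0]]
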