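"""Wasserstein metric, trusted scores and source-domain selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusebci.data_model import TrialSet
from fusebci.source_selection import (
    DistanceMatrix,
    distance_matrix,
    joint_trusted_selection,
    select_source,
    subject_distance,
    trusted_scores,
    wasserstein_1d,
)


def _matching_oracle(p, q):
    """Exhaustive minimum-mean-cost perfect matching between equal-count
    sample sets — the brute-force W1 for equal weights."""
    best = np.inf
    for perm in itertools.permutations(range(len(q))):
        cost = np.mean([abs(p[i] - q[j]) for i, j in enumerate(perm)])
        best = min(best, cost)
    return best


def test_wasserstein_point_masses_and_identity():
    assert wasserstein_1d([0.0], [3.0]) == 3.0
    assert wasserstein_1d([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == 0.0
    assert wasserstein_1d([0.0, 1.0], [2.0, 3.0]) == 2.0


def test_wasserstein_empty_input_raises():
    with pytest.raises(ValueError, match="non-empty"):
        wasserstein_1d([], [1.0])


@pytest.mark.parametrize("n", [2, 3, 4, 5])
def test_wasserstein_agrees_with_exhaustive_matching(n, rng):
    for _ in range(10):
        p = rng.standard_normal(n) * rng.uniform(0.5, 3)
        q = rng.standard_normal(n) + rng.uniform(-2, 2)
        np.testing.assert_allclose(wasserstein_1d(p, q), _matching_oracle(p, q),
                                   rtol=1e-10, atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    p=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    q=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    r=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
)
def test_wasserstein_metric_axioms(p, q, r):
    dpq = wasserstein_1d(p, q)
    assert dpq >= 0
    np.testing.assert_allclose(dpq, wasserstein_1d(q, p), rtol=1e-10, atol=1e-12)
    assert wasserstein_1d(p, p) == pytest.approx(0.0, abs=1e-12)
    assert dpq <= wasserstein_1d(p, r) + wasserstein_1d(r, q) + 1e-9


def _ts(data, sid="a", modality="eeg"):
    data = np.asarray(data, dtype=float)
    return TrialSet(sid, modality, data, np.arange(data.shape[0]) % 2, 100.0,
                    [f"c{i}" for i in range(data.shape[1])])


def test_subject_distance_translation_property(rng):
    base = rng.standard_normal((4, 3, 50))
    c = 1.7
    a = _ts(base, "a")
    b = _ts(base + c, "b")
    np.testing.assert_allclose(subject_distance(a, b), c, rtol=1e-9)
    np.testing.assert_allclose(subject_distance(a, b), subject_distance(b, a))
    assert subject_distance(a, a) == 0.0


def test_subject_distance_channel_mismatch_raises(rng):
    a = _ts(rng.standard_normal((2, 3, 10)))
    b = _ts(rng.standard_normal((2, 4, 10)), "b")
    with pytest.raises(ValueError, match="channel mismatch"):
        subject_distance(a, b)


def test_distance_matrix_on_shifted_subjects(rng):
    base = rng.standard_normal((4, 2, 40))
    c = 0.9
    subjects = [_ts(base + k * c, f"s{k}") for k in range(3)]
    dm = distance_matrix(subjects)
    assert dm.values.shape == (3, 3)
    np.testing.assert_allclose(dm.values, dm.values.T)
    np.testing.assert_allclose(np.diag(dm.values), 0.0, atol=1e-12)
    np.testing.assert_allclose(dm.mean_distances, [1.5 * c, c, 1.5 * c],
                               rtol=1e-9)


def test_distance_matrix_identical_subjects_is_zero(rng):
    base = rng.standard_normal((3, 2, 30))
    dm = distance_matrix([_ts(base, f"s{k}") for k in range(3)])
    assert np.abs(dm.values).max() == 0.0


def test_distance_matrix_order_invariance(rng):
    subjects = [_ts(rng.standard_normal((3, 2, 30)), f"s{k}") for k in range(4)]
    dm = distance_matrix(subjects)
    rev = distance_matrix(subjects[::-1])
    np.testing.assert_allclose(dm.values, rev.values[::-1, ::-1])


def test_distance_matrix_needs_two_subjects(rng):
    with pytest.raises(ValueError, match="2 subjects"):
        distance_matrix([_ts(rng.standard_normal((2, 2, 10)))])


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(values=values, subject_ids=ids, modality="eeg")


def test_trusted_scores_two_subject_hand_example():
    """acc (0.8, 0.6), mean distances (2, 1) -> norm (1, 0) -> T (0, 0.6)."""
    dm = _dm([[0, 2], [2, 0]])
    # mean distances are (2, 2) for a 2x2 matrix; build a 3-subject roster
    # realizing mean distances (2, 1, ...) is cleaner via direct construction:
    dm = _dm([[0, 2, 2], [2, 0, 0], [2, 0, 0]])
    table = trusted_scores([0.8, 0.6, 0.6], dm)
    np.testing.assert_allclose(table.mean_distance, [2.0, 1.0, 1.0])
    np.testing.assert_allclose(table.normalized_distance, [1.0, 0.0, 0.0])
    np.testing.assert_allclose(table.trusted_score, [0.0, 0.6, 0.6])
    assert select_source(table) == "s1"  # tie with s2 broken lexicographically


def test_trusted_scores_degenerate_distances_reduce_to_accuracy():
    dm = _dm(np.zeros((3, 3)))
    table = trusted_scores([0.7, 0.9, 0.5], dm)
    np.testing.assert_allclose(table.trusted_score, [0.7, 0.9, 0.5])
    assert select_source(table) == "s1"


def test_trusted_score_monotone_in_accuracy():
    # subject 0 has a normalized distance strictly inside (0, 1)
    dm = _dm([[0, 1, 2, 1.5], [1, 0, 1, 1], [2, 1, 0, 3], [1.5, 1, 3, 0]])
    assert 0 < trusted_scores([0.5] * 4, dm).normalized_distance[0] < 1
    lo = trusted_scores([0.6, 0.5, 0.5, 0.5], dm).trusted_score[0]
    hi = trusted_scores([0.9, 0.5, 0.5, 0.5], dm).trusted_score[0]
    assert hi > lo


def test_ranking_invariant_to_distance_scale():
    dm1 = _dm([[0, 1, 3], [1, 0, 2], [3, 2, 0]])
    dm2 = _dm(7.3 * dm1.values)
    acc = [0.7, 0.8, 0.65]
    t1 = trusted_scores(acc, dm1)
    t2 = trusted_scores(acc, dm2)
    np.testing.assert_allclose(t1.trusted_score, t2.trusted_score, rtol=1e-12)
    assert select_source(t1) == select_source(t2)


def test_trusted_scores_input_validation():
    dm = _dm(np.zeros((2, 2)))
    with pytest.raises(ValueError, match="aligned"):
        trusted_scores([0.5], dm)
    with pytest.raises(ValueError, match="fractions"):
        trusted_scores([1.5, 0.2], dm)


def test_joint_selection_sums_modalities():
    dm = _dm(np.zeros((2, 2)))
    eeg = trusted_scores([0.5, 0.1], dm)
    fnirs = trusted_scores([0.1, 0.6], dm)
    assert joint_trusted_selection(eeg, fnirs) == "s1"  # 0.7 > 0.6
    zero = trusted_scores([0.0, 0.0], dm)
    assert joint_trusted_selection(eeg, zero) == "s0"
    assert joint_trusted_selection(eeg, eeg) == select_source(eeg)


def test_joint_selection_roster_mismatch_raises():
    a = trusted_scores([0.5, 0.5], _dm(np.zeros((2, 2))))
    b = trusted_scores([0.5, 0.5], _dm(np.zeros((2, 2)), ids=["x", "y"]))
    with pytest.raises(ValueError, match="roster"):
        joint_trusted_selection(a, b)


def test_generator_pattern_family_controls_distances(compact_gp):
    """Subjects sharing the sensorimotor pattern are mutually closer than a
    scrambled-pattern subject — the premise of source selection."""
    from fusebci.synthetic_data import SubjectProfile, generate_subject

    normal = [generate_subject(SubjectProfile(), gp=compact_gp, seed=s,
                               subject_id=f"n{s}").eeg for s in (1, 2)]
    scrambled = generate_subject(SubjectProfile(scramble_pattern=True),
                                 gp=compact_gp, seed=3, subject_id="x").eeg
    within = subject_distance(normal[0], normal[1])
    across = min(subject_distance(normal[0], scrambled),
                 subject_distance(normal[1], scrambled))
    assert within < across
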