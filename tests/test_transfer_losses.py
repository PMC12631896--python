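"""Analytic identities, bounds, oracles and gradients of the transfer losses."""

import numpy as np
import pytest

from fusebci.transfer_losses import (
    DccaConfig,
    LossBundle,
    TransferLossConfig,
    coral_loss,
    coral_loss_grad,
    dcca_loss,
    dcca_loss_grad,
    mmd_loss,
    mmd_loss_grad,
    transfer_loss,
    transfer_loss_grad,
)


def _fd_check(fn, grad_fn, Xs, Xt, atol=1e-6, rtol=1e-4, n_probe=6, seed=0):
    """Central finite differences against the analytic gradients."""
    rng = np.random.default_rng(seed)
    _, gs, gt = grad_fn(Xs, Xt)
    eps = 1e-6
    for X, G, side in ((Xs, gs, 0), (Xt, gt, 1)):
        for flat in rng.choice(X.size, size=min(n_probe, X.size), replace=False):
            ix = np.unravel_index(flat, X.shape)
            Xp, Xm = X.copy(), X.copy()
            Xp[ix] += eps
            Xm[ix] -= eps
            args_p = (Xp, Xt) if side == 0 else (Xs, Xp)
            args_m = (Xm, Xt) if side == 0 else (Xs, Xm)
            num = (fn(*args_p) - fn(*args_m)) / (2 * eps)
            assert abs(num - G[ix]) <= atol + rtol * abs(num), (side, ix)


# ---------------------------------------------------------------------------
# CORAL


def test_coral_identity_is_zero(rng):
    F = rng.standard_normal((6, 4))
    assert coral_loss(F, F) == pytest.approx(0.0, abs=1e-15)


def test_coral_hand_derived_example():
    """C_s = [[2,0],[0,0]], C_t = [[0,0],[0,2]], ||dC||_F^2 = 8, /16 = 0.5;
    confirmed against numpy's covariance routine."""
    Fs = np.array([[0.0, 0.0], [2.0, 0.0]])
    Ft = np.array([[0.0, 0.0], [0.0, 2.0]])
    assert coral_loss(Fs, Ft) == pytest.approx(0.5, rel=1e-12)
    Cs, Ct = np.cov(Fs.T), np.cov(Ft.T)
    oracle = np.sum((Cs - Ct) ** 2) / (4 * 2 * 2)
    assert coral_loss(Fs, Ft) == pytest.approx(oracle, rel=1e-12)


def test_coral_translation_invariance(rng):
    F = rng.standard_normal((8, 5))
    shifted = F + rng.standard_normal(5)[None, :]
    assert coral_loss(F, shifted) == pytest.approx(0.0, abs=1e-12)


def test_coral_matches_dense_covariance_oracle(rng):
    Fs, Ft = rng.standard_normal((9, 6)), 2 * rng.standard_normal((7, 6))
    Cs, Ct = np.cov(Fs.T), np.cov(Ft.T)
    oracle = np.sum((Cs - Ct) ** 2) / (4 * 36)
    assert coral_loss(Fs, Ft) == pytest.approx(oracle, rel=1e-10)


def test_coral_non_negative_and_symmetric(rng):
    for _ in range(5):
        a, b = rng.standard_normal((6, 3)), rng.standard_normal((5, 3))
        assert coral_loss(a, b) >= 0
        assert coral_loss(a, b) == pytest.approx(coral_loss(b, a), rel=1e-12)


def test_coral_errors():
    with pytest.raises(ValueError, match=">= 2 rows"):
        coral_loss(np.zeros((1, 3)), np.zeros((4, 3)))
    with pytest.raises(ValueError, match="dimension mismatch"):
        coral_loss(np.zeros((3, 3)), np.zeros((3, 4)))


def test_coral_gradient_matches_finite_differences(rng):
    Xs, Xt = rng.standard_normal((7, 4)), rng.standard_normal((6, 4)) + 0.3
    _fd_check(coral_loss, coral_loss_grad, Xs, Xt)


# ---------------------------------------------------------------------------
# DCCA


def test_dcca_perfect_correlation_limit(rng):
    """F_t = F_s, r -> 0, k = d: every canonical correlation is 1."""
    X = rng.standard_normal((30, 4))
    cfg = DccaConfig(k=4, r=1e-9)
    assert dcca_loss(X, X, cfg) == pytest.approx(-4.0, abs=1e-6)


def test_dcca_independent_batches_near_zero(rng):
    n = 4000
    A, B = rng.standard_normal((n, 3)), rng.standard_normal((n, 3))
    loss = dcca_loss(A, B, DccaConfig(k=1, r=1e-3))
    assert abs(loss) < 3 / np.sqrt(n)


def test_dcca_affine_invariance(rng):
    X1, X2 = rng.standard_normal((50, 3)), rng.standard_normal((50, 3))
    X2 += 0.5 * X1  # some shared signal so the loss is not trivial
    cfg = DccaConfig(k=3, r=1e-8)
    base = dcca_loss(X1, X2, cfg)
    A = rng.standard_normal((3, 3)) + 2 * np.eye(3)
    transformed = dcca_loss(X1 @ A + 5.0, X2, cfg)
    assert transformed == pytest.approx(base, abs=1e-4)


def test_dcca_bounds(rng):
    for _ in range(5):
        X1 = rng.standard_normal((12, 4))
        X2 = rng.standard_normal((12, 5))
        cfg = DccaConfig(k=3)
        loss = dcca_loss(X1, X2, cfg)
        assert -3 - 1e-9 <= loss <= 0.0


def test_dcca_symmetry(rng):
    X1, X2 = rng.standard_normal((15, 3)), rng.standard_normal((15, 4))
    cfg = DccaConfig(k=2)
    assert dcca_loss(X1, X2, cfg) == pytest.approx(dcca_loss(X2, X1, cfg),
                                                   rel=1e-10)


def test_dcca_matches_dense_whitening_oracle(rng):
    """The low-rank route equals the naive d x d covariance computation."""
    X1, X2 = rng.standard_normal((20, 5)), rng.standard_normal((20, 4))
    k, r = 3, 1e-2
    n = 20
    X1c, X2c = X1 - X1.mean(0), X2 - X2.mean(0)
    H11 = X1c.T @ X1c / (n - 1) + r * np.eye(5)
    H22 = X2c.T @ X2c / (n - 1) + r * np.eye(4)
    H12 = X1c.T @ X2c / (n - 1)

    def isqrt(H):
        w, V = np.linalg.eigh(H)
        return V @ np.diag(w**-0.5) @ V.T

    T = isqrt(H11) @ H12 @ isqrt(H22)
    oracle = -np.sort(np.linalg.svd(T, compute_uv=False))[::-1][:k].sum()
    assert dcca_loss(X1, X2, DccaConfig(k=k, r=r)) == pytest.approx(oracle,
                                                                    rel=1e-10)


def test_dcca_monotone_in_shared_signal(rng):
    n = 60
    shared = rng.standard_normal((n, 3))
    noise1, noise2 = rng.standard_normal((n, 3)), rng.standard_normal((n, 3))
    cfg = DccaConfig(k=3, r=1e-3)
    losses = [dcca_loss(a * shared + noise1, a * shared + noise2, cfg)
              for a in (0.0, 0.5, 1.0, 2.0, 8.0)]
    assert all(b < a for a, b in zip(losses, losses[1:]))
    assert losses[-1] > -3.0 - 1e-9


def test_dcca_errors(rng):
    with pytest.raises(ValueError, match="paired"):
        dcca_loss(np.zeros((4, 2)), np.zeros((5, 2)))
    with pytest.raises(ValueError, match="feasible rank"):
        dcca_loss(rng.standard_normal((4, 5)), rng.standard_normal((4, 5)),
                  DccaConfig(k=4))
    with pytest.raises(ValueError, match="r must be > 0"):
        DccaConfig(r=0.0)


def test_dcca_gradient_matches_finite_differences(rng):
    Xs = rng.standard_normal((8, 5))
    Xt = rng.standard_normal((8, 4)) + 0.4 * Xs[:, :4]
    cfg = DccaConfig(k=3, r=1e-2)
    _fd_check(lambda a, b: dcca_loss(a, b, cfg),
              lambda a, b: dcca_loss_grad(a, b, cfg), Xs, Xt)


# ---------------------------------------------------------------------------
# MMD


def test_mmd_identical_batches(rng):
    X = rng.standard_normal((10, 3))
    assert mmd_loss(X, X, bandwidths=(1.0,)) <= 1e-12  # unbiased: <= 0
    assert mmd_loss(X, X, bandwidths=(1.0,), biased=True) == pytest.approx(0.0, abs=1e-12)


def test_mmd_increases_with_cluster_separation(rng):
    base = rng.standard_normal((40, 2))
    other = rng.standard_normal((40, 2))
    values = [mmd_loss(base, other + np.array([sep, 0.0]), bandwidths=(1.0, 2.0))
              for sep in (1.0, 2.0, 4.0)]
    assert values[0] < values[1] < values[2]
    assert values[0] > 0


def test_mmd_matches_double_sum_oracle(rng):
    X, Y = rng.standard_normal((6, 2)), rng.standard_normal((5, 2)) + 1.0
    gamma = 1.0 / (2 * 1.5**2)

    def k(a, b):
        return np.exp(-gamma * np.sum((a - b) ** 2))

    n, m = len(X), len(Y)
    xx = sum(k(X[i], X[j]) for i in range(n) for j in range(n) if i != j)
    yy = sum(k(Y[i], Y[j]) for i in range(m) for j in range(m) if i != j)
    xy = sum(k(x, y) for x in X for y in Y)
    oracle = xx / (n * (n - 1)) + yy / (m * (m - 1)) - 2 * xy / (n * m)
    assert mmd_loss(X, Y, bandwidths=(1.5,)) == pytest.approx(oracle, rel=1e-10)


def test_mmd_permutation_invariance(rng):
    X, Y = rng.standard_normal((8, 3)), rng.standard_normal((7, 3))
    perm = rng.permutation(8)
    assert mmd_loss(X, Y, bandwidths=(1.0,)) == pytest.approx(
        mmd_loss(X[perm], Y, bandwidths=(1.0,)), rel=1e-12)


def test_mmd_gradient_matches_finite_differences(rng):
    Xs, Xt = rng.standard_normal((6, 3)), rng.standard_normal((5, 3)) + 0.5
    bw = (1.0, 2.0)
    _fd_check(lambda a, b: mmd_loss(a, b, bandwidths=bw),
              lambda a, b: mmd_loss_grad(a, b, bandwidths=bw), Xs, Xt)


# ---------------------------------------------------------------------------
# Combined transfer loss


def test_transfer_loss_composes_components(rng):
    Xs, Xt = rng.standard_normal((10, 4)), rng.standard_normal((10, 4))
    cfg = TransferLossConfig(arm="ours", dcca=DccaConfig(k=2))
    ld, lc, lt = transfer_loss(Xs, Xt, cfg)
    assert ld == pytest.approx(dcca_loss(Xs, Xt, cfg.dcca), rel=1e-12)
    assert lc == pytest.approx(coral_loss(Xs, Xt), rel=1e-12)
    assert lt == pytest.approx(ld + lc, rel=1e-12)


def test_transfer_loss_identity_limit(rng):
    X = rng.standard_normal((30, 3))
    cfg = TransferLossConfig(arm="ours", dcca=DccaConfig(k=3, r=1e-9))
    ld, lc, lt = transfer_loss(X, X.copy(), cfg)
    assert ld == pytest.approx(-3.0, abs=1e-6)
    assert lc == pytest.approx(0.0, abs=1e-12)
    assert lt == pytest.approx(-3.0, abs=1e-6)


def test_transfer_loss_ablation_arms(rng):
    Xs, Xt = rng.standard_normal((8, 3)), rng.standard_normal((8, 3))
    ld, lc, lt = transfer_loss(Xs, Xt, TransferLossConfig(arm="coral"))
    assert ld == 0.0 and lt == lc == pytest.approx(coral_loss(Xs, Xt))
    cfg = TransferLossConfig(arm="mmd", mmd_bandwidths=(1.0,))
    _, lm, ltm = transfer_loss(Xs, Xt, cfg)
    assert ltm == lm == pytest.approx(mmd_loss(Xs, Xt, bandwidths=(1.0,)))
    with pytest.raises(ValueError, match="loss arm"):
        TransferLossConfig(arm="wasserstein")


def test_transfer_loss_gradient_matches_finite_differences(rng):
    Xs = rng.standard_normal((8, 4))
    Xt = rng.standard_normal((8, 4)) + 0.3 * Xs
    cfg = TransferLossConfig(arm="ours", dcca=DccaConfig(k=2, r=1e-2))

    def grad_fn(a, b):
        (_, _, lt), gs, gt = transfer_loss_grad(a, b, cfg)
        return lt, gs, gt

    _fd_check(lambda a, b: transfer_loss(a, b, cfg)[2], grad_fn, Xs, Xt)


def test_loss_bundle_decomposition():
    bundle = LossBundle(l_clf=0.6931, l_dcca_eeg=-0.3, l_coral_eeg=0.1,
                        l_dcca_fnirs=0.05, l_coral_fnirs=0.05)
    assert bundle.l_trans_eeg == pytest.approx(-0.2)
    assert bundle.l_trans_fnirs == pytest.approx(0.1)
    assert bundle.total(0.5, 0.5) == pytest.approx(0.6431, rel=1e-12)
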