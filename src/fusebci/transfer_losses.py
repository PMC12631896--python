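"""Differentiable domain-alignment losses: Deep CORAL, DCCA and MMD.

Deep CORAL penalizes the Frobenius difference between the unbiased feature
covariance matrices of the source and target batches,

    L_coral = ||C_s - C_t||_F^2 / (4 d^2),

DCCA is the negative sum of the top-k singular values of the whitened
cross-covariance T = H_ss^{-1/2} H_st H_tt^{-1/2} of the (paired, centered,
ridge-regularized) batches, and MMD is the kernel two-sample discrepancy
used as an ablation baseline.  The combined transfer loss of the full
method is L_trans = L_dcca + L_coral.

All losses are evaluated without ever forming a d x d matrix: covariance
traces reduce to Gram-matrix norms and the DCCA whitening is carried out in
the (at most n-dimensional) row space of the centered batches, so the
losses scale to the flattened CNN feature dimensions.  Each loss has a
``*_grad`` companion returning exact analytic gradients with respect to
both input batches; tests verify them against central finite differences
and the low-rank DCCA route against a dense eigendecomposition oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base_networks import FeatureBatch

__all__ = [
    "DccaConfig",
    "TransferLossConfig",
    "LossBundle",
    "coral_loss",
    "coral_loss_grad",
    "dcca_loss",
    "dcca_loss_grad",
    "mmd_loss",
    "mmd_loss_grad",
    "transfer_loss",
    "transfer_loss_grad",
]

LOSS_ARMS = ("ours", "coral", "mmd")


def _values(x) -> np.ndarray:
    v = x.values if isinstance(x, FeatureBatch) else np.asarray(x, dtype=np.float64)
    if v.ndim != 2:
        raise ValueError("feature batch must be an n x d matrix")
    return v


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Deep CORAL


def _coral_core(fs, ft):
    Xs, Xt = _values(fs), _values(ft)
    ns, d = Xs.shape
    nt, dt = Xt.shape
    if d != dt:
        raise ValueError(f"feature dimension mismatch: {d} vs {dt}")
    if ns < 2 or nt < 2:
        raise ValueError("covariance needs >= 2 rows in each batch")
    return _center(Xs), _center(Xt), ns, nt, d


def coral_loss(fs, ft) -> float:
    """||C_s - C_t||_F^2 / (4 d^2) with unbiased covariances.

    Computed through Gram matrices: tr(C_a C_b) = ||Xa_c Xb_c^T||_F^2 /
    ((n_a - 1)(n_b - 1)), so no d x d matrix is formed.
    """
    Xs, Xt, ns, nt, d = _coral_core(fs, ft)

    def tr_prod(A, B, na, nb):
        return np.sum((A @ B.T) ** 2) / ((na - 1) * (nb - 1))

    sq = (tr_prod(Xs, Xs, ns, ns) - 2 * tr_prod(Xs, Xt, ns, nt)
          + tr_prod(Xt, Xt, nt, nt))
    return float(max(sq, 0.0) / (4 * d * d))


def coral_loss_grad(fs, ft):
    """(loss, grad wrt source batch, grad wrt target batch)."""
    Xs, Xt, ns, nt, d = _coral_core(fs, ft)
    loss = coral_loss(Xs, Xt)
    # X_c (C_s - C_t) without forming C: (X_c X_c^T) X_c etc., O(n^2 d).
    s_cs = (Xs @ Xs.T) @ Xs / (ns - 1)
    s_ct = (Xs @ Xt.T) @ Xt / (nt - 1)
    t_ct = (Xt @ Xt.T) @ Xt / (nt - 1)
    t_cs = (Xt @ Xs.T) @ Xs / (ns - 1)
    gs = (s_cs - s_ct) / (d * d * (ns - 1))
    gt = (t_ct - t_cs) / (d * d * (nt - 1))
    # chain through centering (numerically a no-op: gradients have zero
    # column mean already)
    return loss, _center_grad(gs), _center_grad(gt)


def _center_grad(g: np.ndarray) -> np.ndarray:
    return g - g.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# DCCA


@dataclass(frozen=True)
class DccaConfig:
    """Number of canonical components ``k``, covariance ridge ``r`` and the
    eigenvalue floor used when whitening.

    ``k=None`` resolves at call time to ``min(d_s, d_t, n - 1, k_cap)``.
    The default cap is 1 (the leading canonical correlation): with the
    small batches used during transfer training the whitened
    cross-covariance is estimated from n ~ 16 rows in a feature space of
    hundreds of dimensions, where many canonical correlations are spurious
    and a large-k loss (bounded by -k) overwhelms the classification term;
    aligning only the leading component keeps the regularizer informative
    and comparable in magnitude to the cross-entropy.
    """

    k: int | None = None
    r: float = 1e-3
    epsilon: float = 1e-8
    k_cap: int = 1

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("ridge r must be > 0")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")

    def resolve_k(self, ds: int, dt: int, n: int) -> int:
        feasible = min(ds, dt, n - 1)
        if self.k is None:
            return max(1, min(feasible, self.k_cap))
        if self.k > feasible:
            raise ValueError(
                f"k={self.k} exceeds feasible rank min(d_s, d_t, n-1)={feasible}"
            )
        return self.k


def _dcca_core(fs, ft, cfg: DccaConfig):
    """Low-rank whitened cross-covariance via thin SVDs of the centered
    batches.  Exact: T = Q1 Atil Q2^T with Atil small, because the
    cross-covariance lives in the row spaces spanned by Q1/Q2 and the
    ridge-regularized inverse square roots act as known diagonals there."""
    X1, X2 = _values(fs), _values(ft)
    n = X1.shape[0]
    if X2.shape[0] != n:
        raise ValueError(
            f"DCCA batches are paired by position: {n} vs {X2.shape[0]} rows"
        )
    if n < 2:
        raise ValueError("DCCA needs >= 2 paired rows")
    k = cfg.resolve_k(X1.shape[1], X2.shape[1], n)
    X1c, X2c = _center(X1), _center(X2)
    P1, s1, Q1t = np.linalg.svd(X1c, full_matrices=False)
    P2, s2, Q2t = np.linalg.svd(X2c, full_matrices=False)
    tol = 1e-12
    m1 = s1 > tol * max(s1[0], 1.0) if s1.size else np.zeros(0, bool)
    m2 = s2 > tol * max(s2[0], 1.0) if s2.size else np.zeros(0, bool)
    P1, s1, Q1 = P1[:, m1], s1[m1], Q1t[m1].T
    P2, s2, Q2 = P2[:, m2], s2[m2], Q2t[m2].T
    lam1 = np.maximum(s1**2 / (n - 1) + cfg.r, cfg.epsilon)
    lam2 = np.maximum(s2**2 / (n - 1) + cfg.r, cfg.epsilon)
    il1, il2 = 1.0 / np.sqrt(lam1), 1.0 / np.sqrt(lam2)
    M = (s1[:, None] * (P1.T @ P2) * s2[None, :]) / (n - 1)
    Atil = il1[:, None] * M * il2[None, :]
    u, sig, vt = np.linalg.svd(Atil)
    return dict(n=n, k=k, X1c=X1c, X2c=X2c, P1=P1, s1=s1, Q1=Q1,
                P2=P2, s2=s2, Q2=Q2, il1=il1, il2=il2,
                u=u, sig=sig, v=vt.T)


def dcca_loss(fs, ft, cfg: DccaConfig | None = None) -> float:
    """Negative sum of the top-k singular values of the whitened
    cross-covariance; bounded in [-k, 0]."""
    cfg = cfg or DccaConfig()
    c = _dcca_core(fs, ft, cfg)
    return float(-np.sum(c["sig"][: c["k"]]))


def dcca_loss_grad(fs, ft, cfg: DccaConfig | None = None):
    """(loss, grad wrt fs, grad wrt ft), exact analytic gradients.

    Uses the canonical-correlation gradient: with T = U S V^T,
    d(sum sigma)/dH_st = H_ss^{-1/2} U_k V_k^T H_tt^{-1/2} and
    d(sum sigma)/dH_ss = -1/2 H_ss^{-1/2} U_k S_k U_k^T H_ss^{-1/2},
    carried in the low-rank bases so no d x d matrix appears.
    """
    cfg = cfg or DccaConfig()
    c = _dcca_core(fs, ft, cfg)
    n = c["n"]
    # realized rank can fall below k (degenerate batches); the missing
    # components are zero singular values with zero gradient
    k = min(c["k"], c["sig"].size, c["u"].shape[1], c["v"].shape[1])
    uk, vk, sk = c["u"][:, :k], c["v"][:, :k], c["sig"][:k]
    il1, il2 = c["il1"], c["il2"]
    G11 = -0.5 * (il1[:, None] * uk) @ (sk[:, None] * (uk.T * il1[None, :]))
    G22 = -0.5 * (il2[:, None] * vk) @ (sk[:, None] * (vk.T * il2[None, :]))
    G12 = (il1[:, None] * uk) @ (vk.T * il2[None, :])
    A1 = c["P1"] * c["s1"][None, :]  # = X1c @ Q1
    A2 = c["P2"] * c["s2"][None, :]
    gcorr1 = (2 * A1 @ G11 + A2 @ G12.T) @ c["Q1"].T / (n - 1)
    gcorr2 = (2 * A2 @ G22 + A1 @ G12) @ c["Q2"].T / (n - 1)
    loss = float(-np.sum(sk))
    return loss, _center_grad(-gcorr1), _center_grad(-gcorr2)


# ---------------------------------------------------------------------------
# MMD (ablation baseline)


def _mmd_gammas(X, Y, bandwidths):
    if bandwidths is not None:
        bw = np.asarray(bandwidths, dtype=np.float64)
    else:
        Z = np.vstack([X, Y])
        d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=-1)
        med = np.sqrt(np.median(d2[d2 > 0])) if (d2 > 0).any() else 1.0
        bw = med * np.array([0.5, 1.0, 2.0])
    if (bw <= 0).any():
        raise ValueError("kernel bandwidths must be positive")
    return 1.0 / (2.0 * bw**2)


def mmd_loss(fs, ft, bandwidths=None, biased: bool = False) -> float:
    """Squared maximum mean discrepancy with a multi-bandwidth Gaussian
    kernel.  The default estimator is unbiased (diagonal terms excluded and
    the value can be slightly negative); ``biased=True`` gives the V-statistic
    which is exactly 0 for identical batches.  Bandwidths default to the
    median pairwise distance times (0.5, 1, 2)."""
    X, Y = _values(fs), _values(ft)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimension mismatch")
    n, m = X.shape[0], Y.shape[0]
    if n < 2 or m < 2:
        raise ValueError("MMD needs >= 2 rows in each batch")
    gammas = _mmd_gammas(X, Y, bandwidths)

    def kernel(A, B):
        d2 = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=-1)
        return np.mean([np.exp(-g * d2) for g in gammas], axis=0)

    Kxx, Kyy, Kxy = kernel(X, X), kernel(Y, Y), kernel(X, Y)
    if biased:
        val = Kxx.mean() + Kyy.mean() - 2 * Kxy.mean()
    else:
        val = ((Kxx.sum() - np.trace(Kxx)) / (n * (n - 1))
               + (Kyy.sum() - np.trace(Kyy)) / (m * (m - 1))
               - 2 * Kxy.mean())
    return float(val)


def mmd_loss_grad(fs, ft, bandwidths=None, biased: bool = False):
    """(loss, grad wrt fs, grad wrt ft) for the Gaussian-kernel MMD."""
    X, Y = _values(fs), _values(ft)
    n, m = X.shape[0], Y.shape[0]
    loss = mmd_loss(X, Y, bandwidths=bandwidths, biased=biased)
    gammas = _mmd_gammas(X, Y, bandwidths)

    def wmat(A, B):
        """mean over bandwidths of -2 gamma exp(-gamma |a-b|^2)."""
        d2 = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=-1)
        return np.mean([-2 * g * np.exp(-g * d2) for g in gammas], axis=0)

    Wxx, Wyy, Wxy = wmat(X, X), wmat(Y, Y), wmat(X, Y)
    if biased:
        cxx, cyy, cxy = 1.0 / n**2, 1.0 / m**2, -2.0 / (n * m)
    else:
        np.fill_diagonal(Wxx, 0.0)
        np.fill_diagonal(Wyy, 0.0)
        cxx, cyy, cxy = 1.0 / (n * (n - 1)), 1.0 / (m * (m - 1)), -2.0 / (n * m)

    def pair_grad(W, A, B, coeff):
        # d/dA_i of coeff * sum_ij w(|A_i - B_j|^2): 2 w' (A_i - B_j)
        return coeff * (W.sum(axis=1)[:, None] * A - W @ B)

    gx = 2 * pair_grad(Wxx, X, X, cxx) + pair_grad(Wxy, X, Y, cxy)
    gy = 2 * pair_grad(Wyy, Y, Y, cyy) + pair_grad(Wxy.T, Y, X, cxy)
    return loss, gx, gy


# ---------------------------------------------------------------------------
# Combined transfer loss and the loss bundle of the total objective


@dataclass(frozen=True)
class TransferLossConfig:
    """Which alignment loss regularizes training: the full method
    (DCCA + CORAL), or one of the ablation arms.

    ``class_conditioned`` switches the DCCA term to pair labeled target
    trials with same-class source trials (aligning within-class
    distributions) instead of the default unconditioned batch pairing;
    CORAL always operates on unlabeled batches.
    """

    arm: str = "ours"
    dcca: DccaConfig = field(default_factory=DccaConfig)
    mmd_bandwidths: tuple[float, ...] | None = None
    class_conditioned: bool = False

    def __post_init__(self) -> None:
        if self.arm not in LOSS_ARMS:
            raise ValueError(f"loss arm must be one of {LOSS_ARMS}, got {self.arm!r}")


def transfer_loss(fs, ft, cfg: TransferLossConfig | None = None):
    """(L_dcca, L_coral, L_trans) for the configured arm.

    For the full method L_trans = L_dcca + L_coral; the CORAL arm drops the
    DCCA term; the MMD arm reports its loss in the CORAL slot of the tuple
    (single-term ablation)."""
    cfg = cfg or TransferLossConfig()
    if cfg.arm == "ours":
        ld = dcca_loss(fs, ft, cfg.dcca)
        lc = coral_loss(fs, ft)
    elif cfg.arm == "coral":
        ld, lc = 0.0, coral_loss(fs, ft)
    else:
        ld, lc = 0.0, mmd_loss(fs, ft, bandwidths=cfg.mmd_bandwidths)
    return ld, lc, ld + lc


def transfer_loss_grad(fs, ft, cfg: TransferLossConfig | None = None):
    """((L_dcca, L_coral, L_trans), grad_fs, grad_ft) of L_trans."""
    cfg = cfg or TransferLossConfig()
    if cfg.arm == "ours":
        ld, gds, gdt = dcca_loss_grad(fs, ft, cfg.dcca)
        lc, gcs, gct = coral_loss_grad(fs, ft)
        return (ld, lc, ld + lc), gds + gcs, gdt + gct
    if cfg.arm == "coral":
        lc, gs, gt = coral_loss_grad(fs, ft)
        return (0.0, lc, lc), gs, gt
    lm, gs, gt = mmd_loss_grad(fs, ft, bandwidths=cfg.mmd_bandwidths)
    return (0.0, lm, lm), gs, gt


@dataclass
class LossBundle:
    """Decomposed training objective of one step:
    L = L_clf + a * L_trans_eeg + b * L_trans_fnirs."""

    l_clf: float
    l_dcca_eeg: float = 0.0
    l_coral_eeg: float = 0.0
    l_dcca_fnirs: float = 0.0
    l_coral_fnirs: float = 0.0

    @property
    def l_trans_eeg(self) -> float:
        return self.l_dcca_eeg + self.l_coral_eeg

    @property
    def l_trans_fnirs(self) -> float:
        return self.l_dcca_fnirs + self.l_coral_fnirs

    def total(self, a: float, b: float) -> float:
        return self.l_clf + a * self.l_trans_eeg + b * self.l_trans_fnirs
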