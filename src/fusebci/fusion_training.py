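"""Multimodal fusion model construction and the transfer-training procedure.

The fusion model joins the EEG and fNIRS feature extractors initialized
from the optimal source subjects' checkpoints and classifies the weighted
concatenation ``[a * F_eeg, b * F_nirs]`` with a single linear head (no
hidden layers).  The mixing ratio comes from the target subject's
single-modality accuracies,

    a = A_eeg / (A_eeg + A_nirs),   b = A_nirs / (A_eeg + A_nirs),

and the training objective is

    L = L_clf + a * L_trans_eeg + b * L_trans_fnirs

with cross-entropy on the labeled target training folds and per-modality
transfer losses (DCCA + CORAL, or an ablation arm) between source features
and target features.  Optimization is Adam at learning rate 0.001.

The full procedure: pretrain every subject's base networks, rank subjects
by trusted score per modality, select the optimal sources, then for each
remaining (target) subject train the fusion model with paired source/target
batches under the 5-fold protocol of the evaluation module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .base_networks import (
    BaseModel,
    FeatureBatch,
    NetworkSpec,
    build_base_model,
    split_train_val,
    train_base,
)
from .data_model import EvalReport, SubjectDataset, TrialSet, subset_trials
from .evaluation import FoldPlan, confusion_from_predictions, make_folds, _report_from_folds
from .source_selection import (
    distance_matrix,
    joint_trusted_selection,
    select_source,
    trusted_scores,
)
from .transfer_losses import (
    LossBundle,
    TransferLossConfig,
    coral_loss_grad,
    dcca_loss_grad,
    transfer_loss_grad,
)

__all__ = [
    "FusionWeights",
    "FusionModel",
    "TransferRunConfig",
    "SourceSelection",
    "fusion_weights",
    "fuse_features",
    "total_loss",
    "build_fusion_model",
    "pretrain_population",
    "select_sources",
    "train_transfer",
    "evaluate_fusion_no_transfer",
]


@dataclass(frozen=True)
class FusionWeights:
    """Accuracy-proportional modality mixing ratio (a + b = 1)."""

    a: float
    b: float
    A_eeg: float
    A_nirs: float


def fusion_weights(A_eeg: float, A_nirs: float) -> FusionWeights:
    """a = A_eeg / (A_eeg + A_nirs), b = A_nirs / (A_eeg + A_nirs)."""
    if not (0 <= A_eeg <= 1 and 0 <= A_nirs <= 1):
        raise ValueError("accuracies must be fractions in [0, 1]")
    s = A_eeg + A_nirs
    if s == 0:
        raise ValueError("both accuracies are 0; mixing ratio undefined")
    return FusionWeights(a=A_eeg / s, b=A_nirs / s, A_eeg=A_eeg, A_nirs=A_nirs)


def fuse_features(f_eeg: FeatureBatch, f_nirs: FeatureBatch,
                  w: FusionWeights) -> FeatureBatch:
    """Row-wise weighted concatenation ``[a * F_eeg, b * F_nirs]``."""
    if f_eeg.n != f_nirs.n:
        raise ValueError(
            f"paired-trial row mismatch: {f_eeg.n} EEG vs {f_nirs.n} fNIRS rows"
        )
    fused = np.hstack([w.a * f_eeg.values, w.b * f_nirs.values])
    return FeatureBatch(values=fused, subject_id=f_eeg.subject_id,
                        domain_tag=f_eeg.domain_tag)


def total_loss(bundle: LossBundle, w: FusionWeights) -> float:
    """L = L_clf + a * L_trans_eeg + b * L_trans_fnirs."""
    return bundle.total(w.a, w.b)


@dataclass
class FusionModel:
    """Two source-initialized extractors + weighted-concatenation linear head."""

    eeg_extractor: nn.Sequential
    fnirs_extractor: nn.Sequential
    head: nn.Sequential
    weights: FusionWeights
    eeg_spec: NetworkSpec
    fnirs_spec: NetworkSpec

    @property
    def d_eeg(self) -> int:
        return self.eeg_spec.flatten_length

    @property
    def d_fnirs(self) -> int:
        return self.fnirs_spec.flatten_length

    def forward(self, x_eeg: np.ndarray, x_fnirs: np.ndarray, train: bool):
        fe, ce = self.eeg_extractor.forward(x_eeg, train)
        fn, cn = self.fnirs_extractor.forward(x_fnirs, train)
        fused = np.hstack([self.weights.a * fe, self.weights.b * fn])
        logits, ch = self.head.forward(fused, train)
        return logits, (ce, cn, ch)

    def backward(self, caches, glogits):
        ce, cn, ch = caches
        gfused = self.head.backward(ch, glogits)
        ge = self.weights.a * gfused[:, : self.d_eeg]
        gn = self.weights.b * gfused[:, self.d_eeg:]
        self.eeg_extractor.backward(ce, ge)
        self.fnirs_extractor.backward(cn, gn)

    def predict(self, x_eeg: np.ndarray, x_fnirs: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x_eeg, x_fnirs, train=False)
        return logits.argmax(axis=1)

    def zero_grads(self):
        self.eeg_extractor.zero_grads()
        self.fnirs_extractor.zero_grads()
        self.head.zero_grads()


def build_fusion_model(eeg_ckpt: BaseModel, fnirs_ckpt: BaseModel,
                       w: FusionWeights, seed: int = 0) -> FusionModel:
    """Fusion model with extractors copied from the two source checkpoints
    and a freshly initialized linear head (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    eeg = build_base_model(eeg_ckpt.spec, rng=rng)
    eeg.feature_extractor.load_state_dict(eeg_ckpt.feature_extractor.state_dict())
    fnirs = build_base_model(fnirs_ckpt.spec, rng=rng)
    fnirs.feature_extractor.load_state_dict(fnirs_ckpt.feature_extractor.state_dict())
    d = eeg_ckpt.spec.flatten_length + fnirs_ckpt.spec.flatten_length
    head = nn.Sequential([nn.Linear(d, 2, rng=rng)])
    return FusionModel(eeg_extractor=eeg.feature_extractor,
                       fnirs_extractor=fnirs.feature_extractor,
                       head=head, weights=w,
                       eeg_spec=eeg_ckpt.spec, fnirs_spec=fnirs_ckpt.spec)


@dataclass(frozen=True)
class TransferRunConfig:
    """Configuration of one transfer-training run (Adam, lr 0.001)."""

    target: str
    source_eeg: str | None = None
    source_fnirs: str | None = None
    epochs: int = 20
    batch_size: int = 16
    lr: float = 0.001
    seed: int = 0
    loss: TransferLossConfig = field(default_factory=TransferLossConfig)
    source_mode: str = "separate"  # "separate" | "same"
    transfer_weight_scale: float = 1.0  # 0 => supervised fine-tuning only
    freeze_extractors: bool = False
    k_folds: int = 5

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.source_mode not in ("separate", "same"):
            raise ValueError("source_mode must be 'separate' or 'same'")


@dataclass(frozen=True)
class SourceSelection:
    eeg_source: str
    fnirs_source: str
    eeg_table: object
    fnirs_table: object


def pretrain_population(population: list[SubjectDataset], specs: dict,
                        epochs: int = 30, batch_size: int = 16,
                        seed: int = 0) -> dict:
    """Train each subject's EEGBase / fNIRSBase nets on their own data.

    Returns ``{(subject_id, modality): BaseModel}`` with validation
    accuracies recorded in each model's metadata (the Acc_k of the trusted
    scores and the A_eeg/A_nirs of the fusion weights).
    """
    out = {}
    for s_i, sd in enumerate(population):
        for modality in ("eeg", "fnirs"):
            ts: TrialSet = getattr(sd, modality)
            sub_seed = seed + 1000 * s_i + (0 if modality == "eeg" else 500)
            model = build_base_model(specs[modality], seed=sub_seed)
            tr, val = split_train_val(ts, seed=sub_seed)
            train_base(model, tr, val, epochs=epochs, batch_size=batch_size,
                       seed=sub_seed)
            out[(sd.subject_id, modality)] = model
    return out


def select_sources(population: list[SubjectDataset], pretrained: dict,
                   source_mode: str = "separate") -> SourceSelection:
    """Trusted-score ranking per modality over the preprocessed signals.

    ``separate`` picks the argmax per modality independently; ``same``
    aggregates the two modality scores and uses one shared source subject.
    """
    tables = {}
    for modality in ("eeg", "fnirs"):
        subjects = [getattr(sd, modality) for sd in population]
        dm = distance_matrix(subjects)
        acc = {sd.subject_id: pretrained[(sd.subject_id, modality)].meta["val_accuracy"]
               for sd in population}
        tables[modality] = trusted_scores(acc, dm)
    if source_mode == "same":
        shared = joint_trusted_selection(tables["eeg"], tables["fnirs"])
        return SourceSelection(shared, shared, tables["eeg"], tables["fnirs"])
    return SourceSelection(select_source(tables["eeg"]),
                           select_source(tables["fnirs"]),
                           tables["eeg"], tables["fnirs"])


def _get_subject(population: list[SubjectDataset], sid: str) -> SubjectDataset:
    for sd in population:
        if sd.subject_id == sid:
            return sd
    raise KeyError(f"subject {sid!r} not in population")


def _train_fusion_fold(
    model: FusionModel,
    target_eeg_tr: TrialSet, target_fnirs_tr: TrialSet,
    target_eeg_all: TrialSet, target_fnirs_all: TrialSet,
    source_eeg: TrialSet | None, source_fnirs: TrialSet | None,
    cfg: TransferRunConfig,
) -> list[LossBundle]:
    """Inner Adam loop of one fold; returns the per-step loss bundles."""
    modules = [model.head]
    if not cfg.freeze_extractors:
        modules = [model.eeg_extractor, model.fnirs_extractor, model.head]
    opt = nn.Adam(modules, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    B = cfg.batch_size
    n_clf = target_eeg_tr.n_trials
    use_transfer = cfg.transfer_weight_scale > 0 and source_eeg is not None
    a = cfg.transfer_weight_scale * model.weights.a
    b = cfg.transfer_weight_scale * model.weights.b
    log: list[LossBundle] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n_clf)
        for start in range(0, n_clf, B):
            idx = order[start:start + B]
            if idx.size < 2:
                continue
            model.zero_grads()
            # classification pass on labeled target training trials
            logits, caches = model.forward(target_eeg_tr.data[idx],
                                           target_fnirs_tr.data[idx], train=True)
            l_clf, glog = nn.softmax_cross_entropy(logits, target_eeg_tr.labels[idx])
            model.backward(caches, glog)
            bundle = LossBundle(l_clf=l_clf)
            if use_transfer:
                nb = idx.size  # equal batch sizes (paired DCCA batches)
                ti = rng.choice(target_eeg_all.n_trials, size=nb,
                                replace=target_eeg_all.n_trials < nb)
                y_batch = target_eeg_tr.labels[idx]
                for modality, src, tgt, tgt_tr, coeff in (
                    ("eeg", source_eeg, target_eeg_all, target_eeg_tr, a),
                    ("fnirs", source_fnirs, target_fnirs_all, target_fnirs_tr, b),
                ):
                    ext = model.eeg_extractor if modality == "eeg" else model.fnirs_extractor
                    si = rng.choice(src.n_trials, size=nb, replace=src.n_trials < nb)
                    # batch statistics only: keep evaluation statistics tied
                    # to the labeled target classification passes
                    with nn.frozen_running_stats(ext):
                        if cfg.loss.arm == "ours" and cfg.loss.class_conditioned:
                            # CORAL on unlabeled batches
                            fs, cs = ext.forward(src.data[si], train=True)
                            ftr, ct = ext.forward(tgt.data[ti], train=True)
                            lc, gcs, gct = coral_loss_grad(fs, ftr)
                            # DCCA on class-matched labeled pairs
                            sm = np.array([
                                rng.choice(np.flatnonzero(src.labels == c))
                                for c in y_batch])
                            fs2, cs2 = ext.forward(src.data[sm], train=True)
                            ft2, ct2 = ext.forward(tgt_tr.data[idx], train=True)
                            ld, gds, gdt = dcca_loss_grad(fs2, ft2, cfg.loss.dcca)
                            if not cfg.freeze_extractors:
                                ext.backward(cs, coeff * gcs)
                                ext.backward(ct, coeff * gct)
                                ext.backward(cs2, coeff * gds)
                                ext.backward(ct2, coeff * gdt)
                        else:
                            fs, cs = ext.forward(src.data[si], train=True)
                            ftr, ct = ext.forward(tgt.data[ti], train=True)
                            (ld, lc, _), gs, gt = transfer_loss_grad(fs, ftr, cfg.loss)
                            if not cfg.freeze_extractors:
                                ext.backward(cs, coeff * gs)
                                ext.backward(ct, coeff * gt)
                    if modality == "eeg":
                        bundle.l_dcca_eeg, bundle.l_coral_eeg = ld, lc
                    else:
                        bundle.l_dcca_fnirs, bundle.l_coral_fnirs = ld, lc
            log.append(bundle)
            opt.step()
    return log


def train_transfer(population: list[SubjectDataset], cfg: TransferRunConfig,
                   pretrained: dict, specs: dict,
                   plan: FoldPlan | None = None,
                   labeled_idx: np.ndarray | None = None):
    """Transfer-train the fusion model for one target subject.

    Per fold: extractors initialize from the per-modality source
    checkpoints; each step pairs a labeled target batch (cross-entropy
    through the fused head) with equal-size source/target batches whose
    extracted features feed the per-modality transfer losses; the total
    loss L_clf + a*L_trans_eeg + b*L_trans_fnirs is backpropagated with
    Adam.  Returns ``(last fold's FusionModel, EvalReport)`` under the
    stratified k-fold protocol (or a single split when ``labeled_idx``
    restricts the labeled target trials).
    """
    target = _get_subject(population, cfg.target)
    for sid, modality in ((cfg.source_eeg, "eeg"), (cfg.source_fnirs, "fnirs")):
        if cfg.transfer_weight_scale > 0 and sid is not None \
                and (sid, modality) not in pretrained:
            raise KeyError(
                f"no pretrained checkpoint for ({sid}, {modality}); "
                "run the pretraining step first"
            )
    # fusion weights from the target's single-modality pretraining accuracies
    try:
        A_eeg = pretrained[(cfg.target, "eeg")].meta["val_accuracy"]
        A_nirs = pretrained[(cfg.target, "fnirs")].meta["val_accuracy"]
    except KeyError:
        raise KeyError(
            f"target {cfg.target!r} has no pretrained base models; "
            "run the pretraining step first"
        ) from None
    w = fusion_weights(A_eeg, A_nirs)

    src_eeg_ts = src_fnirs_ts = None
    if cfg.source_eeg is not None:
        src_eeg_ts = _get_subject(population, cfg.source_eeg).eeg
        src_fnirs_ts = _get_subject(population, cfg.source_fnirs).fnirs
        eeg_ckpt = pretrained[(cfg.source_eeg, "eeg")]
        fnirs_ckpt = pretrained[(cfg.source_fnirs, "fnirs")]
    else:  # no source: random-init fine-tuning baseline
        eeg_ckpt = build_base_model(specs["eeg"], seed=cfg.seed)
        fnirs_ckpt = build_base_model(specs["fnirs"], seed=cfg.seed + 1)

    if labeled_idx is not None:
        splits = [(np.asarray(labeled_idx, dtype=np.int64),
                   np.setdiff1d(np.arange(target.eeg.n_trials), labeled_idx))]
    else:
        if plan is None:
            plan = make_folds(target.eeg.labels, k=cfg.k_folds, seed=cfg.seed)
        splits = [plan.train_test(f) for f in range(plan.k)]

    cms, model = [], None
    for f, (tr_idx, te_idx) in enumerate(splits):
        model = build_fusion_model(eeg_ckpt, fnirs_ckpt, w, seed=cfg.seed + 31 * f)
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + 31 * f)
        _train_fusion_fold(
            model,
            subset_trials(target.eeg, tr_idx), subset_trials(target.fnirs, tr_idx),
            target.eeg, target.fnirs,
            src_eeg_ts, src_fnirs_ts,
            fold_cfg,
        )
        pred = model.predict(target.eeg.data[te_idx], target.fnirs.data[te_idx])
        cms.append(confusion_from_predictions(target.eeg.labels[te_idx], pred))
    report = _report_from_folds(f"transfer_{cfg.loss.arm}_{cfg.source_mode}",
                                target.subject_id, cms)
    return model, report


def evaluate_fusion_no_transfer(sd: SubjectDataset, specs: dict, plan: FoldPlan,
                                epochs: int = 20, batch_size: int = 16,
                                seed: int = 0) -> EvalReport:
    """Baseline arm: the fusion architecture trained on the target's own
    labeled folds only (random initialization, no transfer losses)."""
    cms = []
    for f in range(plan.k):
        tr_idx, te_idx = plan.train_test(f)
        w = fusion_weights(0.5, 0.5)
        eeg_ckpt = build_base_model(specs["eeg"], seed=seed + 7 * f)
        fnirs_ckpt = build_base_model(specs["fnirs"], seed=seed + 7 * f + 1)
        model = build_fusion_model(eeg_ckpt, fnirs_ckpt, w, seed=seed + 7 * f)
        cfg = TransferRunConfig(target=sd.subject_id, epochs=epochs,
                                batch_size=batch_size, seed=seed + 7 * f,
                                transfer_weight_scale=0.0)
        _train_fusion_fold(
            model,
            subset_trials(sd.eeg, tr_idx), subset_trials(sd.fnirs, tr_idx),
            sd.eeg, sd.fnirs, None, None, cfg,
        )
        pred = model.predict(sd.eeg.data[te_idx], sd.fnirs.data[te_idx])
        cms.append(confusion_from_predictions(sd.eeg.labels[te_idx], pred))
    return _report_from_folds("linear_fusion_no_transfer", sd.subject_id, cms)
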