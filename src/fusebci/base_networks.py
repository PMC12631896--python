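"""Modality-specific CNN base networks (EEGBase Net / fNIRSBase Net).

Each network is a three-block 1-D convolutional feature extractor plus a
single linear classifier to two logits.  Blocks 1-2 are ordinary 1-D
convolutions; block 3 is a depthwise separable convolution (per-channel
temporal convolution followed by a pointwise 1x1 cross-channel mix).  Every
convolution is followed by batch normalization and a sigmoid activation;
adaptive average pooling follows blocks 2 and 3.  Filter counts are
``F1`` for block 1 and ``F2 = F1 * D`` thereafter (defaults F1=16, D=4).

The printed reference architecture has two internal inconsistencies on the
fNIRS side: its Conv1 (input 100, kernel 36, padding 18) yields 101 samples
where 100 is printed, and its final pooling is printed as length 17 where
the floor formula gives 12.  In the default ``table_compat`` mode the model
reproduces the printed lengths exactly (cropping one sample after Conv1 and
pooling adaptively to 17); ``table_compat=False`` follows the strict
conv/pool arithmetic instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .data_model import TrialSet

__all__ = [
    "NetworkSpec",
    "BaseModel",
    "FeatureBatch",
    "layer_output_length",
    "build_base_model",
    "extract_features",
    "train_base",
    "split_train_val",
    "save_checkpoint",
    "load_checkpoint",
]


def layer_output_length(L_in: int, kernel: int, padding: int = 0,
                        stride: int = 1, op_kind: str = "conv") -> int:
    """Temporal output length of a convolution or pooling layer.

    conv: ``L_in + 2*padding - kernel + 1`` (stride 1); pool:
    ``floor(L_in / kernel)``.  Raises on a non-positive result.
    """
    if op_kind == "conv":
        out = (L_in + 2 * padding - kernel) // stride + 1
    elif op_kind == "pool":
        out = L_in // kernel
    else:
        raise ValueError(f"op_kind must be 'conv' or 'pool', got {op_kind!r}")
    if out < 1:
        raise ValueError(
            f"{op_kind} layer with input {L_in}, kernel {kernel}, padding "
            f"{padding} yields non-positive length {out}"
        )
    return out


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description of one base network.

    ``conv1/conv2`` are ``(kernel, padding)`` pairs, ``conv3`` the depthwise
    kernel of the separable block, ``pool1/pool2`` average-pooling factors.
    ``pool2_target`` overrides the pool2 output length (printed-architecture
    compatibility); ``crop_conv1`` drops trailing samples after conv1.
    """

    modality: str
    input_channels: int
    input_samples: int
    F1: int = 16
    D: int = 4
    conv1: tuple[int, int] = (63, 31)
    conv2: tuple[int, int] = (30, 0)
    pool1: int = 4
    conv3: tuple[int, int] = (15, 7)
    pool2: int = 2
    crop_conv1: int = 0
    pool2_target: int | None = None
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.F1 < 1 or self.D < 1:
            raise ValueError("F1 and D must be >= 1")
        for k, _ in (self.conv1, self.conv2, self.conv3):
            if k < 1:
                raise ValueError("kernel sizes must be >= 1")
        self.layer_chain()  # validates positivity of every length

    @property
    def F2(self) -> int:
        return self.F1 * self.D

    def layer_chain(self) -> list[tuple[str, int]]:
        """(layer name, temporal output length) through the extractor."""
        L = layer_output_length(self.input_samples, *self.conv1, op_kind="conv")
        L -= self.crop_conv1
        if L < 1:
            raise ValueError("crop_conv1 removes every sample")
        chain = [("conv1", L)]
        L = layer_output_length(L, *self.conv2, op_kind="conv")
        chain.append(("conv2", L))
        L = layer_output_length(L, self.pool1, op_kind="pool")
        chain.append(("pool1", L))
        L = layer_output_length(L, *self.conv3, op_kind="conv")
        chain.append(("conv3", L))
        if self.pool2_target is None:
            L = layer_output_length(L, self.pool2, op_kind="pool")
        else:
            if self.pool2_target > L:
                raise ValueError(
                    f"pool2 target {self.pool2_target} exceeds input length {L}"
                )
            L = self.pool2_target
        chain.append(("pool2", L))
        return chain

    @property
    def flatten_length(self) -> int:
        return self.F2 * self.layer_chain()[-1][1]

    # -- presets ------------------------------------------------------------
    @classmethod
    def eeg_default(cls, input_channels: int = 30, input_samples: int = 2000,
                    F1: int = 16, D: int = 4) -> "NetworkSpec":
        """EEGBase Net: 30 x 2000 (10 s at 200 Hz) -> flatten F2 x 246."""
        return cls(modality="eeg", input_channels=input_channels,
                   input_samples=input_samples, F1=F1, D=D)

    @classmethod
    def fnirs_default(cls, input_channels: int = 36, input_samples: int = 100,
                      F1: int = 16, D: int = 4,
                      table_compat: bool = True) -> "NetworkSpec":
        """fNIRSBase Net: 36 x 100 -> flatten F2 x 17 (printed lengths)."""
        return cls(modality="fnirs", input_channels=input_channels,
                   input_samples=input_samples, F1=F1, D=D,
                   conv1=(36, 18), conv2=(101, 50), pool1=4,
                   conv3=(15, 7), pool2=2,
                   crop_conv1=1 if table_compat else 0,
                   pool2_target=17 if table_compat else None)

    @classmethod
    def eeg_compact(cls, input_channels: int = 8, input_samples: int = 500,
                    F1: int = 4, D: int = 2) -> "NetworkSpec":
        """Scaled-down EEG network (10 s at 50 Hz) for CPU-budget studies."""
        return cls(modality="eeg", input_channels=input_channels,
                   input_samples=input_samples, F1=F1, D=D,
                   conv1=(25, 12), conv2=(10, 0), pool1=4, conv3=(9, 4),
                   pool2=2)

    @classmethod
    def fnirs_compact(cls, input_channels: int = 12, input_samples: int = 100,
                      F1: int = 4, D: int = 2) -> "NetworkSpec":
        """Scaled-down fNIRS network for CPU-budget studies."""
        return cls(modality="fnirs", input_channels=input_channels,
                   input_samples=input_samples, F1=F1, D=D,
                   conv1=(13, 6), conv2=(11, 5), pool1=4, conv3=(9, 4),
                   pool2=2)


@dataclass
class BaseModel:
    """A feature extractor + linear classifier pair with training metadata."""

    spec: NetworkSpec
    feature_extractor: nn.Sequential
    classifier: nn.Sequential
    meta: dict = field(default_factory=dict)

    def forward(self, x: np.ndarray, train: bool):
        feats, c1 = self.feature_extractor.forward(x, train)
        logits, c2 = self.classifier.forward(feats, train)
        return logits, (c1, c2)

    def backward(self, caches, glogits):
        c1, c2 = caches
        gfeats = self.classifier.backward(c2, glogits)
        return self.feature_extractor.backward(c1, gfeats)

    def predict(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x, train=False)
        return logits.argmax(axis=1)

    def zero_grads(self):
        self.feature_extractor.zero_grads()
        self.classifier.zero_grads()


@dataclass
class FeatureBatch:
    """n x d matrix of flattened extractor outputs, the operand of the
    covariance/correlation transfer losses."""

    values: np.ndarray
    subject_id: str
    domain_tag: str = "source"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("FeatureBatch.values must be n x d")
        if not np.isfinite(self.values).all():
            raise ValueError("FeatureBatch contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def build_base_model(spec: NetworkSpec, rng: np.random.Generator | None = None,
                     seed: int | None = None) -> BaseModel:
    """Instantiate the three-block extractor and linear head of ``spec``."""
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    chain = dict(spec.layer_chain())
    layers: list[nn.Layer] = [
        nn.Conv1d(spec.input_channels, spec.F1, *spec.conv1, rng=rng),
    ]
    if spec.crop_conv1:
        layers.append(nn.Crop1d(spec.crop_conv1))
    layers += [
        nn.BatchNorm1d(spec.F1),
        nn.Sigmoid(),
        nn.Conv1d(spec.F1, spec.F2, *spec.conv2, rng=rng),
        nn.BatchNorm1d(spec.F2),
        nn.Sigmoid(),
        nn.AdaptiveAvgPool1d(chain["pool1"]),
        # depthwise separable block
        nn.DepthwiseConv1d(spec.F2, *spec.conv3, rng=rng),
        nn.Conv1d(spec.F2, spec.F2, 1, 0, rng=rng),
        nn.BatchNorm1d(spec.F2),
        nn.Sigmoid(),
        nn.AdaptiveAvgPool1d(chain["pool2"]),
        nn.Flatten(),
    ]
    extractor = nn.Sequential(layers)
    classifier = nn.Sequential([nn.Linear(spec.flatten_length, spec.n_classes, rng=rng)])
    return BaseModel(spec=spec, feature_extractor=extractor, classifier=classifier)


def extract_features(model: BaseModel, ts: TrialSet,
                     domain_tag: str = "source") -> FeatureBatch:
    """Flattened extractor outputs, one row per trial (evaluation mode)."""
    _check_shape(model.spec, ts)
    feats, _ = model.feature_extractor.forward(ts.data, train=False)
    return FeatureBatch(values=feats, subject_id=ts.subject_id,
                        domain_tag=domain_tag)


def _check_shape(spec: NetworkSpec, ts: TrialSet) -> None:
    expected = (spec.input_channels, spec.input_samples)
    actual = (ts.n_channels, ts.n_samples)
    if expected != actual:
        raise ValueError(
            f"trial shape mismatch: model expects channels x samples "
            f"{expected}, got {actual}"
        )


def split_train_val(ts: TrialSet, val_fraction: float = 0.2,
                    seed: int = 0) -> tuple[TrialSet, TrialSet]:
    """Deterministic stratified train/validation split of one TrialSet."""
    from .data_model import subset_trials

    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for c in np.unique(ts.labels):
        idx = np.flatnonzero(ts.labels == c)
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.extend(rng.permutation(idx)[:n_val])
    val_mask = np.zeros(ts.n_trials, dtype=bool)
    val_mask[val_idx] = True
    return subset_trials(ts, ~val_mask), subset_trials(ts, val_mask)


def train_base(model: BaseModel, train: TrialSet, val: TrialSet,
               lr: float = 0.001, epochs: int = 200, batch_size: int = 16,
               seed: int = 0, patience: int | None = 20) -> tuple[BaseModel, float]:
    """Train extractor + classifier with Adam on cross-entropy.

    Tracks validation accuracy each epoch, restores the best snapshot at the
    end and stops early after ``patience`` epochs without improvement.
    Deterministic for a fixed seed.  Returns ``(model, val_accuracy)``; the
    accuracy is also recorded in ``model.meta['val_accuracy']`` and feeds
    the trusted scores and fusion weights downstream.
    """
    if train.n_trials == 0 or val.n_trials == 0:
        raise ValueError("both train and validation splits must be non-empty")
    if np.unique(train.labels).size < 2:
        raise ValueError("training set contains a single class")
    _check_shape(model.spec, train)
    _check_shape(model.spec, val)
    rng = np.random.default_rng(seed)
    opt = nn.Adam([model.feature_extractor, model.classifier], lr=lr)
    best_acc, best_state, best_epoch = -1.0, None, 0
    for epoch in range(epochs):
        order = rng.permutation(train.n_trials)
        for start in range(0, train.n_trials, batch_size):
            idx = order[start:start + batch_size]
            if idx.size < 2:
                continue  # batch statistics need >= 2 trials
            model.zero_grads()
            logits, caches = model.forward(train.data[idx], train=True)
            _, glogits = nn.softmax_cross_entropy(logits, train.labels[idx])
            model.backward(caches, glogits)
            opt.step()
        acc = float((model.predict(val.data) == val.labels).mean())
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_state = (model.feature_extractor.state_dict(),
                          model.classifier.state_dict())
        if patience is not None and epoch - best_epoch >= patience:
            break
    if best_state is not None:
        model.feature_extractor.load_state_dict(best_state[0])
        model.classifier.load_state_dict(best_state[1])
    model.meta.update({
        "val_accuracy": best_acc, "seed": seed, "epochs": epochs,
        "lr": lr, "batch_size": batch_size,
        "val_split": "held-out stratified 20%",
    })
    return model, best_acc


# ---------------------------------------------------------------------------
# Checkpoints: named parameter arrays + spec + metadata in one .npz file.


def save_checkpoint(model: BaseModel, path) -> None:
    arrays = {f"extractor/{k}": v for k, v in model.feature_extractor.state_dict().items()}
    arrays |= {f"classifier/{k}": v for k, v in model.classifier.state_dict().items()}
    header = json.dumps({"spec": asdict(model.spec), "meta": model.meta})
    arrays["__header__"] = np.frombuffer(header.encode(), dtype=np.uint8)
    with open(path, "wb") as f:
        np.savez(f, **arrays)


def load_checkpoint(path) -> BaseModel:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        spec_d = header["spec"]
        for key in ("conv1", "conv2", "conv3"):
            spec_d[key] = tuple(spec_d[key])
        spec = NetworkSpec(**spec_d)
        model = build_base_model(spec)
        model.meta = header["meta"]
        ext = {k.split("/", 1)[1]: z[k] for k in z.files if k.startswith("extractor/")}
        clf = {k.split("/", 1)[1]: z[k] for k in z.files if k.startswith("classifier/")}
    model.feature_extractor.load_state_dict(ext)
    model.classifier.load_state_dict(clf)
    return model
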