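"""Multi-class sequence -> accessibility predictors and their training loop.

A *Predictor* maps a batch of one-hot sequences to one score per class:
peak heights in the regression setting, topic probabilities in the
classification setting. Regression uses a composite loss — the average
cosine distance between predicted and target per-region class vectors
(capturing the cell-type specificity profile) plus the mean squared error
between log-transformed heights (capturing magnitude) — optionally with the
cosine term weighted dynamically by the current log-MSE magnitude.
Classification uses binary cross-entropy.

Training follows a plateau schedule: Adam at 1e-3, learning rate divided by
4 after 5 epochs without validation improvement, early stop after 10, and
the best-validation weights are restored. Batches are augmented by a
stochastic +/-3 bp interval shift (re-fetched from the genome, so flanking
sequence enters) and reverse complementation with probability 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from . import nn
from .genomic_io import (
    GenomeSequence,
    GenomicInterval,
    one_hot_encode,
    reverse_complement,
)

__all__ = [
    "Predictor",
    "ModelConfig",
    "TrainingConfig",
    "LossValue",
    "LinearPredictor",
    "NetworkPredictor",
    "build_model",
    "tiny_dilated_config",
    "cosine_logmse_loss",
    "bce_loss",
    "poisson_loss",
    "augment_batch",
    "train",
    "finetune",
    "pad_to_input",
    "save_checkpoint",
    "load_checkpoint",
]


@runtime_checkable
class Predictor(Protocol):
    """Contract: one-hot batches in, per-class scores out."""

    class_names: list[str]
    input_length: int | None

    def predict(self, x: np.ndarray) -> np.ndarray:
        """[B, L, 4] -> [B, n_classes]; deterministic in inference mode."""
        ...

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """d score[class] / d input, shape [B, L, 4]."""
        ...


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None], True
    return x, False


class LinearPredictor:
    """Closed-form linear model: score_c(x) = sum(W[c] * x) + b[c].

    Useful as an analytically tractable predictor for attribution and
    design tests; also the ``linear`` architecture.
    """

    def __init__(self, weights: np.ndarray, bias: np.ndarray | None = None,
                 class_names: Sequence[str] | None = None):
        self.weights = np.asarray(weights, dtype=np.float64)  # [C, L, 4]
        if self.weights.ndim != 3 or self.weights.shape[2] != 4:
            raise ValueError("weights must have shape [classes, L, 4]")
        n_classes = self.weights.shape[0]
        self.bias = np.zeros(n_classes) if bias is None else np.asarray(bias, dtype=np.float64)
        self.class_names = list(class_names or [f"class_{i}" for i in range(n_classes)])
        self.input_length = self.weights.shape[1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        xb, squeeze = _as_batch(x)
        out = np.tensordot(xb, self.weights, axes=([1, 2], [1, 2])) + self.bias
        return out[0] if squeeze else out

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        xb, squeeze = _as_batch(x)
        g = np.broadcast_to(self.weights[class_index], xb.shape).copy()
        return g[0] if squeeze else g


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The dilated CNN (regression default) is a conv stem followed by
    residual dilated conv blocks with doubling dilation, global average
    pooling and a dense head; the regression head is softplus (nonnegative
    heights), the classification head sigmoid.
    """

    architecture: str = "dilated_cnn"  # dilated_cnn | simple_cnn | linear
    input_length: int = 2114
    n_classes: int = 1
    class_names: list[str] | None = None
    filters: int = 512
    kernel: int = 17
    n_dilated_blocks: int = 4
    dilated_kernel: int = 3
    hidden: int = 128
    dropout: float = 0.1
    activation: str = "gelu"
    output: str = "regression"  # regression | classification

    def resolved_class_names(self) -> list[str]:
        return list(self.class_names or [f"class_{i}" for i in range(self.n_classes)])


def tiny_dilated_config(n_classes: int, class_names: Sequence[str] | None = None,
                        input_length: int = 500, output: str = "regression") -> ModelConfig:
    """Small preset (well under 100k parameters) for 500-bp inputs."""
    return ModelConfig(
        architecture="dilated_cnn",
        input_length=input_length,
        n_classes=n_classes,
        class_names=list(class_names) if class_names else None,
        filters=48,
        kernel=13,
        n_dilated_blocks=3,
        hidden=64,
        dropout=0.1,
        output=output,
    )


class NetworkPredictor:
    """Predictor backed by the numpy network core."""

    def __init__(self, network: nn.Network, cfg: ModelConfig):
        self.network = network
        self.cfg = cfg
        self.class_names = cfg.resolved_class_names()
        self.input_length = cfg.input_length
        self.base_lr: float | None = None  # recorded by train()

    def predict(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        xb, squeeze = _as_batch(x)
        if xb.shape[1] != self.input_length:
            raise ValueError(f"expected input length {self.input_length}, got {xb.shape[1]}")
        outs = [self.network.forward(xb[i : i + batch_size], train=False)
                for i in range(0, len(xb), batch_size)]
        out = np.concatenate(outs, axis=0)
        return out[0] if squeeze else out

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        xb, squeeze = _as_batch(x)
        self.network.forward(xb, train=False)
        dout = np.zeros((len(xb), len(self.class_names)))
        dout[:, class_index] = 1.0
        g = self.network.backward(dout)
        return g[0] if squeeze else g


def _receptive_field(cfg: ModelConfig) -> int:
    rf = cfg.kernel
    for i in range(cfg.n_dilated_blocks):
        rf += (cfg.dilated_kernel - 1) * 2 ** (i + 1)
    return rf


def build_model(cfg: ModelConfig, seed: int = 0) -> Predictor:
    """Build a randomly initialized predictor for the given architecture."""
    rng = np.random.default_rng(seed)
    names = cfg.resolved_class_names()
    if cfg.architecture == "linear":
        w = rng.normal(0.0, 0.01, size=(cfg.n_classes, cfg.input_length, 4))
        return LinearPredictor(w, class_names=names)
    head = "softplus" if cfg.output == "regression" else "sigmoid"
    if cfg.architecture == "simple_cnn":
        layers: list[nn.Layer] = [
            nn.Conv1D(4, cfg.filters, cfg.kernel, rng=rng),
            nn.BatchNorm(cfg.filters),
            nn.Activation(cfg.activation),
            nn.GlobalAvgPool(),
            nn.Dropout(cfg.dropout),
            nn.Dense(cfg.filters, cfg.hidden, rng=rng),
            nn.Activation(cfg.activation),
            nn.Dense(cfg.hidden, cfg.n_classes, rng=rng),
            nn.Activation(head),
        ]
    elif cfg.architecture == "dilated_cnn":
        rf = _receptive_field(cfg)
        if rf > cfg.input_length:
            raise ValueError(
                f"receptive field {rf} exceeds input length {cfg.input_length}; "
                "reduce n_dilated_blocks or kernel sizes"
            )
        layers = [
            nn.Conv1D(4, cfg.filters, cfg.kernel, rng=rng),
            nn.BatchNorm(cfg.filters),
            nn.Activation(cfg.activation),
        ]
        for i in range(cfg.n_dilated_blocks):
            layers.append(
                nn.Residual([
                    nn.BatchNorm(cfg.filters),
                    nn.Activation(cfg.activation),
                    nn.Conv1D(cfg.filters, cfg.filters, cfg.dilated_kernel,
                              dilation=2 ** (i + 1), rng=rng),
                ])
            )
        layers += [
            nn.BatchNorm(cfg.filters),
            nn.Activation(cfg.activation),
            nn.GlobalAvgPool(),
            nn.Dropout(cfg.dropout),
            nn.Dense(cfg.filters, cfg.hidden, rng=rng),
            nn.Activation(cfg.activation),
            nn.Dense(cfg.hidden, cfg.n_classes, rng=rng),
            nn.Activation(head),
        ]
    else:
        raise ValueError(f"unknown architecture {cfg.architecture!r}")
    net = nn.Network(layers)
    net.seed_dropout(seed)
    return NetworkPredictor(net, cfg)


@dataclass
class TrainingConfig:
    loss: str = "cosine_logmse"  # cosine_logmse | cosine | poisson | bce
    learning_rate: float = 1e-3
    decay_factor: float = 4.0
    decay_patience: int = 5
    early_stop_patience: int = 10
    batch_size: int = 256
    epochs_max: int = 100
    seed: int = 0
    shift_max_bp: int = 3
    revcomp_prob: float = 0.5
    dynamic_loss_weight: bool = True
    improvement_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.decay_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LossValue:
    total: float
    cosine_term: float = 0.0
    logmse_term: float = 0.0
    weight: float = 1.0


_LAMBDA_MIN, _LAMBDA_MAX = 0.1, 10.0


def cosine_logmse_loss(
    y: np.ndarray, yhat: np.ndarray, dynamic: bool = False,
    return_grad: bool = False,
):
    """Composite regression loss: lambda * mean(1 - cos) + log-MSE.

    The cosine term compares each region's class-profile direction (scale
    invariant); the log-MSE term compares ln(1+.) magnitudes entrywise.
    With ``dynamic=True`` the cosine weight is the current log-MSE value,
    treated as a constant (detached) and clipped to [0.1, 10].
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=np.float64))
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    B, C = y.shape
    ny = np.linalg.norm(y, axis=1)
    nh = np.linalg.norm(yhat, axis=1)
    dots = (y * yhat).sum(axis=1)
    ok = (ny > 0) & (nh > 0)
    cos = np.zeros(B)  # zero-norm rows get cosine term 1 - 0 = 1
    cos[ok] = dots[ok] / (ny[ok] * nh[ok])
    if not ok.all():
        warnings.warn("zero-norm row(s); cosine term set to 1 there", stacklevel=2)
    cosine_term = float(np.mean(1.0 - cos))
    ly, lh = np.log1p(y), np.log1p(yhat)
    logmse_term = float(np.mean((lh - ly) ** 2))
    lam = float(np.clip(logmse_term, _LAMBDA_MIN, _LAMBDA_MAX)) if dynamic else 1.0
    total = lam * cosine_term + logmse_term
    value = LossValue(total, cosine_term, logmse_term, lam)
    if not return_grad:
        return value
    grad = 2.0 * (lh - ly) / (1.0 + yhat) / (B * C)
    dcos = np.zeros_like(yhat)
    o = ok
    dcos[o] = -(y[o] / (ny[o] * nh[o])[:, None]
                - (dots[o] / (ny[o] * nh[o] ** 3))[:, None] * yhat[o])
    grad += lam * dcos / B
    return value, grad


def bce_loss(y: np.ndarray, yhat: np.ndarray, return_grad: bool = False):
    """Mean binary cross-entropy over all entries; targets must be 0/1."""
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=np.float64))
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("BCE targets must be binary")
    eps = 1e-12
    p = np.clip(yhat, eps, 1 - eps)
    total = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
    if not return_grad:
        return total
    grad = (p - y) / (p * (1 - p)) / y.size
    return total, grad


def poisson_loss(y: np.ndarray, yhat: np.ndarray, return_grad: bool = False):
    """Mean Poisson negative log-likelihood (up to the y! constant)."""
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=np.float64))
    eps = 1e-12
    total = float(np.mean(yhat - y * np.log(yhat + eps)))
    if not return_grad:
        return total
    grad = (1.0 - y / (yhat + eps)) / y.size
    return total, grad


def cosine_loss(y: np.ndarray, yhat: np.ndarray, return_grad: bool = False):
    """Mean cosine distance between target and predicted class profiles."""
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=np.float64))
    B = y.shape[0]
    ny = np.linalg.norm(y, axis=1)
    nh = np.linalg.norm(yhat, axis=1)
    dots = (y * yhat).sum(axis=1)
    ok = (ny > 0) & (nh > 0)
    cos = np.zeros(B)
    cos[ok] = dots[ok] / (ny[ok] * nh[ok])
    total = float(np.mean(1.0 - cos))
    if not return_grad:
        return total
    grad = np.zeros_like(yhat)
    grad[ok] = -(y[ok] / (ny[ok] * nh[ok])[:, None]
                 - (dots[ok] / (ny[ok] * nh[ok] ** 3))[:, None] * yhat[ok]) / B
    return total, grad


def _loss_fn(name: str, dynamic: bool):
    if name == "cosine_logmse":
        def f(y, yhat):
            value, grad = cosine_logmse_loss(y, yhat, dynamic=dynamic, return_grad=True)
            return value.total, grad
        return f
    if name == "cosine":
        return lambda y, yhat: cosine_loss(y, yhat, return_grad=True)
    if name == "bce":
        return lambda y, yhat: bce_loss(y, yhat, return_grad=True)
    if name == "poisson":
        return lambda y, yhat: poisson_loss(y, yhat, return_grad=True)
    raise ValueError(f"unknown loss {name!r}")


def pad_to_input(seq: str, input_length: int) -> np.ndarray:
    """Center a short sequence in a zero-padded one-hot of ``input_length``.

    Odd remainders place the extra pad base on the right.
    """
    if len(seq) > input_length:
        raise ValueError(f"sequence length {len(seq)} exceeds input length {input_length}")
    pad = input_length - len(seq)
    left = pad // 2
    right = pad - left
    return one_hot_encode("N" * left + seq + "N" * right)


def augment_batch(
    batch: Sequence[tuple[GenomicInterval, np.ndarray]],
    genome: GenomeSequence,
    shift_max_bp: int = 3,
    revcomp_prob: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fetch one-hot sequences with stochastic shift/revcomp augmentation.

    The shift moves the *interval* before fetching, so flanking genomic
    sequence enters the view; chromosome edges are N-padded. Targets pass
    through unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs, ys = [], []
    for iv, target in batch:
        shift = int(rng.integers(-shift_max_bp, shift_max_bp + 1)) if shift_max_bp > 0 else 0
        x = one_hot_encode(genome.fetch(iv.chrom, iv.start + shift, iv.end + shift))
        if revcomp_prob > 0 and rng.random() < revcomp_prob:
            x = reverse_complement(x)
        xs.append(x)
        ys.append(np.asarray(target, dtype=np.float64))
    return np.stack(xs), np.stack(ys)


def _targets_of(data) -> np.ndarray:
    if hasattr(data, "values"):
        return np.asarray(data.values, dtype=np.float64)
    if getattr(data, "mask", None) is not None:
        return data.mask.astype(np.float64)
    raise ValueError("data must be a PeakMatrix or a binarized TopicMatrix")


def _encode_batch(regions, genome) -> np.ndarray:
    return np.stack([one_hot_encode(genome.fetch(iv.chrom, iv.start, iv.end)) for iv in regions])


def train(
    predictor: NetworkPredictor,
    data,
    genome: GenomeSequence,
    cfg: TrainingConfig | None = None,
    region_mask: np.ndarray | None = None,
) -> tuple[NetworkPredictor, list[dict]]:
    """Train on the ``train`` split, monitoring the ``val`` split.

    Returns the predictor with the best-validation-epoch weights restored,
    plus a per-epoch history (train loss, val loss, learning rate).
    """
    cfg = cfg or TrainingConfig()
    targets = _targets_of(data)
    split = data.obs["split"].to_numpy() if "split" in data.obs else None
    if split is None:
        raise ValueError("regions must be split before training")
    keep = np.ones(len(targets), dtype=bool) if region_mask is None else np.asarray(region_mask)
    train_idx = np.flatnonzero((split == "train") & keep)
    val_idx = np.flatnonzero((split == "val") & keep)
    if train_idx.size == 0:
        raise ValueError("empty training split")
    if val_idx.size == 0:
        raise ValueError("empty validation split")

    rng = np.random.default_rng(cfg.seed)
    predictor.network.seed_dropout(cfg.seed)
    if predictor.base_lr is None:
        predictor.base_lr = cfg.learning_rate
    opt = nn.Adam(predictor.network, lr=cfg.learning_rate)
    loss_fn = _loss_fn(cfg.loss, cfg.dynamic_loss_weight)
    regions = data.regions

    x_val = _encode_batch([regions[i] for i in val_idx], genome)
    y_val = targets[val_idx]

    def val_loss() -> float:
        pv = predictor.predict(x_val)
        lv, _ = loss_fn(y_val, pv)
        return lv

    best = predictor.network.state_dict()
    best_val = val_loss()
    history: list[dict] = []
    since_best_stop = 0
    since_best_decay = 0
    for epoch in range(cfg.epochs_max):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for b0 in range(0, order.size, cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            batch = [(regions[i], targets[i]) for i in idx]
            xb, yb = augment_batch(batch, genome, cfg.shift_max_bp, cfg.revcomp_prob, rng)
            pred = predictor.network.forward(xb, train=True)
            lval, grad = loss_fn(yb, pred)
            predictor.network.backward(grad)
            opt.step()
            epoch_losses.append(lval)
        lv = val_loss()
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                        "val_loss": lv, "lr": opt.lr})
        if lv < best_val - cfg.improvement_tol:
            best_val = lv
            best = predictor.network.state_dict()
            since_best_stop = since_best_decay = 0
        else:
            since_best_stop += 1
            since_best_decay += 1
            if since_best_decay >= cfg.decay_patience:
                opt.lr /= cfg.decay_factor
                since_best_decay = 0
            if since_best_stop >= cfg.early_stop_patience:
                break
    predictor.network.load_state_dict(best)
    return predictor, history


def finetune(
    predictor: NetworkPredictor,
    data,
    genome: GenomeSequence,
    cfg: TrainingConfig | None = None,
) -> tuple[NetworkPredictor, list[dict]]:
    """Continue training on cell-type-specific regions only.

    Same loop as :func:`train`, restricted to regions flagged ``specific``,
    with a smaller default batch (64) and a learning rate below the base
    model's. The base predictor is left untouched; a fine-tuned copy is
    returned.
    """
    if "specific" not in data.obs:
        raise ValueError("no 'specific' flags; run select_specific_regions first")
    flags = data.obs["specific"].to_numpy().astype(bool)
    if not flags.any():
        raise ValueError("no regions flagged as cell-type specific")
    if cfg is None:
        base = predictor.base_lr or 1e-3
        cfg = TrainingConfig(learning_rate=base / 100.0, batch_size=64)
    if predictor.base_lr is not None and cfg.learning_rate >= predictor.base_lr:
        warnings.warn("fine-tune learning rate is not below the base model's", stacklevel=2)
    clone = build_model(predictor.cfg, seed=0)
    clone.network.load_state_dict(predictor.network.state_dict())
    clone.base_lr = predictor.base_lr
    return train(clone, data, genome, cfg, region_mask=flags)


def save_checkpoint(predictor: NetworkPredictor, path: str) -> None:
    """Self-describing checkpoint: weights (npz) with embedded config JSON."""
    state = predictor.network.state_dict()
    cfg = predictor.cfg
    meta = json.dumps({
        "architecture": cfg.architecture, "input_length": cfg.input_length,
        "n_classes": cfg.n_classes, "class_names": predictor.class_names,
        "filters": cfg.filters, "kernel": cfg.kernel,
        "n_dilated_blocks": cfg.n_dilated_blocks, "dilated_kernel": cfg.dilated_kernel,
        "hidden": cfg.hidden, "dropout": cfg.dropout,
        "activation": cfg.activation, "output": cfg.output,
    })
    np.savez(path, __config__=np.array(meta), **state)


def load_checkpoint(path: str) -> NetworkPredictor:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__config__"]))
    cfg = ModelConfig(**{k: v for k, v in meta.items() if k != "class_names"},
                      class_names=meta["class_names"])
    predictor = build_model(cfg, seed=0)
    predictor.network.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return predictor
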