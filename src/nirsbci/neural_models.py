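"""Convolutional classifiers for epoch tensors, and their shared trainer.

Two architectures are provided, both implemented on the package's NumPy
neural-network core (:mod:`nirsbci._nn`):

* the **temporal 1D CNN with EvoNorm**: two strided valid-padding 1D
  convolutions (32 filters each, kernels 13 and 6, strides 9 and 4) over the
  ``201 × 32`` epoch tensor, with an EvoNorm-S0 normalization-activation and
  dropout (p = 0.5) after the input and after each convolution, a flatten to
  128 features and a softmax dense head.  An ablation flag swaps every
  EvoNorm for BatchNorm + ReLU.
* **EEGNet** (F1 = 8, D = 2, F2 = 16): temporal 'same' convolution (kernel
  ``(1, 6)``, half the sampling rate), full-height depthwise convolution
  with unit max-norm, separable convolution, two average pools and dropout
  (p = 0.25), flatten to 96, softmax dense head.

Training follows the same recipe for both: Adamax (lr 0.0005, legacy decay
5e-8), batch size 100, categorical cross-entropy, a stratified random 10%
validation split, early stopping with patience 20 on validation loss with
best-weight restoration, all randomness drawn from one seed (default 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import (Adamax, AvgPoolW, BatchNorm, Conv1dValid, Dense,
                  DepthwiseFullHeight, Dropout, ELU, EvoNormS0, Flatten, ReLU,
                  SeparableConvSame, Sequential, TemporalConvSame,
                  conv1d_out_len, softmax, softmax_cross_entropy)
from .preprocess import EpochSet

__all__ = ["ProposedCnnConfig", "EegnetConfig", "TrainSpec", "TrainingLog",
           "conv1d_out_len", "build_proposed_cnn", "build_eegnet", "train",
           "predict_proba", "predict_labels", "shape_trace"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProposedCnnConfig:
    """Architecture constants of the temporal EvoNorm CNN."""

    input_shape: tuple[int, int] = (201, 32)
    conv_filters: tuple[int, int] = (32, 32)
    kernel_sizes: tuple[int, int] = (13, 6)
    strides: tuple[int, int] = (9, 4)
    dropout_p: float = 0.5
    dense_units: int = 2
    evonorm_groups: int = 8
    normalization: str = "evonorm"  # or "batchnorm_relu" (ablation)

    def layer_lengths(self) -> tuple[int, int, int]:
        t1 = conv1d_out_len(self.input_shape[0], self.kernel_sizes[0], self.strides[0])
        t2 = conv1d_out_len(t1, self.kernel_sizes[1], self.strides[1])
        return t1, t2, t2 * self.conv_filters[1]


@dataclass(frozen=True)
class EegnetConfig:
    """Architecture constants of the EEGNet comparison model."""

    input_shape: tuple[int, int, int] = (32, 201, 1)
    f1: int = 8
    d: int = 2
    f2: int = 16
    temporal_kernel: int = 6
    separable_kernel: int = 2
    pools: tuple[int, int] = (4, 8)
    dropout_p: float = 0.25
    depthwise_max_norm: float = 1.0


@dataclass(frozen=True)
class TrainSpec:
    """Optimization settings; defaults are the pipeline's standard recipe."""

    learning_rate: float = 5e-4
    lr_decay: float = 5e-8
    batch_size: int = 100
    validation_fraction: float = 0.10
    early_stopping_patience: int = 20
    max_epochs: int = 500
    rng_seed: int = 0


@dataclass
class TrainingLog:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1
    n_updates: int = 0
    val_indices: np.ndarray | None = None
    small_batch_warning: bool = False

    @property
    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch]


def _norm_block(kind, channels, groups):
    if kind == "evonorm":
        return [EvoNormS0(channels, groups)]
    if kind == "batchnorm_relu":
        return [BatchNorm(channels), ReLU()]
    raise ValueError(f"unknown normalization {kind!r}")


def build_proposed_cnn(cfg: ProposedCnnConfig = ProposedCnnConfig(),
                       seed: int = 0) -> Sequential:
    """Build the temporal CNN; He-Normal weights drawn from ``seed``."""
    t_in, c_in = cfg.input_shape
    t1, t2, flat = cfg.layer_lengths()
    rng = np.random.default_rng(seed)
    g = cfg.evonorm_groups
    layers = []
    layers += _norm_block(cfg.normalization, c_in, g)
    layers += [Dropout(cfg.dropout_p),
               Conv1dValid(c_in, cfg.conv_filters[0], cfg.kernel_sizes[0],
                           cfg.strides[0], rng)]
    layers += _norm_block(cfg.normalization, cfg.conv_filters[0], g)
    layers += [Dropout(cfg.dropout_p),
               Conv1dValid(cfg.conv_filters[0], cfg.conv_filters[1],
                           cfg.kernel_sizes[1], cfg.strides[1], rng)]
    layers += _norm_block(cfg.normalization, cfg.conv_filters[1], g)
    layers += [Dropout(cfg.dropout_p), Flatten(),
               Dense(flat, cfg.dense_units, rng, init="he")]
    model = Sequential(layers, rng_seed=seed).astype(np.float32)
    model.input_shape = cfg.input_shape
    model.tag = "cnn" if cfg.normalization == "evonorm" else "cnn_bnrelu"
    trace = model.shape_trace(cfg.input_shape)
    for expected in [(t1, cfg.conv_filters[0]), (t2, cfg.conv_filters[1]),
                     (flat,), (cfg.dense_units,)]:
        if expected not in trace:
            raise AssertionError(f"layer shape {expected} missing from trace {trace}")
    return model


def build_eegnet(cfg: EegnetConfig = EegnetConfig(), seed: int = 0) -> Sequential:
    """Build EEGNet on (channels, time, 1) maps; Glorot weights from ``seed``."""
    h, w, c = cfg.input_shape
    rng = np.random.default_rng(seed)
    layers = [
        TemporalConvSame(c, cfg.f1, cfg.temporal_kernel, rng),
        BatchNorm(cfg.f1),
        DepthwiseFullHeight(h, cfg.f1, cfg.d, rng, max_norm=cfg.depthwise_max_norm),
        BatchNorm(cfg.f1 * cfg.d),
        ELU(),
        AvgPoolW(cfg.pools[0]),
        Dropout(cfg.dropout_p),
        SeparableConvSame(cfg.f1 * cfg.d, cfg.f2, cfg.separable_kernel, rng),
        BatchNorm(cfg.f2),
        ELU(),
        AvgPoolW(cfg.pools[1]),
        Dropout(cfg.dropout_p),
        Flatten(),
        Dense((w // cfg.pools[0] // cfg.pools[1]) * cfg.f2, 2, rng, init="glorot"),
    ]
    model = Sequential(layers, rng_seed=seed).astype(np.float32)
    model.input_shape = cfg.input_shape
    model.tag = "eegnet"
    flat = (w // cfg.pools[0] // cfg.pools[1]) * cfg.f2
    trace = model.shape_trace(cfg.input_shape)
    if (flat,) not in trace:
        raise AssertionError(f"EEGNet flatten length missing from trace {trace}")
    return model


def shape_trace(model: Sequential) -> list[tuple[int, ...]]:
    """Layer-by-layer output shapes for the model's declared input shape."""
    return model.shape_trace(model.input_shape)


def _model_input(model: Sequential, ep: EpochSet) -> np.ndarray:
    dtype = getattr(model, "dtype", np.float64)
    if len(model.input_shape) == 3:  # EEGNet: (channels, time, 1)
        return np.ascontiguousarray(ep.data.transpose(0, 2, 1)[..., None], dtype=dtype)
    return ep.data.astype(dtype)


def _stratified_split(labels, fraction, rng):
    n = len(labels)
    n_val = int(round(fraction * n))
    val_idx = []
    classes = np.unique(labels)
    for i, c in enumerate(classes):
        idx_c = np.flatnonzero(labels == c)
        take = max(1, int(round(fraction * idx_c.size))) if n_val else 0
        val_idx.append(rng.permutation(idx_c)[:take])
    val_idx = np.sort(np.concatenate(val_idx))
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    return train_idx, val_idx


def train(model: Sequential, ep: EpochSet,
          spec: TrainSpec = TrainSpec()) -> tuple[Sequential, TrainingLog]:
    """Train with early stopping on a stratified validation split.

    Requires a z-scored :class:`EpochSet` (the networks consume normalized
    epochs).  Stops after ``patience`` epochs without validation-loss
    improvement and restores the best weights.  Bit-reproducible for a fixed
    seed, data, and initial weights.
    """
    if not ep.normalized:
        raise ValueError("EpochSet must be z-scored before network training")
    if np.unique(ep.labels).size < 2:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(spec.rng_seed)
    x_all = _model_input(model, ep)
    y_all = ep.labels
    train_idx, val_idx = _stratified_split(y_all, spec.validation_fraction, rng)
    x_tr, y_tr = x_all[train_idx], y_all[train_idx]
    x_va, y_va = x_all[val_idx], y_all[val_idx]

    log = TrainingLog(val_indices=val_idx)
    if len(train_idx) < spec.batch_size:
        log.small_batch_warning = True
        logger.info("training set (%d) smaller than batch size (%d); using one batch",
                    len(train_idx), spec.batch_size)

    opt = Adamax(model, lr=spec.learning_rate, decay=spec.lr_decay)
    best_loss, best_weights, wait = np.inf, model.get_weights(), 0
    for epoch_i in range(spec.max_epochs):
        order = rng.permutation(len(train_idx))
        batch_losses = []
        for lo in range(0, len(order), spec.batch_size):
            sel = order[lo:lo + spec.batch_size]
            logits = model.forward(x_tr[sel], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[sel])
            model.backward(dlogits)
            opt.step()
            batch_losses.append(loss)
        log.n_updates = opt.t
        log.train_losses.append(float(np.mean(batch_losses)))
        val_logits = model.forward(x_va, training=False)
        val_loss, _ = softmax_cross_entropy(val_logits, y_va)
        log.val_losses.append(float(val_loss))
        if val_loss < best_loss:
            best_loss, best_weights, wait = val_loss, model.get_weights(), 0
            log.best_epoch = epoch_i
        else:
            wait += 1
            if wait >= spec.early_stopping_patience:
                break
    log.stopped_epoch = epoch_i
    model.set_weights(best_weights)
    return model, log


def predict_proba(model: Sequential, ep: EpochSet) -> np.ndarray:
    """Class probabilities (n_trials, 2); dropout off, rows sum to 1."""
    if not ep.normalized:
        raise ValueError("EpochSet must be z-scored before network inference")
    logits = model.forward(_model_input(model, ep), training=False)
    return softmax(logits)


def predict_labels(model: Sequential, ep: EpochSet) -> np.ndarray:
    return predict_proba(model, ep).argmax(axis=1)
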