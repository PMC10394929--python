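"""Two-phase freeze/unfreeze training of the segmentation network.

Training follows a transfer-learning schedule: during the frozen phase
(epochs [init_epoch, freeze_epoch)) only the representation head is optimized
and the backbone's parameters are left untouched; from ``freeze_epoch`` on,
all parameters train and the batch size drops (the defaults mirror the
standard schedule: freeze for 50 of 300 epochs, batches 16 frozen / 8
unfrozen).  The optimizer is re-created at the phase boundary because the
parameter groups change.  The loss is per-pixel cross-entropy over the two
classes.

The validation partition doubles as the test partition (flagged in the docs as
methodologically weak, but replicated here); both training and validation mIoU
are logged per epoch.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from . import nn
from .hrnet import HRNetSeg
from .nn import Tensor

__all__ = [
    "TrainConfig",
    "EpochPhase",
    "TrainingLog",
    "LoadReport",
    "phase_schedule",
    "load_pretrained_backbone",
    "train",
]

_OPTIMIZER_DEFAULTS = {  # (learning rate, weight decay)
    "adam": (5e-4, 0.0),
    "sgd": (4e-3, 1e-4),
}


@dataclass
class TrainConfig:
    init_epoch: int = 0
    freeze_epoch: int = 50
    freeze_batch: int = 16
    total_epochs: int = 300
    unfreeze_batch: int = 8
    optimizer: str = "adam"
    lr: float | None = None  # None -> per-optimizer default
    weight_decay: float | None = None
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.init_epoch <= self.freeze_epoch <= self.total_epochs:
            raise ValueError("need 0 <= init_epoch <= freeze_epoch <= total_epochs")
        if self.freeze_batch < 1 or self.unfreeze_batch < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.optimizer not in _OPTIMIZER_DEFAULTS:
            raise ValueError(f"optimizer must be one of {sorted(_OPTIMIZER_DEFAULTS)}")
        defaults = _OPTIMIZER_DEFAULTS[self.optimizer]
        if self.lr is None:
            self.lr = defaults[0]
        if self.weight_decay is None:
            self.weight_decay = defaults[1]


@dataclass
class EpochPhase:
    phase: str  # "frozen" | "unfrozen"
    batch_size: int
    trainable_scope: str  # "head-only" | "all"


@dataclass
class TrainingLog:
    records: list = field(default_factory=list)

    def append(self, **kwargs):
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class LoadReport:
    loaded: list
    missing: list
    ignored: list


def phase_schedule(epoch: int, config: TrainConfig) -> EpochPhase:
    """Phase of a given epoch; the freeze boundary is half-open (epoch 50 is unfrozen)."""
    if not config.init_epoch <= epoch < config.total_epochs:
        raise ValueError(
            f"epoch {epoch} outside [{config.init_epoch}, {config.total_epochs})"
        )
    if epoch < config.freeze_epoch:
        return EpochPhase("frozen", config.freeze_batch, "head-only")
    return EpochPhase("unfrozen", config.unfreeze_batch, "all")


def load_pretrained_backbone(weights, network: HRNetSeg) -> LoadReport:
    """Overwrite matching backbone parameters; head parameters keep their init.

    ``weights`` maps parameter paths to arrays.  Keys that match a backbone
    parameter (name and shape) are loaded; backbone parameters without a
    matching key are reported missing; unknown or head keys are reported
    ignored.  Loading nothing at all is a hard error (wrong checkpoint).
    """
    weights = dict(weights)
    backbone = dict(network.backbone_parameters())
    loaded, ignored = [], []
    for key, value in weights.items():
        p = backbone.get(key)
        if p is not None and p.data.shape == np.asarray(value).shape:
            p.data = np.asarray(value, dtype=p.data.dtype).copy()
            loaded.append(key)
        else:
            ignored.append(key)
    missing = [k for k in backbone if k not in loaded]
    if not loaded:
        raise ValueError("no backbone parameter matched the checkpoint (wrong weights?)")
    return LoadReport(loaded=loaded, missing=missing, ignored=ignored)


def _miou(network, samples, ids) -> float:
    scores = []
    for i in ids:
        img, mask = samples[i]
        logits = network(Tensor(img[None])).data[0]
        cm = M.confusion(logits.argmax(axis=0), mask, k=network.config.num_classes)
        scores.append(M.mean_scores(cm).miou)
    return float(np.mean(scores))


def _epoch_loss(network, samples, ids, batch_size, optimizer=None, rng=None):
    order = list(ids)
    if rng is not None:
        order = [order[j] for j in rng.permutation(len(order))]
    losses = []
    for start in range(0, len(order), batch_size):
        chunk = order[start : start + batch_size]
        imgs = np.stack([samples[i][0] for i in chunk])
        masks = np.stack([samples[i][1] for i in chunk])
        loss = nn.softmax_cross_entropy(network(Tensor(imgs)), masks)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite training loss {loss.data!r}; aborting"
            )
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            optimizer.zero_grad()
        losses.append(float(loss.data))
    return float(np.mean(losses))


def _make_optimizer(config: TrainConfig, params):
    if config.optimizer == "adam":
        return nn.Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    return nn.SGD(params, lr=config.lr, momentum=config.momentum,
                  weight_decay=config.weight_decay)


def train(network: HRNetSeg, samples, split, config: TrainConfig) -> TrainingLog:
    """Train under the freeze/unfreeze schedule and log per-epoch metrics.

    ``samples`` maps sample id -> (image, mask) with image (3, H, W) float in
    [0, 1] and mask (H, W) integer labels; ``split`` supplies train/test ids
    (the test partition serves as the validation set).
    """
    if not split.train_ids:
        raise ValueError("training partition is empty")
    log = TrainingLog()
    optimizer = None
    current_scope = None
    for epoch in range(config.init_epoch, config.total_epochs):
        ph = phase_schedule(epoch, config)
        if ph.trainable_scope != current_scope:
            params = (
                [p for _, p in network.head_parameters()]
                if ph.trainable_scope == "head-only"
                else network.parameters()
            )
            optimizer = _make_optimizer(config, params)
            current_scope = ph.trainable_scope
        rng = np.random.default_rng((config.seed, epoch))
        tic = time.perf_counter()
        network.train()
        train_loss = _epoch_loss(
            network, samples, split.train_ids, ph.batch_size, optimizer, rng
        )
        network.eval()
        val_loss = (
            _epoch_loss(network, samples, split.test_ids, ph.batch_size)
            if split.test_ids
            else float("nan")
        )
        val_miou = _miou(network, samples, split.test_ids) if split.test_ids else float("nan")
        train_miou = _miou(network, samples, split.train_ids)
        log.append(
            epoch=epoch,
            phase=ph.phase,
            batch_size=ph.batch_size,
            train_loss=train_loss,
            val_loss=val_loss,
            train_miou=train_miou,
            val_miou=val_miou,
            seconds=time.perf_counter() - tic,
        )
    network.eval()
    return log
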