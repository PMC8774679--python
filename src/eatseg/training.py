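"""Dice-loss training with Adam and the stratified cross-validation harness.

The loss is one minus the mean soft dice over the three foreground classes
(EAT, PAT, HV) — the background channel exists in the softmax but is
excluded from the loss, which is what makes the loss robust to the extreme
foreground/background imbalance of thin fat layers.  Sums run over the whole
batch and all pixels (batch aggregation is stabler than per-sample dice when
EAT is sparse), with a small smoothing term ε = 1e-6.

All randomness (weight init, batch shuffling, augmentation) flows from one
master seed through named substreams, so a fold trains bit-reproducibly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, augment_sample
from .dataio import FoldSplit, MultiFrameSample
from .nets import MultiFrameNet, NetworkConfig, build_network

FOREGROUND_CLASSES = (1, 2, 3)  # EAT, PAT, HV
DICE_EPS = 1e-6


@dataclass
class TrainConfig:
    batch_size: int = 30
    learning_rate: float = 1e-3   # constant across epochs
    epochs: int = 10
    augment: AugmentConfig | None = None
    seed: int = 0
    checkpoint_policy: str = "best-validation-dice"


@dataclass
class TrainRecord:
    fold_id: int
    seed: int
    epoch_train_loss: list[float] = field(default_factory=list)
    epoch_val_dice: list[dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -1.0
    wall_clock_s: float = 0.0


# ---------------------------------------------------------------------------
# dice loss
# ---------------------------------------------------------------------------

def one_hot_targets(targets: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """(N, H, W) integer labels → (N, C, H, W) one-hot float array."""
    n, h, w = targets.shape
    out = np.zeros((n, n_classes, h, w), dtype=np.float64)
    for c in range(n_classes):
        out[:, c] = targets == c
    return out


def _check_probabilities(probs: np.ndarray) -> None:
    if probs.min() < -1e-7 or probs.max() > 1 + 1e-7:
        raise ValueError("probabilities must lie in [0, 1]")


def dice_loss(probs: np.ndarray, targets_onehot: np.ndarray) -> float:
    """1 − mean soft dice over the foreground classes.

    Per class c: (2·Σ p_c t_c + ε) / (Σ p_c + Σ t_c + ε), summed over the
    whole batch and all pixels.
    """
    if probs.shape != targets_onehot.shape:
        raise ValueError("probability and target shapes differ")
    _check_probabilities(probs)
    p = probs.astype(np.float64)
    t = targets_onehot.astype(np.float64)
    dices = []
    for c in FOREGROUND_CLASSES:
        num = 2.0 * (p[:, c] * t[:, c]).sum() + DICE_EPS
        den = p[:, c].sum() + t[:, c].sum() + DICE_EPS
        dices.append(num / den)
    return float(1.0 - np.mean(dices))


def dice_loss_grad(probs: np.ndarray,
                   targets_onehot: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`dice_loss` w.r.t. the probabilities.

    d/dp_c of (2Σpt+ε)/(Σp+Σt+ε) is (2 t·D − N)/D²; background channel 0.
    """
    if probs.shape != targets_onehot.shape:
        raise ValueError("probability and target shapes differ")
    _check_probabilities(probs)
    p = probs.astype(np.float64)
    t = targets_onehot.astype(np.float64)
    grad = np.zeros_like(p)
    k = len(FOREGROUND_CLASSES)
    for c in FOREGROUND_CLASSES:
        num = 2.0 * (p[:, c] * t[:, c]).sum() + DICE_EPS
        den = p[:, c].sum() + t[:, c].sum() + DICE_EPS
        grad[:, c] = -(2.0 * t[:, c] * den - num) / (den**2) / k
    return grad


def hard_dice_per_class(pred_labels: np.ndarray,
                        true_labels: np.ndarray) -> dict[str, float]:
    """Pooled (all pixels of all samples) dice of the argmax segmentation."""
    from .dataio import LABEL_NAMES
    out = {}
    for c in FOREGROUND_CLASSES:
        a = pred_labels == c
        b = true_labels == c
        denom = a.sum() + b.sum()
        out[LABEL_NAMES[c]] = float(
            2.0 * np.logical_and(a, b).sum() / denom) if denom else 1.0
    return out


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64)
                  for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64)
                  for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.value = (p.value.astype(np.float64)
                       - self.lr * update).astype(p.value.dtype)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _subject_set(samples: list[MultiFrameSample]) -> set[str]:
    return {s.subject_id for s in samples}


def _evaluate_dice(net: MultiFrameNet, samples: list[MultiFrameSample],
                   batch_size: int) -> dict[str, float]:
    preds = []
    trues = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        x = np.stack([s.window for s in chunk]).astype(net.dtype)
        probs = net.forward(x, train=False)
        preds.append(np.argmax(probs, axis=1))
        trues.append(np.stack([s.target for s in chunk]))
    return hard_dice_per_class(np.concatenate(preds), np.concatenate(trues))


def train_fold(
    train_samples: list[MultiFrameSample],
    val_samples: list[MultiFrameSample],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    fold_id: int = 0,
) -> tuple[MultiFrameNet, TrainRecord]:
    """Train one fold with Adam at a constant learning rate.

    Augmentation (if configured) is applied per sample on the fly; the
    checkpoint with the best validation foreground mean dice is retained.
    Train and validation subject sets must be disjoint.
    """
    leak = _subject_set(train_samples) & _subject_set(val_samples)
    if leak:
        raise ValueError(f"subject leakage between train and validation: "
                         f"{sorted(leak)}")
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")

    master = np.random.SeedSequence([int(train_config.seed), fold_id])
    init_seed, shuffle_seed, aug_seed = master.spawn(3)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    aug_rng = np.random.default_rng(aug_seed)

    cfg = NetworkConfig(**{**vars(net_config),
                           "seed": int(init_seed.generate_state(1)[0]
                                       % (2**31 - 1))})
    net = build_network(cfg)
    optimizer = Adam(net.params(), lr=train_config.learning_rate)

    record = TrainRecord(fold_id=fold_id, seed=train_config.seed)
    best_state = None
    start_time = time.perf_counter()
    for epoch in range(train_config.epochs):
        order = shuffle_rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            batch = [train_samples[i] for i in idx]
            if train_config.augment is not None:
                batch = [augment_sample(s, train_config.augment, aug_rng)
                         for s in batch]
            x = np.stack([s.window for s in batch]).astype(net.dtype)
            t = one_hot_targets(np.stack([s.target for s in batch]),
                                net_config.n_classes)
            probs = net.forward(x, train=True)
            losses.append(dice_loss(probs, t))
            grad = dice_loss_grad(probs, t)
            net.zero_grad()
            net.backward(grad)
            optimizer.step()
        record.epoch_train_loss.append(float(np.mean(losses)))
        val_dice = _evaluate_dice(net, val_samples, train_config.batch_size)
        record.epoch_val_dice.append(val_dice)
        mean_fg = float(np.mean(list(val_dice.values())))
        if mean_fg > record.best_val_dice:
            record.best_val_dice = mean_fg
            record.best_epoch = epoch
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
    if best_state is not None:
        net.load_state_dict(best_state)
    record.wall_clock_s = time.perf_counter() - start_time
    return net, record


def cross_validate(
    samples_by_subject: dict[str, list[MultiFrameSample]],
    fold_split: FoldSplit,
    net_config: NetworkConfig,
    train_config: TrainConfig,
) -> list[tuple[MultiFrameNet, TrainRecord]]:
    """Train the 4 rotation models of a fold split.

    Test-subset subjects are never seen by any rotation; each non-test
    subject validates exactly once.
    """
    test_ids = set(fold_split.test_subjects)
    results = []
    for fold_id, (train_ids, val_ids) in enumerate(
            fold_split.train_val_assignments):
        if set(train_ids) & test_ids or set(val_ids) & test_ids:
            raise ValueError("test subjects leaked into a training rotation")
        train_samples = [s for sid in train_ids
                         for s in samples_by_subject[sid]]
        val_samples = [s for sid in val_ids for s in samples_by_subject[sid]]
        results.append(train_fold(train_samples, val_samples, net_config,
                                  train_config, fold_id=fold_id))
    return results


def ensemble_probabilities(nets: list[MultiFrameNet],
                           sample: MultiFrameSample) -> np.ndarray:
    """Mean softmax over fold models (the 4-model ensemble output)."""
    x = sample.window[None]
    probs = [net.forward(x.astype(net.dtype), train=False)[0]
             for net in nets]
    return np.mean(probs, axis=0)
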