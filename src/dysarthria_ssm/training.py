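"""Training protocol: speaker-disjoint splits, speaker-block oversampling,
inverse-frequency class weighting, cosine learning-rate schedule with linear
warm-up, AdamW with gradient clipping, and early stopping on validation MCC.

Speaker disjointness is audited on every split, including after
oversampling: all segments of any speaker live in exactly one partition.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .nn import (AdamW, CNNMambaClassifier, Tensor, clip_grad_norm,
                 weighted_cross_entropy)
from .synth import CLASS_ORDER

logger = logging.getLogger(__name__)

DEFAULT_SEEDS = (42, 123, 456)


@dataclass
class TrainConfig:
    batch_size: int = 64
    lr_max: float = 1e-3
    lr_min: float = 1e-6
    weight_decay: float = 0.01
    max_epochs: int = 200
    patience: int = 15
    clip_norm: float = 1.0
    warmup_fraction: float = 0.10
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    balance_target: int | None = None   # segments per class; None = max class

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("batch_size, max_epochs, patience must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not (0 < self.lr_min <= self.lr_max):
            raise ValueError("need 0 < lr_min <= lr_max")


@dataclass
class SplitPlan:
    """speaker_id -> partition name ('fold0'..'fold{k-1}' or train/val/test)."""

    assignment: dict[str, str]
    mode: str                   # "cv5" | "train_val_test"

    def partitions(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for sid, part in self.assignment.items():
            out[part].add(sid)
        return dict(out)

    def check_disjoint(self) -> None:
        parts = list(self.partitions().values())
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                inter = parts[i] & parts[j]
                if inter:
                    raise LeakageError(
                        f"speakers {sorted(inter)} appear in two partitions")


class LeakageError(RuntimeError):
    pass


def make_splits(manifest, k: int = 5, seed: int = 0,
                mode: str = "cv5") -> SplitPlan:
    """Speaker-level stratified assignment into ``k`` folds (or 60/20/20
    train/val/test), keeping every speaker in exactly one partition.

    ``manifest`` needs ``speaker_id`` and ``label`` columns.
    """
    rng = np.random.default_rng(seed)
    spk_label = (manifest[["speaker_id", "label"]]
                 .drop_duplicates("speaker_id"))
    dup = manifest.groupby("speaker_id")["label"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"speakers with multiple labels: {bad}")

    counts = spk_label["label"].value_counts()
    need = k if mode == "cv5" else 3
    low = {c: int(n) for c, n in counts.items() if n < need}
    if low:
        raise ValueError(
            f"too few speakers for {need} partitions in classes {low} "
            f"(per-class counts: {counts.to_dict()})")

    assignment: dict[str, str] = {}
    for label in sorted(spk_label["label"].unique()):
        sids = sorted(spk_label.loc[spk_label["label"] == label, "speaker_id"])
        sids = list(rng.permutation(sids))
        if mode == "cv5":
            for i, sid in enumerate(sids):
                assignment[sid] = f"fold{i % k}"
        elif mode == "train_val_test":
            n = len(sids)
            n_test = max(1, round(0.2 * n))
            n_val = max(1, round(0.2 * n))
            for sid in sids[:n_test]:
                assignment[sid] = "test"
            for sid in sids[n_test:n_test + n_val]:
                assignment[sid] = "val"
            for sid in sids[n_test + n_val:]:
                assignment[sid] = "train"
        else:
            raise ValueError(f"unknown split mode {mode!r}")
    plan = SplitPlan(assignment, mode)
    plan.check_disjoint()
    return plan


def oversample_speaker_blocks(indices: list[int], speakers: list[str],
                              labels: list[str],
                              target_per_class: int | None = None,
                              seed: int = 0) -> list[int]:
    """Balance the *training* partition by duplicating whole speaker blocks.

    Minority-class speakers are duplicated round-robin until each class
    count reaches (within one block of) the target.  Duplicates keep their
    original speaker_id, so the leakage audit still applies.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, dict[str, list[int]]] = defaultdict(lambda: defaultdict(list))
    for i in indices:
        by_class[labels[i]][speakers[i]].append(i)
    counts = {c: sum(len(v) for v in spk.values()) for c, spk in by_class.items()}
    for c, spk in by_class.items():
        if not spk:
            raise ValueError(f"class {c} has zero training speakers")
    target = target_per_class or max(counts.values())
    out = list(indices)
    for c, spk in by_class.items():
        order = list(rng.permutation(sorted(spk)))
        total = counts[c]
        j = 0
        while total < target:
            block = spk[order[j % len(order)]]
            out.extend(block)
            total += len(block)
            j += 1
    return out


def class_weights(labels: list[str] | np.ndarray,
                  class_order: list[str] = CLASS_ORDER) -> np.ndarray:
    """Inverse relative-frequency weights w_i = 1 / f_i."""
    counts = Counter(labels)
    missing = [c for c in class_order if counts[c] == 0]
    if missing:
        raise ValueError(f"classes missing from training labels: {missing}")
    n = len(labels)
    freqs = np.array([counts[c] / n for c in class_order])
    return 1.0 / freqs


def lr_at_step(t: int, total_steps: int, config: TrainConfig) -> float:
    """Linear warm-up to lr_max over the first 10% of steps, then cosine
    annealing to lr_min over the remainder."""
    warmup = max(int(round(config.warmup_fraction * total_steps)), 1)
    if t < warmup:
        return config.lr_max * (t + 1) / warmup
    tt = t - warmup
    T = max(total_steps - warmup, 1)
    return config.lr_min + 0.5 * (config.lr_max - config.lr_min) * (
        1.0 + math.cos(min(tt, T) / T * math.pi))


class EarlyStopper:
    """Stops after ``patience`` epochs without improvement of the metric."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -math.inf
        self.best_epoch = -1
        self.epoch = -1

    def update(self, value: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        self.epoch += 1
        if value > self.best:
            self.best = value
            self.best_epoch = self.epoch
            return False
        return self.epoch - self.best_epoch >= self.patience


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_mcc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


@dataclass
class TrainResult:
    best_state: dict
    best_bn_stats: list[tuple[np.ndarray, np.ndarray]]
    history: TrainHistory
    best_epoch: int
    best_val_mcc: float


def train(model: CNNMambaClassifier,
          X_train: np.ndarray, y_train: np.ndarray,
          X_val: np.ndarray, y_val: np.ndarray,
          config: TrainConfig, seed: int = 42,
          weights: np.ndarray | None = None) -> TrainResult:
    """Train with AdamW + weighted cross-entropy; restore the best-MCC state.

    ``y`` vectors are integer class indices.  Deterministic on CPU for a
    fixed seed (initialization is the model's; shuffling/dropout use
    ``seed``).
    """
    from .evaluation import multiclass_mcc

    rng = np.random.default_rng(seed)
    for blk in model.blocks:
        blk.drop.rng = rng
    model.head_drop.rng = rng

    n = len(X_train)
    steps_per_epoch = max(n // config.batch_size, 1)
    total_steps = steps_per_epoch * config.max_epochs
    opt = AdamW(model.parameters(), lr=config.lr_max,
                weight_decay=config.weight_decay)
    stopper = EarlyStopper(config.patience)
    history = TrainHistory()
    best_state, best_bn = None, None
    step = 0

    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for i in range(steps_per_epoch):
            idx = order[i * config.batch_size:(i + 1) * config.batch_size]
            opt.lr = lr_at_step(step, total_steps, config)
            logits = model(X_train[idx])
            loss = weighted_cross_entropy(logits, y_train[idx], weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {i}: {loss.data}")
            model.zero_grad()
            loss.backward()
            clip_grad_norm(model.parameters(), config.clip_norm)
            opt.step()
            losses.append(float(loss.data))
            step += 1

        proba = model.predict_proba(X_val, batch_size=config.batch_size)
        val_mcc = multiclass_mcc(y_val, np.argmax(proba, axis=1))
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_mcc.append(val_mcc)
        history.lr.append(opt.lr)
        logger.info("epoch %d loss %.4f val MCC %.4f lr %.2e",
                    epoch, history.train_loss[-1], val_mcc, opt.lr)

        improved = val_mcc > stopper.best
        stop = stopper.update(val_mcc)
        if improved or best_state is None:
            best_state = model.state_dict()
            best_bn = [(b.bn.running_mean.copy(), b.bn.running_var.copy())
                       for b in model.blocks]
        if stop:
            break

    model.load_state_dict(best_state)
    for blk, (mu, var) in zip(model.blocks, best_bn):
        blk.bn.running_mean, blk.bn.running_var = mu.copy(), var.copy()
    model.eval()
    return TrainResult(best_state, best_bn, history,
                       stopper.best_epoch, stopper.best)
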