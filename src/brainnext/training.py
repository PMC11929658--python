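"""Momentum-SGD training of the network on a labelled image set.

The recipe is plain: cross-entropy loss, SGD with momentum 0.1 (as printed
in the training recipe this package follows; overridable), initial learning
rate 0.01 held constant, L2 weight decay 1e-4, mini-batch 32, a 70/30
stratified train/validation split, validation every 50 iterations, and the
best-validation checkpoint retained.  Pixel intensities are scaled to [0, 1];
no augmentation is applied.  Everything is seeded and single-threaded NumPy,
so runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from brainnext.architecture import BrainNeXt
from brainnext.errors import ConfigurationError, StratificationError
from brainnext.nn import SGDMomentum, softmax_cross_entropy
from brainnext.patch_features import resize_image
from brainnext.phantoms import ImageItem, LabeledImageSet


@dataclass
class TrainConfig:
    initial_lr: float = 0.01
    momentum: float = 0.1
    epochs: int = 30
    minibatch: int = 32
    l2: float = 1e-4
    val_fraction: float = 0.30
    val_frequency: int = 50       # iterations between validation passes
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ConfigurationError("val_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.minibatch < 1:
            raise ConfigurationError("minibatch must be >= 1")


@dataclass
class EvalRecord:
    iteration: int
    train_loss: float
    train_accuracy: float          # percent
    val_accuracy: float            # percent


@dataclass
class TrainReport:
    records: list[EvalRecord] = field(default_factory=list)
    final_val_accuracy: float = 0.0
    best_val_accuracy: float = 0.0
    checkpoint_path: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "records": [asdict(r) for r in self.records],
            "final_val_accuracy": self.final_val_accuracy,
            "best_val_accuracy": self.best_val_accuracy,
            "checkpoint_path": self.checkpoint_path,
        }, indent=2))


def split_train_val(image_set: LabeledImageSet, fraction: float = 0.30,
                    seed: int = 0) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified, seeded, disjoint train/validation split (fraction = val)."""
    if not image_set.items:
        raise ConfigurationError("empty image set")
    labels = image_set.labels()
    train_items: list[ImageItem] = []
    val_items: list[ImageItem] = []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if len(idx) < 2:
            raise StratificationError(
                f"class {image_set.class_names[c]} has fewer than 2 items")
        rng = np.random.default_rng([seed, int(c)])
        perm = rng.permutation(len(idx))
        n_val = max(1, int(round(len(idx) * fraction)))
        n_val = min(n_val, len(idx) - 1)
        chosen = set(idx[perm[:n_val]].tolist())
        for i in idx:
            (val_items if i in chosen else train_items).append(
                image_set.items[i])
    return (LabeledImageSet(train_items, image_set.class_names),
            LabeledImageSet(val_items, image_set.class_names))


def _to_batch(items: list[ImageItem], size: int) -> np.ndarray:
    arr = np.stack([np.transpose(resize_image(it.image, size), (2, 0, 1))
                    for it in items])
    return arr.astype(np.float32)


def evaluate_accuracy(net: BrainNeXt, image_set: LabeledImageSet,
                      batch: int = 32) -> float:
    """Top-1 accuracy (percent) in evaluation mode."""
    if not image_set.items:
        return 0.0
    correct = 0
    size = net.spec.input_size
    for s in range(0, len(image_set.items), batch):
        chunk = image_set.items[s:s + batch]
        logits = net.forward(_to_batch(chunk, size), train=False)
        pred = logits.argmax(axis=1)
        correct += int((pred == np.array([it.label for it in chunk])).sum())
    return 100.0 * correct / len(image_set.items)


def train(net: BrainNeXt, image_set: LabeledImageSet,
          cfg: TrainConfig | None = None,
          checkpoint_path: str | Path | None = None) -> TrainReport:
    """Train with momentum SGD; retains the best-validation checkpoint.

    Aborts with a diagnostic if the loss becomes non-finite.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    train_set, val_set = split_train_val(image_set, cfg.val_fraction, cfg.seed)
    size = net.spec.input_size
    xs = _to_batch(train_set.items, size)
    ys = train_set.labels()
    n = len(ys)
    opt = SGDMomentum(net.params(), lr=cfg.initial_lr, momentum=cfg.momentum,
                      weight_decay=cfg.l2)
    rng = np.random.default_rng(cfg.seed)
    report = TrainReport()
    best_state = None
    iteration = 0
    last_loss, last_acc = float("nan"), 0.0

    def validate_now() -> None:
        nonlocal best_state
        val_acc = evaluate_accuracy(net, val_set)
        report.records.append(EvalRecord(iteration, last_loss, last_acc,
                                         val_acc))
        if val_acc >= report.best_val_accuracy:
            report.best_val_accuracy = val_acc
            best_state = {k: v.copy() for k, v in net.state_dict().items()}

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for s in range(0, n, cfg.minibatch):
            sel = order[s:s + cfg.minibatch]
            logits = net.forward(xs[sel], train=True)
            loss, dlogits = softmax_cross_entropy(logits, ys[sel])
            if not np.isfinite(loss):
                raise ConfigurationError(
                    f"non-finite loss at iteration {iteration} "
                    f"(lr={cfg.initial_lr})")
            last_loss = loss
            last_acc = 100.0 * float(
                (logits.argmax(axis=1) == ys[sel]).mean())
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            iteration += 1
            if iteration % cfg.val_frequency == 0:
                validate_now()
    validate_now()
    report.final_val_accuracy = report.records[-1].val_accuracy

    if best_state is not None:
        net.load_state_dict(best_state)
    if checkpoint_path is not None:
        checkpoint_path = Path(checkpoint_path)
        net.save(checkpoint_path)
        sidecar = checkpoint_path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "arch": net.spec.to_dict(),
            "train_config": asdict(cfg),
            "final_val_accuracy": report.final_val_accuracy,
            "best_val_accuracy": report.best_val_accuracy,
        }, indent=2))
        report.checkpoint_path = str(checkpoint_path)
    return report
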