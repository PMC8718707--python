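"""Per-class training of memory-augmented autoencoders.

Each heartbeat class gets its own model, trained *only* on beats of that
class by minimizing the reconstruction error; the trained models are then
assembled into an ensemble scored by the minimum-error rule in
:mod:`memae.detector`. Beats are standardized per beat before training so
the same preprocessing is applied at detection time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autoencoder import ArchConfig, ECGBeat, MAEModel, zscore
from .memory import init_memory_bank
from .nn import Adam

__all__ = ["TrainConfig", "TrainLog", "init_model", "train_single_class",
           "train_ensemble", "stack_beats", "desk_scale_config"]


@dataclass
class TrainConfig:
    """Hyperparameters for one-class training.

    Defaults follow the reference protocol: 200 epochs, batch 16, learning
    rate 1e-5, memory capacity 300 with shrinkage threshold 2/N.
    """

    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-5
    memory_capacity: int = 300
    alpha: float | None = None  # defaults to 2/N
    loss_p: int = 2
    seed: int = 0
    memory_bypass: bool = False
    arch: ArchConfig = field(default_factory=ArchConfig)

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 0, batch_size >= 1, learning_rate > 0 required")
        if self.memory_capacity < 1:
            raise ValueError("memory_capacity must be >= 1")
        if self.loss_p not in (1, 2):
            raise ValueError("loss_p must be 1 or 2")
        n = self.memory_capacity
        if self.alpha is not None and not (1.0 / n <= self.alpha <= 3.0 / n):
            raise ValueError(f"alpha must lie in [1/{n}, 3/{n}]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arch"] = {"channels": list(self.arch.channels),
                     "kernel": self.arch.kernel, "stride": self.arch.stride}
        return d


@dataclass
class TrainLog:
    """Per-epoch mean training loss plus the exact configuration used."""

    epoch_losses: list
    seed: int
    config: dict


def desk_scale_config(seed: int = 0, memory_bypass: bool = False) -> TrainConfig:
    """The reduced-budget protocol used for synthetic-data experiments.

    40 epochs at Adam lr 1e-3 instead of the full 200-epoch / 1e-5 reference
    protocol; batch size, memory capacity and shrinkage threshold are
    unchanged. See docs/methods.md for the rationale.
    """
    return TrainConfig(epochs=40, learning_rate=1e-3, seed=seed,
                       memory_bypass=memory_bypass)


def stack_beats(beats: list, normalize: bool = True) -> np.ndarray:
    """Stack equal-shape beats into a (B, C, T) array, z-scoring each."""
    if not beats:
        raise ValueError("empty beat list")
    arrays = []
    shape = None
    for b in beats:
        s = b.samples if isinstance(b, ECGBeat) else np.atleast_2d(np.asarray(b))
        if shape is None:
            shape = s.shape
        elif s.shape != shape:
            raise ValueError(f"inconsistent beat shapes: {s.shape} vs {shape}")
        arrays.append(zscore(s) if normalize else s)
    return np.stack(arrays)


def init_model(config: TrainConfig, input_shape: tuple,
               class_label: str | None = None) -> MAEModel:
    """Seeded construction of an (optionally memory-bypassed) model."""
    c, t = input_shape
    rng = np.random.default_rng(config.seed)
    bank = None
    if not config.memory_bypass:
        bank = init_memory_bank(config.memory_capacity, config.arch.latent_channels,
                                alpha=config.alpha, rng=rng)
    return MAEModel(c, t, bank=bank, arch=config.arch, loss_p=config.loss_p,
                    class_label=class_label, rng=rng)


def train_single_class(beats: list, config: TrainConfig,
                       class_label: str | None = None):
    """Train one model on beats of a single class.

    Returns ``(model, log)``. All beats must carry the same label (or none);
    one "iteration" is one full pass over the data.
    """
    if not beats:
        raise ValueError("no training beats supplied")
    labels = {b.label for b in beats if isinstance(b, ECGBeat) and b.label is not None}
    if len(labels) > 1:
        raise ValueError(f"mixed labels in single-class training set: {sorted(labels)}")
    if class_label is None and labels:
        class_label = labels.pop()

    x = stack_beats(beats)
    model = init_model(config, x.shape[1:], class_label=class_label)
    optimizer = Adam(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    losses = []
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        batch_losses, batch_sizes = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_losses.append(model.training_step(x[idx], optimizer))
            batch_sizes.append(len(idx))
        losses.append(float(np.average(batch_losses, weights=batch_sizes)))
    log = TrainLog(epoch_losses=losses, seed=config.seed, config=config.to_dict())
    return model, log


def train_ensemble(beats: list, config: TrainConfig):
    """Train one model per label and assemble them into a ClassEnsemble.

    Per-class runs derive their seeds deterministically from ``config.seed``
    and the sorted label order.
    """
    from .detector import ClassEnsemble  # local import to avoid a cycle

    by_label: dict = {}
    for b in beats:
        if not isinstance(b, ECGBeat) or b.label is None:
            raise ValueError("train_ensemble requires labelled ECGBeat inputs")
        by_label.setdefault(b.label, []).append(b)
    if len(by_label) < 2:
        raise ValueError("need at least two distinct classes")
    for label, group in by_label.items():
        if not group:
            raise ValueError(f"class {label!r} has no samples")

    models, logs = {}, {}
    for i, label in enumerate(sorted(by_label)):
        cfg = TrainConfig(**{**config.to_dict(),
                             "arch": config.arch,
                             "seed": (config.seed + 7919 * i) % (2 ** 31)})
        models[label], logs[label] = train_single_class(
            by_label[label], cfg, class_label=label)
    return ClassEnsemble(models=models), logs
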