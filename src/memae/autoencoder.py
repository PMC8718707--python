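"""One-class convolutional autoencoder with an optional memory bottleneck.

The encoder is four strided 1-D convolution blocks (conv -> batch norm ->
ReLU, kernel 15, stride 2), so the latent map is 16x shorter than the padded
input. The decoder mirrors it with fractionally-strided convolutions; the
final layer is linear because ECG amplitudes are signed. Between the two, an
optional :class:`~memae.memory.MemoryBank` replaces each latent time-step
with a sparse combination of learned prototypes; with the bank bypassed the
model is a conventional autoencoder (the ablation baseline).

Reconstruction error — mean absolute (p=1) or mean squared (p=2) deviation —
is both the training loss and the detection statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .memory import (
    MemoryBank,
    retrieve_batch_backward,
    retrieve_batch_forward,
)
from .nn import Adam, BatchNorm1d, Conv1d, ConvTranspose1d, ReLU, Sequential

__all__ = [
    "ECGBeat",
    "ArchConfig",
    "MAEModel",
    "reconstruction_error",
    "zscore",
]


@dataclass
class ECGBeat:
    """A fixed-length beat window: ``samples`` is a (channels, length) matrix."""

    samples: np.ndarray
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("beat samples must be finite")

    @property
    def channels(self) -> int:
        return self.samples.shape[0]

    @property
    def length(self) -> int:
        return self.samples.shape[1]


@dataclass
class ArchConfig:
    """Encoder layer widths; the decoder mirrors them in reverse."""

    channels: tuple = (16, 32, 64, 64)
    kernel: int = 15
    stride: int = 2

    @property
    def total_stride(self) -> int:
        return self.stride ** len(self.channels)

    @property
    def latent_channels(self) -> int:
        return self.channels[-1]


def zscore(samples: np.ndarray, sigma_floor: float = 1e-6) -> np.ndarray:
    """Per-beat, per-channel standardization (removes baseline offset and gain)."""
    x = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    mean = x.mean(axis=1, keepdims=True)
    std = np.maximum(x.std(axis=1, keepdims=True), sigma_floor)
    return (x - mean) / std


def reconstruction_error(x: np.ndarray, xhat: np.ndarray, p: int = 2) -> float:
    """Mean elementwise |x - xhat|^p: the detection statistic.

    p=1 is the mean absolute error (L1 loss), p=2 the mean squared error.
    """
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    d = np.abs(x - xhat)
    return float(np.mean(d if p == 1 else d * d))


class MAEModel:
    """One class-specific autoencoder (optionally memory-augmented).

    Parameters
    ----------
    in_channels, input_length : int
        Shape of the beats this model reconstructs.
    bank : MemoryBank or None
        ``None`` bypasses the memory module (plain-autoencoder ablation).
    loss_p : {1, 2}
        Order of the reconstruction error.
    class_label : str, optional
        The single training class this model represents.
    """

    def __init__(self, in_channels: int, input_length: int,
                 bank: MemoryBank | None,
                 arch: ArchConfig | None = None,
                 loss_p: int = 2,
                 class_label: str | None = None,
                 rng: np.random.Generator | None = None) -> None:
        arch = arch or ArchConfig()
        if loss_p not in (1, 2):
            raise ValueError("loss_p must be 1 or 2")
        if input_length < arch.total_stride:
            raise ValueError(
                f"input length {input_length} shorter than total stride {arch.total_stride}")
        if bank is not None and bank.item_dim != arch.latent_channels:
            raise ValueError("memory item dim must equal final encoder channel count")
        self.arch = arch
        self.in_channels = in_channels
        self.input_length = input_length
        self.bank = bank
        self.loss_p = loss_p
        self.class_label = class_label
        self._bank_grad = None if bank is None else np.zeros_like(bank.items)
        rng = np.random.default_rng() if rng is None else rng

        k, s = arch.kernel, arch.stride
        pad = (k - 1) // 2
        enc: list = []
        cin = in_channels
        for cout in arch.channels:
            enc += [Conv1d(cin, cout, k, stride=s, padding=pad, rng=rng),
                    BatchNorm1d(cout), ReLU()]
            cin = cout
        self.encoder = Sequential(enc)

        dec: list = []
        rev = list(arch.channels[::-1])  # e.g. (64, 64, 32, 16)
        outs = rev[1:] + [in_channels]
        cin = rev[0]
        for i, cout in enumerate(outs):
            dec.append(ConvTranspose1d(cin, cout, k, stride=s, padding=pad,
                                       output_padding=s - 1, rng=rng))
            if i < len(outs) - 1:  # final layer linear: signed amplitudes
                dec += [BatchNorm1d(cout), ReLU()]
            cin = cout
        self.decoder = Sequential(dec)

    # ------------------------------------------------------------------
    @property
    def memory_bypassed(self) -> bool:
        return self.bank is None

    def _pad_length(self, t: int) -> int:
        return (-t) % self.arch.total_stride

    def _pad(self, x: np.ndarray) -> np.ndarray:
        """Replicate-pad on the left to the next multiple of the total stride."""
        p = self._pad_length(x.shape[2])
        return np.pad(x, ((0, 0), (0, 0), (p, 0)), mode="edge") if p else x

    @staticmethod
    def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            return x[None], True
        if x.ndim == 3:
            return x, False
        raise ValueError("expected (C, T) or (B, C, T)")

    def encode(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Latent map of shape (C_f, T') — or (B, C_f, T') for a batch."""
        xb, single = self._as_batch(x)
        if xb.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {xb.shape[1]}")
        z = self.encoder.forward(self._pad(xb), training=training)
        return z[0] if single else z

    def retrieve_latent(self, z: np.ndarray) -> np.ndarray:
        """Memory lookup applied independently at each latent time position."""
        if self.bank is None:
            return z
        zb, single = self._as_batch(z)
        b, cf, tp = zb.shape
        queries = zb.transpose(0, 2, 1).reshape(b * tp, cf)
        zhat, _ = retrieve_batch_forward(queries, self.bank)
        out = zhat.reshape(b, tp, cf).transpose(0, 2, 1)
        return out[0] if single else out

    def decode(self, zhat: np.ndarray, target_length: int | None = None,
               training: bool = False) -> np.ndarray:
        zb, single = self._as_batch(zhat)
        if zb.shape[1] != self.arch.latent_channels:
            raise ValueError("latent channel mismatch")
        target_length = self.input_length if target_length is None else target_length
        y = self.decoder.forward(zb, training=training)
        if y.shape[2] < target_length:
            raise ValueError("decoder output shorter than target length")
        y = y[:, :, y.shape[2] - target_length:]  # drop the left replicate-pad
        return y[0] if single else y

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """encode -> memory retrieval -> decode, shape-preserving."""
        xb, single = self._as_batch(x)
        z = self.encode(xb)
        zhat = self.retrieve_latent(z)
        y = self.decode(zhat, target_length=xb.shape[2])
        return y[0] if single else y

    def score(self, x: np.ndarray) -> float:
        """Reconstruction error of one beat under this model."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return reconstruction_error(x, self.reconstruct(x), p=self.loss_p)

    # ------------------------------------------------------------------
    def param_items(self):
        for key, p, g in self.encoder.param_items():
            yield ("enc",) + key, p, g
        for key, p, g in self.decoder.param_items():
            yield ("dec",) + key, p, g
        if self.bank is not None:
            yield ("memory", "items"), self.bank.items, self._bank_grad

    def training_step(self, batch: np.ndarray, optimizer: Adam) -> float:
        """One gradient step on a (B, C, T) batch; returns the batch loss."""
        x = np.asarray(batch, dtype=np.float64)
        b, _, t = x.shape
        xp = self._pad(x)
        z = self.encoder.forward(xp, training=True)
        _, cf, tp = z.shape

        if self.bank is not None:
            queries = z.transpose(0, 2, 1).reshape(b * tp, cf)
            zq, cache = retrieve_batch_forward(queries, self.bank)
            zhat = zq.reshape(b, tp, cf).transpose(0, 2, 1)
        else:
            zhat = z

        y = self.decoder.forward(zhat, training=True)
        crop = y.shape[2] - t
        yc = y[:, :, crop:]
        diff = yc - x
        n = diff.size
        if self.loss_p == 2:
            loss = float(np.mean(diff * diff))
            dyc = 2.0 * diff / n
        else:
            loss = float(np.mean(np.abs(diff)))
            dyc = np.sign(diff) / n
        dy = np.zeros_like(y)
        dy[:, :, crop:] = dyc

        dzhat = self.decoder.backward(dy)
        if self.bank is not None:
            dq = dzhat.transpose(0, 2, 1).reshape(b * tp, cf)
            dqueries, d_items = retrieve_batch_backward(dq, cache, self.bank)
            self._bank_grad = d_items
            dz = dqueries.reshape(b, tp, cf).transpose(0, 2, 1)
        else:
            dz = dzhat
        self.encoder.backward(dz)
        optimizer.step(self.param_items())
        return loss

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        state: dict = {
            "meta:in_channels": self.in_channels,
            "meta:input_length": self.input_length,
            "meta:loss_p": self.loss_p,
            "meta:channels": np.asarray(self.arch.channels),
            "meta:kernel": self.arch.kernel,
            "meta:stride": self.arch.stride,
            "meta:class_label": self.class_label or "",
            "meta:has_bank": self.bank is not None,
        }
        for stack, name in ((self.encoder, "enc"), (self.decoder, "dec")):
            for i, layer in enumerate(stack.layers):
                for pname, val in layer.params.items():
                    state[f"{name}:{i}:{pname}"] = val
                if isinstance(layer, BatchNorm1d):
                    state[f"{name}:{i}:running_mean"] = layer.running_mean
                    state[f"{name}:{i}:running_var"] = layer.running_var
        if self.bank is not None:
            state["bank:items"] = self.bank.items
            state["bank:alpha"] = self.bank.alpha
            state["bank:epsilon"] = self.bank.epsilon
        return state

    def save(self, path) -> None:
        np.savez(path, **{k: np.asarray(v) for k, v in self.state_dict().items()})

    @classmethod
    def load(cls, path) -> "MAEModel":
        with np.load(path, allow_pickle=False) as data:
            arch = ArchConfig(channels=tuple(int(c) for c in data["meta:channels"]),
                              kernel=int(data["meta:kernel"]),
                              stride=int(data["meta:stride"]))
            bank = None
            if bool(data["meta:has_bank"]):
                bank = MemoryBank(items=data["bank:items"],
                                  alpha=float(data["bank:alpha"]),
                                  epsilon=float(data["bank:epsilon"]))
            label = str(data["meta:class_label"]) or None
            model = cls(int(data["meta:in_channels"]), int(data["meta:input_length"]),
                        bank=bank, arch=arch, loss_p=int(data["meta:loss_p"]),
                        class_label=label, rng=np.random.default_rng(0))
            for stack, name in ((model.encoder, "enc"), (model.decoder, "dec")):
                for i, layer in enumerate(stack.layers):
                    for pname in layer.params:
                        layer.params[pname][...] = data[f"{name}:{i}:{pname}"]
                    if isinstance(layer, BatchNorm1d):
                        layer.running_mean[...] = data[f"{name}:{i}:running_mean"]
                        layer.running_var[...] = data[f"{name}:{i}:running_var"]
        return model
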