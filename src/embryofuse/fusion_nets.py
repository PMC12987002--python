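"""U-Net fusion networks distilled from Laplacian-pyramid fusion.

Three variants share one skeleton — a 3-stage encoder (64 -> 128 -> 256
channels, 2x max-pool between stages), a 512-channel bottleneck, and a
decoder with channel-concatenation skip connections, closed by a 1-channel
convolution with a sigmoid:

* ``DC`` — double Conv-BatchNorm-ReLU units per stage (high capacity);
* ``SC`` — single Conv-BatchNorm-ReLU units (lightweight);
* ``AFU`` — SC-style encoder plus an attention-gated bottleneck
  (channel layer-norm -> 1x1 conv -> sigmoid gate, applied multiplicatively).

The seven focal planes enter stacked channel-wise in F-3..F+3 order; the
training objective is the pixel mean-squared error against the classical
Laplacian fusion of the same stack, so the networks learn to replicate the
per-coefficient max-abs selection rule end-to-end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from embryofuse import nn
from embryofuse.phantom import FocalStack, LabeledDataset
from embryofuse.pyramid import fuse_lp

__all__ = [
    "FusionModelConfig",
    "TrainingRun",
    "UNetFusion",
    "build_fusion_model",
    "mse_loss",
    "train_fusion",
    "fuse_neural",
    "save_fusion_model",
    "load_fusion_model",
]

VARIANTS = ("DC", "SC", "AFU")


@dataclass(frozen=True)
class FusionModelConfig:
    variant: str = "SC"
    in_channels: int = 7
    out_channels: int = 1
    encoder_widths: tuple[int, int, int] = (64, 128, 256)
    bottleneck_width: int = 512

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown fusion variant {self.variant!r}; expected one of {VARIANTS}")
        if self.in_channels != 7:
            raise ValueError("fusion networks consume exactly 7 focal planes")


@dataclass
class TrainingRun:
    epoch_losses: list[float] = field(default_factory=list)
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)


def _conv_block(cin: int, cout: int, rng, double: bool) -> nn.Sequential:
    layers = [nn.Conv2d(cin, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU()]
    if double:
        layers += [nn.Conv2d(cout, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU()]
    return nn.Sequential(*layers)


class _AttentionGate(nn.Module):
    """Channel layer-norm -> 1x1 conv -> sigmoid, applied as a multiplicative gate."""

    def __init__(self, channels: int, rng):
        self.norm = nn.LayerNorm(channels)
        self.conv = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x):
        normed = self.norm(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
        return x * self.conv(normed).sigmoid()


class UNetFusion(nn.Module):
    def __init__(self, config: FusionModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 613]))
        double = config.variant == "DC"
        w1, w2, w3 = config.encoder_widths
        wb = config.bottleneck_width

        self.enc1 = _conv_block(config.in_channels, w1, rng, double)
        self.enc2 = _conv_block(w1, w2, rng, double)
        self.enc3 = _conv_block(w2, w3, rng, double)
        self.pool = nn.MaxPool2d()
        self.bottleneck = _conv_block(w3, wb, rng, double)
        self.attention = _AttentionGate(wb, rng) if config.variant == "AFU" else nn.Identity()
        self.up = nn.UpsampleNearest2x()
        self.up3 = nn.Conv2d(wb, w3, 3, rng)
        self.dec3 = _conv_block(2 * w3, w3, rng, double)
        self.up2 = nn.Conv2d(w3, w2, 3, rng)
        self.dec2 = _conv_block(2 * w2, w2, rng, double)
        self.up1 = nn.Conv2d(w2, w1, 3, rng)
        self.dec1 = _conv_block(2 * w1, w1, rng, double)
        self.head = nn.Conv2d(w1, config.out_channels, 1, rng)

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input channels, got {c}")
        if h % 8 or w % 8:
            raise ValueError(
                f"spatial dims must be divisible by 8 (three pooling stages), got {h}x{w}"
            )
        e1 = self.enc1(x)
        e2 = self.enc2(self.pool(e1))
        e3 = self.enc3(self.pool(e2))
        b = self.attention(self.bottleneck(self.pool(e3)))
        d3 = self.dec3(nn.concat([self.up3(self.up(b)), e3], axis=1))
        d2 = self.dec2(nn.concat([self.up2(self.up(d3)), e2], axis=1))
        d1 = self.dec1(nn.concat([self.up1(self.up(d2)), e1], axis=1))
        return self.head(d1).sigmoid()


def build_fusion_model(config: FusionModelConfig, seed: int = 0) -> UNetFusion:
    """Construct a seeded, randomly initialized fusion network."""
    return UNetFusion(config, seed=seed)


def mse_loss(pred, target):
    """Mean over all pixels of squared differences.

    Accepts numpy arrays (returns a float) or autograd tensors (returns a
    scalar tensor usable as a training loss).
    """
    if isinstance(pred, nn.Tensor) or isinstance(target, nn.Tensor):
        p = nn.Tensor.as_tensor(pred)
        t = nn.Tensor.as_tensor(target)
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
        diff = p - t
        return (diff * diff).mean()
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def _stack_input(stack: FocalStack) -> np.ndarray:
    return np.asarray(stack.planes, dtype=np.float32)


def distillation_pairs(dataset: LabeledDataset, split: str = "train",
                       n_levels: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """(inputs, targets) arrays: channel-stacked planes and their LP fusions."""
    items = dataset.subset(split)
    if not items:
        raise ValueError(f"dataset split {split!r} is empty")
    x = np.stack([_stack_input(item.stack) for item in items])
    y = np.stack([fuse_lp(item.stack, n_levels)[None].astype(np.float32) for item in items])
    return x, y


def _augment_pair(x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Seeded dihedral augmentation applied jointly to stack and target."""
    k = int(rng.integers(0, 4))
    if k:
        x = np.rot90(x, k, axes=(1, 2))
        y = np.rot90(y, k, axes=(1, 2))
    if rng.integers(0, 2):
        x = x[:, :, ::-1]
        y = y[:, :, ::-1]
    return np.ascontiguousarray(x), np.ascontiguousarray(y)


def train_fusion(model: UNetFusion, dataset: LabeledDataset, epochs: int,
                 lr: float = 1e-3, seed: int = 0, batch_size: int = 8,
                 n_levels: int = 4, augment: bool = True) -> TrainingRun:
    """Distill Laplacian-pyramid fusion into ``model`` on the train split.

    Targets are the LP fusions of the training stacks; the loss is the pixel
    MSE.  With ``augment`` each sample receives a seeded random rotation/flip
    (applied jointly to stack and target) every epoch, which multiplies the
    effective variety of a desk-scale training set eightfold.  Data order,
    augmentation draws and optimizer state are pure functions of ``seed``, so
    a rerun reproduces the loss history bit for bit.  ``epochs=0`` returns an
    empty history and leaves the model untouched.
    """
    run = TrainingRun(seed=seed, hyperparameters={
        "epochs": epochs, "lr": lr, "batch_size": batch_size,
        "n_levels": n_levels, "augment": augment,
    })
    if epochs == 0:
        return run
    x, y = distillation_pairs(dataset, "train", n_levels)
    square = x.shape[-2] == x.shape[-1]
    opt = nn.Adam(model.parameters(), lr=lr)
    model.train()
    for epoch in range(epochs):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, 29, epoch]))
        order = rng.permutation(len(x))
        total, count = 0.0, 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            if augment and square:
                pairs = [_augment_pair(xi, yi, rng) for xi, yi in zip(xb, yb)]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs])
            pred = model(nn.Tensor(xb))
            loss = mse_loss(pred, nn.Tensor(yb))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            count += len(idx)
        run.epoch_losses.append(total / count)
    return run


def fuse_neural(model: UNetFusion, stack: FocalStack) -> np.ndarray:
    """Fuse a 7-plane stack with a (trained or untrained) network."""
    x = _stack_input(stack)[None]
    model.eval()
    with nn.no_grad():
        out = model(nn.Tensor(x))
    model.train()
    return out.data[0, 0].astype(np.float64)


def save_fusion_model(model: UNetFusion, path) -> None:
    arrays = model.state_arrays()
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:  # file handle keeps the exact filename
        np.savez_compressed(fh, **arrays)


def load_fusion_model(path) -> UNetFusion:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"].tobytes()).decode())
        cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
        model = UNetFusion(FusionModelConfig(**cfg_dict))
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model
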