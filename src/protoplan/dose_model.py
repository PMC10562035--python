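"""3D U-Net dose prediction: architecture, training, inference.

The network maps 4 binary ROI-mask channels (targets, lungs,
heart+esophagus, external) to one Rx-normalized dose volume.  Structure is
the classic encoder-decoder with concatenation skip connections: two 3x3x3
"same" convolutions per level, 2x max pooling down, stride-2 transposed
convolution up, ReLU after every convolution except the last, and a final
1x1x1 projection.

Two named configurations ship with the package:

* ``FULL_SCALE_CONFIG`` — channel widths (21, 37, 167), chosen by exhaustive
  calibration (see ``scripts/calibrate_unet.py``) so that the total
  trainable parameter count is exactly 1,194,857; built for the
  200 x 160 x 224 voxel clinical lattice.  Constructible and countable on
  any machine; training it is not a desk-scale activity.
* ``DESK_CONFIG`` — widths (8, 16, 32) for the 32 x 32 x 48 lattice at 5 mm,
  CPU-trainable in minutes.

Training follows the usual regression recipe: Adam (lr 1e-3, default
moments), batch size 1, voxel-wise L1 loss, and best-epoch selection on a
held-out validation split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .grid_core import DoseGrid

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "UNet3d",
    "build_unet",
    "count_parameters",
    "train",
    "predict_dose",
    "FULL_SCALE_CONFIG",
    "DESK_CONFIG",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``level_channels`` gives the feature width at each resolution level from
    finest to coarsest; its length minus one is the number of poolings.
    """

    in_channels: int = 4
    out_channels: int = 1
    level_channels: tuple[int, ...] = (8, 16, 32)
    convs_per_level: int = 2
    final_kernel: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.level_channels) < 2:
            raise ValueError("need at least one pooling level")
        if any(c <= 0 for c in self.level_channels):
            raise ValueError("channel counts must be positive")
        if self.convs_per_level < 1:
            raise ValueError("convs_per_level must be >= 1")

    @property
    def depth(self) -> int:
        return len(self.level_channels) - 1


FULL_SCALE_CONFIG = UNetConfig(level_channels=(21, 37, 167))
DESK_CONFIG = UNetConfig(level_channels=(8, 16, 32))


@dataclass
class TrainConfig:
    """Optimization settings: Adam at lr 1e-3, batch size 1, L1 loss."""

    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


class UNet3d:
    """Encoder-decoder network assembled from :mod:`protoplan.nn` layers."""

    def __init__(self, config: UNetConfig = DESK_CONFIG):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.level_channels
        d = config.depth

        def block(cin, cout):
            layers = []
            prev = cin
            for _ in range(config.convs_per_level):
                layers.append(nn.Conv3d(prev, cout, 3, rng))
                layers.append(nn.ReLU())
                prev = cout
            return layers

        self.enc_blocks = []
        prev = config.in_channels
        for lvl in range(d):
            self.enc_blocks.append(block(prev, ch[lvl]))
            prev = ch[lvl]
        self.pools = [nn.MaxPool3d() for _ in range(d)]
        self.bottleneck = block(prev, ch[d])
        self.ups = []
        self.dec_blocks = []
        prev = ch[d]
        for lvl in range(d - 1, -1, -1):
            self.ups.append(nn.ConvTranspose3d(prev, ch[lvl], rng))
            self.dec_blocks.append(block(2 * ch[lvl], ch[lvl]))
            prev = ch[lvl]
        self.final = nn.Conv3d(prev, config.out_channels, config.final_kernel, rng)

    # -- plumbing ----------------------------------------------------------
    @property
    def params(self) -> list[nn.Param]:
        out = []
        for blk in self.enc_blocks + [self.bottleneck] + self.dec_blocks:
            for layer in blk:
                out.extend(layer.params)
        for up in self.ups:
            out.extend(up.params)
        out.extend(self.final.params)
        return out

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected ({self.config.in_channels}, X, Y, Z) input, got {x.shape}"
            )
        f = 2**self.config.depth
        if any(s % f for s in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be divisible by 2^depth = {f}"
            )

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_shape(x)
        h = np.asarray(x, dtype=np.float32)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                h = layer.forward(h)
            skips.append(h)
            h = pool.forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[0])
            h = np.concatenate([skip, h], axis=0)
            for layer in blk:
                h = layer.forward(h)
        return self.final.forward(h)

    def backward(self, dout: np.ndarray) -> None:
        d = self.final.backward(dout)
        dskips = []
        for up, blk, nskip in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(self._skip_channels)
        ):
            for layer in reversed(blk):
                d = layer.backward(d)
            dskips.append(d[:nskip])
            d = up.backward(d[nskip:])
        for layer in reversed(self.bottleneck):
            d = layer.backward(d)
        # dskips were collected finest level first; the encoder unwinds from
        # the coarsest level, so consume them in reverse
        for blk, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d) + dskip
            for layer in reversed(blk):
                d = layer.backward(d)

    __call__ = forward


def build_unet(config: UNetConfig = DESK_CONFIG, input_shape=None) -> UNet3d:
    """Construct the network; if ``input_shape`` is given, validate its
    divisibility by ``2**depth`` immediately."""
    model = UNet3d(config)
    if input_shape is not None:
        f = 2**config.depth
        if any(int(s) % f for s in input_shape):
            raise ValueError(
                f"input shape {tuple(input_shape)} not divisible by 2^depth = {f}"
            )
    return model


def count_parameters(model: UNet3d | None) -> int:
    """Total number of trainable scalar parameters (weights + biases)."""
    if model is None:
        return 0
    return int(sum(p.size for p in model.params))


@dataclass
class TrainResult:
    model: UNet3d  # weights restored to the best-validation epoch
    train_losses: np.ndarray  # per-epoch mean training L1
    val_losses: np.ndarray  # per-epoch mean validation L1
    best_epoch: int  # argmin of val_losses (0-based)


def train(
    model: UNet3d,
    train_pairs: list[tuple[np.ndarray, np.ndarray]],
    val_pairs: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Fit the network on (mask channels, Rx-normalized dose) pairs.

    Batch size is 1; one epoch is one seeded-shuffled pass over the training
    pairs.  Validation loss is evaluated after each epoch and the parameter
    snapshot at its argmin is restored into the returned model.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("need at least one training and one validation pair")
    for _, target in train_pairs + val_pairs:
        if np.asarray(target).max() > 1.2 * 1.5:
            warnings.warn(
                "training target maximum far above 1: doses should be Rx-normalized",
                stacklevel=2,
            )
            break

    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    train_losses, val_losses = [], []
    best_state, best_epoch, best_val = None, -1, np.inf
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_pairs)) if cfg.shuffle else np.arange(len(train_pairs))
        epoch_loss = 0.0
        for idx in order:
            x, y = train_pairs[idx]
            pred = model.forward(np.asarray(x, dtype=np.float32))
            loss, grad = nn.l1_loss(pred, np.asarray(y, dtype=np.float32))
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss
        train_losses.append(epoch_loss / len(train_pairs))

        vloss = 0.0
        for x, y in val_pairs:
            pred = model.forward(np.asarray(x, dtype=np.float32))
            vloss += float(np.abs(pred - np.asarray(y, dtype=np.float32)).mean())
        vloss /= len(val_pairs)
        val_losses.append(vloss)
        if vloss < best_val:
            best_val, best_epoch, best_state = vloss, epoch, model.state_dict()

    model.load_state(best_state)
    return TrainResult(
        model=model,
        train_losses=np.asarray(train_losses),
        val_losses=np.asarray(val_losses),
        best_epoch=best_epoch,
    )


def predict_dose(
    model: UNet3d,
    channels: np.ndarray,
    rx: float,
    spacing=(2.5, 2.5, 2.5),
    origin=(0.0, 0.0, 0.0),
) -> DoseGrid:
    """Run inference and denormalize to Gy; negative outputs are clamped to
    zero (the network head is unconstrained)."""
    if rx <= 0:
        raise ValueError("rx must be > 0")
    out = model.forward(np.asarray(channels, dtype=np.float32))
    if out.shape[0] != 1:
        raise ValueError("dose model must have a single output channel")
    dose = np.maximum(out[0].astype(np.float64), 0.0) * float(rx)
    return DoseGrid(dose, spacing, origin)


# ---------------------------------------------------------------------------
# checkpoints: npz weights + sidecar JSON with configs and provenance
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    model: UNet3d,
    train_cfg: TrainConfig | None = None,
    best_epoch: int | None = None,
) -> None:
    path = Path(path)
    np.savez_compressed(path, *[p.value for p in model.params])
    sidecar = {
        "unet": {
            "in_channels": model.config.in_channels,
            "out_channels": model.config.out_channels,
            "level_channels": list(model.config.level_channels),
            "convs_per_level": model.config.convs_per_level,
            "final_kernel": model.config.final_kernel,
            "seed": model.config.seed,
        },
        "train": None
        if train_cfg is None
        else {
            "epochs": train_cfg.epochs,
            "learning_rate": train_cfg.learning_rate,
            "seed": train_cfg.seed,
            "shuffle": train_cfg.shuffle,
        },
        "best_epoch": best_epoch,
        "parameter_count": count_parameters(model),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[UNet3d, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    u = sidecar["unet"]
    config = UNetConfig(
        in_channels=u["in_channels"],
        out_channels=u["out_channels"],
        level_channels=tuple(u["level_channels"]),
        convs_per_level=u["convs_per_level"],
        final_kernel=u["final_kernel"],
        seed=u["seed"],
    )
    model = UNet3d(config)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        state = [data[k] for k in data.files]
    model.load_state(state)
    return model, sidecar
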