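"""U-Net segmentation of gland regions, with the study's parameter grid.

The network is the canonical encoder-decoder with skip connections: each
encoder level applies two 3x3 convolutions with ReLU and then halves the
spatial size by 2x2 max pooling; the number of kernels is ``base_kernels``
at the first level and doubles at every deeper level; the decoder mirrors
the encoder with 2x2 transposed-convolution upsampling and concatenated
skip features; a final 1x1 convolution produces a per-pixel foreground
logit. ``depth`` counts the downsampling steps, so a 256-pixel input with
depth 6 reaches a 4-pixel bottleneck.

The tunable grid is depth in {3..7}, learning rate in {0.001, 0.0001} and
batch size in {16, 32} (20 combinations), each trained in triplicate.
Training uses Adam and binary cross-entropy by default (soft Dice loss is
available), keeps the weights of the epoch with the best validation Dice,
and is fully seeded.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .evaluation import dice_with_unmasked_rule
from .images import Mammogram, ValidationError

__all__ = [
    "UNetConfig",
    "UNet",
    "TrainRecord",
    "build_unet",
    "train",
    "predict",
    "run_grid",
    "grid_report",
    "standard_grid",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class UNetConfig:
    """One cell of the parameter grid plus training settings."""

    depth: int = 3
    learning_rate: float = 1e-4
    batch_size: int = 16
    base_kernels: int = 64
    epochs: int = 50
    seed: int = 0
    loss: str = "bce"  # "bce" | "dice"
    norm: str = "batch"  # "batch" | "none"
    optimizer: str = "sgd"  # "sgd" (momentum) | "adam"
    momentum: float = 0.9
    lr_schedule: str = "linear"  # "linear" (decay to 10%) | "constant"
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError(f"depth must be >= 1, got {self.depth}")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.base_kernels < 1 or self.epochs < 1:
            raise ValidationError("batch_size, base_kernels and epochs must be >= 1")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValidationError(
                f"binarize_threshold must be in (0, 1), got {self.binarize_threshold}"
            )
        if self.loss not in ("bce", "dice"):
            raise ValidationError(f"loss must be 'bce' or 'dice', got {self.loss!r}")
        if self.norm not in ("batch", "none"):
            raise ValidationError(f"norm must be 'batch' or 'none', got {self.norm!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValidationError(
                f"optimizer must be 'sgd' or 'adam', got {self.optimizer!r}"
            )
        if self.lr_schedule not in ("linear", "constant"):
            raise ValidationError(
                f"lr_schedule must be 'linear' or 'constant', got {self.lr_schedule!r}"
            )

    def encoder_channels(self) -> list[int]:
        """Kernel counts of the encoder levels (doubling per level)."""
        return [self.base_kernels * 2**k for k in range(self.depth)]


class _DoubleConv:
    """Two 3x3 conv (+ optional batch norm) + ReLU stages (one level)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, norm: str = "batch"):
        self.layers = []
        for cin in (c_in, c_out):
            self.layers.append(nn.Conv3x3(cin, c_out, rng))
            if norm == "batch":
                self.layers.append(nn.BatchNorm(c_out))
            self.layers.append(nn.ReLU())

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class UNet:
    """Numpy U-Net mapping a 1-channel image to per-pixel foreground
    probabilities of the same spatial size."""

    def __init__(self, cfg: UNetConfig, in_channels: int = 1):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chs = cfg.encoder_channels()
        bottleneck_ch = cfg.base_kernels * 2**cfg.depth

        self.enc: list[_DoubleConv] = []
        c_prev = in_channels
        for c in chs:
            self.enc.append(_DoubleConv(c_prev, c, rng, cfg.norm))
            c_prev = c
        self.pools = [nn.MaxPool2() for _ in chs]
        self.bottleneck = _DoubleConv(c_prev, bottleneck_ch, rng, cfg.norm)

        self.upconvs: list[nn.UpConv2] = []
        self.dec: list[_DoubleConv] = []
        c_prev = bottleneck_ch
        for c in reversed(chs):
            self.upconvs.append(nn.UpConv2(c_prev, c, rng))
            self.dec.append(_DoubleConv(2 * c, c, rng, cfg.norm))
            c_prev = c
        self.head = nn.Conv1x1(chs[0], 1, rng, zero_init=True)

    # -- parameters ---------------------------------------------------
    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for up, block in zip(self.upconvs, self.dec):
            out += up.params() + block.params()
        out += self.head.params()
        return out

    @property
    def num_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def _norm_layers(self) -> list[nn.BatchNorm]:
        blocks = [*self.enc, self.bottleneck, *self.dec]
        return [
            layer
            for block in blocks
            for layer in block.layers
            if isinstance(layer, nn.BatchNorm)
        ]

    def set_training(self, training: bool) -> None:
        for bn in self._norm_layers():
            bn.training = training

    def get_weights(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for bn in self._norm_layers():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        for p, w in zip(params, weights):
            p.value[...] = w
        rest = weights[len(params):]
        for bn, mean, var in zip(self._norm_layers(), rest[0::2], rest[1::2]):
            bn.running_mean = mean.copy()
            bn.running_var = var.copy()

    # -- forward/backward ---------------------------------------------
    def _check_size(self, h: int, w: int) -> None:
        f = 1 << self.cfg.depth
        if h % f or w % f:
            raise ValidationError(
                f"input size {h}x{w} not divisible by 2^depth = {f}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W) or (N, H, W, 1) float32 in [0, 1] -> logits (N, H, W)."""
        if x.ndim == 3:
            x = x[..., None]
        x = x.astype(np.float32, copy=False)
        self._check_size(x.shape[1], x.shape[2])
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, block, skip in zip(self.upconvs, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=-1)
            self._skip_channels.append(skip.shape[-1])
            x = block.forward(x)
        z = self.head.forward(x)
        return z[..., 0]

    def backward(self, dz: np.ndarray) -> None:
        d = self.head.backward(dz[..., None].astype(np.float32, copy=False))
        dskips = []
        for up, block, c_skip in zip(
            reversed(self.upconvs), reversed(self.dec), reversed(self._skip_channels)
        ):
            d = block.backward(d)
            dskip, dup = d[..., :c_skip], d[..., c_skip:]
            dskips.append(dskip)
            d = up.backward(np.ascontiguousarray(dup))
        d = self.bottleneck.backward(d)
        for pool, block, dskip in zip(
            reversed(self.pools), reversed(self.enc), reversed(dskips)
        ):
            d = pool.backward(d)
            d = block.backward(d + dskip)

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Foreground probability maps (inference mode), minibatched."""
        single = x.ndim == 2
        if single:
            x = x[None]
        self.set_training(False)
        try:
            out = np.empty(x.shape[:3], dtype=np.float32)
            for i in range(0, x.shape[0], batch_size):
                out[i : i + batch_size] = nn.sigmoid(self.forward(x[i : i + batch_size]))
        finally:
            self.set_training(True)
        return out[0] if single else out


def build_unet(cfg: UNetConfig, in_channels: int = 1) -> UNet:
    """Construct a U-Net with seeded He initialisation (zero-initialised
    output head). Same config and seed give identical initial weights."""
    return UNet(cfg, in_channels=in_channels)


@dataclass
class TrainRecord:
    """Outcome of one training run (one grid cell, one replicate)."""

    config: UNetConfig
    replicate: int = 1
    dataset: str = ""
    epoch_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    best_epoch: int = -1
    test_dice: float | None = None
    failed: bool = False
    error: str = ""

    @property
    def best_val_dice(self) -> float:
        return self.val_dice[self.best_epoch] if self.val_dice else float("nan")


def _as_input(images) -> np.ndarray:
    """Stack images as float32 in [0, 1]; Mammograms are scaled by their
    bit depth, integer arrays by their dtype range."""
    arrs = []
    for im in images:
        if isinstance(im, Mammogram):
            arrs.append(np.asarray(im.pixels, dtype=np.float32) / im.max_value)
        else:
            a = np.asarray(im)
            if a.dtype.kind in "ui":
                a = a.astype(np.float32) / np.iinfo(a.dtype).max
            arrs.append(a.astype(np.float32, copy=False))
    return np.stack(arrs)


def _mean_val_dice(model: UNet, X: np.ndarray, Y: np.ndarray, thr: float) -> float:
    proba = model.predict_proba(X)
    scores = [
        dice_with_unmasked_rule(Y[i], proba[i] >= thr)[0] for i in range(len(Y))
    ]
    return float(np.mean(scores))


def train(
    model: UNet,
    train_set: tuple,
    val_set: tuple,
    cfg: UNetConfig | None = None,
    replicate: int = 1,
    dataset: str = "",
) -> TrainRecord:
    """Mini-batch Adam training with best-validation-Dice checkpointing.

    ``train_set``/``val_set`` are ``(images, masks)`` pairs; images may be
    Mammograms or arrays (scaled to [0, 1] automatically), masks boolean.
    After training, the model holds the weights of the epoch whose
    validation Dice was highest.
    """
    cfg = cfg or model.cfg
    if len(train_set[0]) == 0:
        raise ValidationError("training set is empty")
    X, Y = _as_input(train_set[0]), np.stack([np.asarray(m, bool) for m in train_set[1]])
    Xv, Yv = _as_input(val_set[0]), np.stack([np.asarray(m, bool) for m in val_set[1]])
    if X.shape[0] == 0:
        raise ValidationError("training set is empty")
    loss_fn = nn.bce_with_logits if cfg.loss == "bce" else nn.soft_dice_loss

    rng = np.random.default_rng([cfg.seed, replicate, 0x5E6])
    params = model.params()
    if cfg.optimizer == "sgd":
        opt = nn.SGD(params, lr=cfg.learning_rate, momentum=cfg.momentum)
    else:
        opt = nn.Adam(params, lr=cfg.learning_rate)
    record = TrainRecord(config=cfg, replicate=replicate, dataset=dataset)
    best_weights = model.get_weights()
    best_dice = -np.inf

    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "linear" and cfg.epochs > 1:
            # anneal the nominal rate linearly down to 10% by the last epoch
            opt.lr = cfg.learning_rate * (1.0 - 0.9 * epoch / (cfg.epochs - 1))
        order = rng.permutation(X.shape[0])
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z = model.forward(X[idx])
            loss, dz = loss_fn(z, Y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch + 1}; "
                    f"lr={cfg.learning_rate}, loss={cfg.loss}"
                )
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        record.epoch_loss.append(float(np.mean(losses)))
        vd = _mean_val_dice(model, Xv, Yv, cfg.binarize_threshold)
        record.val_dice.append(vd)
        if vd > best_dice:
            best_dice = vd
            best_weights = model.get_weights()
            record.best_epoch = epoch

    model.set_weights(best_weights)
    return record


def predict(model: UNet, image, binarize_threshold: float | None = None) -> np.ndarray:
    """Binary gland mask for one preprocessed image (Mammogram or array)."""
    thr = model.cfg.binarize_threshold if binarize_threshold is None else binarize_threshold
    x = _as_input([image])[0]
    model._check_size(*x.shape)
    return model.predict_proba(x) >= thr


# ---------------------------------------------------------------------------
# Parameter grid
# ---------------------------------------------------------------------------

def standard_grid(
    depths=(3, 4, 5, 6, 7),
    learning_rates=(1e-3, 1e-4),
    batch_sizes=(16, 32),
    **common,
) -> list[UNetConfig]:
    """Enumerate the full parameter grid (5 x 2 x 2 = 20 cells by default).

    Extra keyword arguments (epochs, base_kernels, seed, ...) are applied
    to every cell."""
    return [
        UNetConfig(depth=d, learning_rate=lr, batch_size=b, **common)
        for d in depths
        for lr in learning_rates
        for b in batch_sizes
    ]


def run_grid(
    grid: list[UNetConfig],
    datasets: dict[str, dict],
    replicates: int = 3,
) -> list[TrainRecord]:
    """Train every (config, dataset) cell ``replicates`` times.

    ``datasets`` maps a name to ``{"train": (X, Y), "val": (X, Y),
    "test": (X, Y)}``; each replicate r re-seeds the run with
    ``cfg.seed + r``. The test-set mean Dice (unmasked rule) is recorded
    per run. A failing cell is marked failed and the grid continues.
    """
    records: list[TrainRecord] = []
    for cfg in grid:
        for name, data in datasets.items():
            for rep in range(1, replicates + 1):
                cfg_rep = replace(cfg, seed=cfg.seed + rep)
                rec = TrainRecord(config=cfg_rep, replicate=rep, dataset=name)
                try:
                    model = build_unet(cfg_rep)
                    rec = train(
                        model, data["train"], data["val"], cfg_rep,
                        replicate=rep, dataset=name,
                    )
                    Xt, Yt = data.get("test", data["val"])
                    rec.test_dice = _mean_val_dice(
                        model, _as_input(Xt),
                        np.stack([np.asarray(m, bool) for m in Yt]),
                        cfg_rep.binarize_threshold,
                    )
                except (ValidationError, RuntimeError) as exc:
                    rec.failed = True
                    rec.error = str(exc)
                records.append(rec)
    return records


def grid_report(records: list[TrainRecord]) -> pd.DataFrame:
    """Replicate-averaged Dice per grid cell, one row per
    (depth, learning rate, batch size, dataset)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "depth": rec.config.depth,
                "learning_rate": rec.config.learning_rate,
                "batch_size": rec.config.batch_size,
                "dataset": rec.dataset,
                "replicate": rec.replicate,
                "test_dice": rec.test_dice,
                "failed": rec.failed,
            }
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["depth", "learning_rate", "batch_size", "dataset"], sort=True)
        .agg(
            mean_dice=("test_dice", "mean"),
            n_replicates=("replicate", "count"),
            n_failed=("failed", "sum"),
        )
        .reset_index()
    )
    return agg


# ---------------------------------------------------------------------------
# Weight serialisation
# ---------------------------------------------------------------------------

def save_weights(path: str | Path, model: UNet) -> None:
    """Save weights as .npz with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, *[p.value for p in model.params()])
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.cfg.__dict__, indent=2))


def load_weights(path: str | Path) -> UNet:
    path = Path(path)
    cfg = UNetConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = build_unet(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        keys = sorted(data.files, key=lambda k: int(k.split("_")[1]))
        weights = [data[k] for k in keys]
    model.set_weights(weights)
    return model
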