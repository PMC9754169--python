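"""The 2-D U-net reconstructor and its parallel multi-branch architecture.

One branch is an encoder–decoder convolutional network with skip
connections that maps the two bounding slices of a gap (stacked as two
input channels) to one intermediate slice. The parallel architecture
instantiates 2m-1 such networks with independent parameters, all fed the
identical slice pair; branch k is dedicated to target position k, so the
different reconstructed positions cannot influence one another. A
single-network multi-output variant (one U-net emitting 2m-1 channels)
is provided as the comparison architecture.

Default geometry follows the full-scale design — eight encoder and seven
decoder modules with batch normalization and dropout in the last decoder
block — but the effective depth auto-reduces for small images so every
resolution level keeps a spatial extent of at least 2. Training
minimizes mean absolute error by default (the evaluation criterion for
CT-value fidelity), with squared error selectable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn

__all__ = ["UnetSpec", "TrainConfig", "UNet", "ParallelModel", "build_unet",
           "build_parallel", "build_multi_output", "train_parallel",
           "train_network", "predict_slices", "save_model", "load_model"]


@dataclass(frozen=True)
class UnetSpec:
    """Architecture hyperparameters for one branch.

    ``encoder_blocks`` counts resolution levels including the bottleneck;
    ``decoder_blocks`` defaults to one fewer. Channel widths double per
    level from ``base_channels``, capped at ``max_channels``.

    With ``residual`` (default), the network predicts the correction to a
    fractional linear blend of its two input slices instead of the slice
    itself: output = head(features) + (1 - w) left + w right, with the
    head zero-initialized so an untrained branch reproduces the linear
    estimate exactly. Residual prediction of the interpolation error is
    the standard conditioning device in learned super-resolution and
    leaves the encoder-decoder architecture itself unchanged.
    """

    encoder_blocks: int = 8
    decoder_blocks: int = 7
    base_channels: int = 64
    max_channels: int = 512
    input_channels: int = 2
    output_channels: int = 1
    dropout_rate: float = 0.5
    use_batchnorm: bool = True
    residual: bool = True
    image_shape: tuple[int, int] = (400, 320)

    def __post_init__(self):
        if self.decoder_blocks != self.encoder_blocks - 1:
            raise ValueError("decoder_blocks must equal encoder_blocks - 1")
        if self.encoder_blocks < 2:
            raise ValueError("need at least 2 encoder blocks")

    def effective_levels(self) -> int:
        """Depth actually used: each level must keep spatial extent >= 2."""
        smallest = min(self.image_shape)
        levels = self.encoder_blocks
        while levels > 2 and smallest // (2 ** (levels - 1)) < 2:
            levels -= 1
        if smallest // (2 ** (levels - 1)) < 2:
            raise ValueError(
                f"image shape {self.image_shape} too small for a U-net "
                f"(needs min side >= 4)")
        return levels


@dataclass
class TrainConfig:
    """Optimization settings; ``seed`` fixes init, shuffling and dropout."""

    loss: str = "mae"          # "mae" (the evaluation criterion) or "mse"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    lr_schedule: str = "constant"   # or "cosine" (decays to lr/10)
    epochs: int = 50
    batch_size: int = 8
    augment_flips: bool = False     # random in-plane mirror flips per batch
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self):
        if self.loss not in ("mae", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown schedule {self.lr_schedule!r}")


class UNet:
    """Encoder–decoder network with skip connections, built from _nn layers."""

    def __init__(self, spec: UnetSpec, seed: int = 0,
                 output_channels: int | None = None,
                 anchor_weights=None):
        self.spec = spec
        self.seed = int(seed)
        self.output_channels = spec.output_channels if output_channels is None else output_channels
        if anchor_weights is None and spec.residual:
            # default anchor: midpoint blend for every output channel
            anchor_weights = [0.5] * self.output_channels
        if anchor_weights is not None and len(anchor_weights) != self.output_channels:
            raise ValueError("need one anchor weight per output channel")
        self.anchor_weights = (None if anchor_weights is None
                               else np.asarray(anchor_weights, dtype=np.float32))
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        L = spec.effective_levels()
        self.levels = L
        self._pad_multiple = 2 ** (L - 1)
        ch = [min(spec.base_channels * 2 ** i, spec.max_channels) for i in range(L)]
        self.channels = ch

        def block(cin, cout, with_dropout=False):
            layers = [_nn.Conv2d(cin, cout, 3, rng)]
            if spec.use_batchnorm:
                layers.append(_nn.BatchNorm2d(cout))
            layers.append(_nn.ReLU())
            if with_dropout and spec.dropout_rate > 0:
                layers.append(_nn.Dropout(spec.dropout_rate))
            return layers

        self.enc = []
        cin = spec.input_channels
        for i in range(L):
            self.enc.append(block(cin, ch[i]))
            cin = ch[i]
        self.pools = [_nn.AvgPool2() for _ in range(L - 1)]
        self.ups = [_nn.Upsample2() for _ in range(L - 1)]
        # dec[j] operates at level L-2-j; the last one (level 0) carries dropout
        self.dec = []
        for j, i in enumerate(range(L - 2, -1, -1)):
            self.dec.append(block(ch[i] + ch[i + 1], ch[i], with_dropout=(i == 0)))
        self.head = _nn.Conv2d(ch[0], self.output_channels, 1, rng)
        if self.anchor_weights is not None:
            # zero head: the untrained network outputs the anchor exactly
            self.head.W.value[...] = 0.0
            self.head.b.value[...] = 0.0

    # -- plumbing ----------------------------------------------------------
    def parameters(self) -> list[_nn.Param]:
        params = []
        for blk in self.enc + self.dec:
            for layer in blk:
                params.extend(layer.parameters())
        params.extend(self.head.parameters())
        return params

    @staticmethod
    def _run(blk, x, training, rng):
        for layer in blk:
            x = layer.forward(x, training=training, rng=rng)
        return x

    @staticmethod
    def _run_back(blk, dy):
        for layer in reversed(blk):
            dy = layer.backward(dy)
        return dy

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Map (N, in_ch, H, W) to (N, out_ch, H, W).

        Inputs whose sides are not multiples of 2^(levels-1) are edge-padded
        internally and the output is cropped back, so the spatial contract
        holds for any shape with min side >= 4.
        """
        if x.ndim != 4 or x.shape[1] != self.spec.input_channels:
            raise ValueError(f"expected (N, {self.spec.input_channels}, H, W), got {x.shape}")
        x = x.astype(np.float32, copy=False)
        anchor = None
        if self.anchor_weights is not None:
            w = self.anchor_weights[None, :, None, None]
            anchor = (1.0 - w) * x[:, :1] + w * x[:, 1:2]
        N, _, H, W = x.shape
        ph = (-H) % self._pad_multiple
        pw = (-W) % self._pad_multiple
        self._hw = (H, W)
        self._pad = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        skips = []
        for i in range(self.levels):
            x = self._run(self.enc[i], x, training, rng)
            if i < self.levels - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = [s.shape[1] for s in skips]
        for j in range(len(self.dec)):
            x = self.ups[j].forward(x)
            skip = skips.pop()
            x = np.concatenate([skip, x], axis=1)
            x = self._run(self.dec[j], x, training, rng)
        y = self.head.forward(x)[:, :, :H, :W]
        if anchor is not None:
            y = y + anchor
        return y

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for the last forward pass."""
        H, W = self._hw
        ph, pw = self._pad
        if ph or pw:
            dy = np.pad(dy, ((0, 0), (0, 0), (0, ph), (0, pw)))
        dx = self.head.backward(dy)
        dskips: dict[int, np.ndarray] = {}
        for j in range(len(self.dec) - 1, -1, -1):
            level = self.levels - 2 - j
            dx = self._run_back(self.dec[j], dx)
            ck = self._skip_channels[level]
            dskips[level] = dx[:, :ck]
            dx = self.ups[j].backward(dx[:, ck:])
        for i in range(self.levels - 1, -1, -1):
            if i < self.levels - 1:
                dx = self.pools[i].backward(dx)
                dx = dx + dskips[i]
            dx = self._run_back(self.enc[i], dx)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward with outputs clamped to [0, 1]."""
        return np.clip(self.forward(x, training=False), 0.0, 1.0)

    # -- state -------------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.parameters()]
        for blk in self.enc + self.dec:
            for layer in blk:
                if isinstance(layer, _nn.BatchNorm2d):
                    arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def set_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match architecture")
        for dst, src in zip(own, arrays):
            dst[...] = src


@dataclass
class ParallelModel:
    """2m-1 independently parameterized U-nets sharing one slice-pair input."""

    branches: list[UNet]
    spec: UnetSpec
    seed: int

    @property
    def targets_per_gap(self) -> int:
        return len(self.branches)


def _anchor_fractions(targets_per_gap: int) -> list[float]:
    step = targets_per_gap + 1
    return [k / step for k in range(1, step)]


def build_unet(spec: UnetSpec, seed: int = 0) -> UNet:
    """One network mapping a 2-channel slice pair to a 1-channel slice."""
    return UNet(spec, seed=seed)


def build_parallel(spec: UnetSpec, targets_per_gap: int, seed: int = 0) -> ParallelModel:
    """Independent branches; branch k is seeded by (seed, k) so its
    parameters do not depend on how many siblings exist. With residual
    prediction, branch k anchors on the linear blend at fraction k/(2m)."""
    if targets_per_gap < 1:
        raise ValueError("targets_per_gap must be >= 1")
    fractions = _anchor_fractions(targets_per_gap)
    branches = [
        UNet(spec, seed=_branch_seed(seed, k),
             anchor_weights=[fractions[k]] if spec.residual else None)
        for k in range(targets_per_gap)
    ]
    return ParallelModel(branches=branches, spec=spec, seed=seed)


def build_multi_output(spec: UnetSpec, targets_per_gap: int, seed: int = 0) -> UNet:
    """The comparison architecture: one U-net emitting all 2m-1 slices."""
    anchors = _anchor_fractions(targets_per_gap) if spec.residual else None
    return UNet(spec, seed=seed, output_channels=targets_per_gap,
                anchor_weights=anchors)


def _branch_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# training


def _loss_grad(pred: np.ndarray, target: np.ndarray, loss: str):
    diff = pred - target
    n = diff.size
    if loss == "mae":
        return float(np.abs(diff).mean()), np.sign(diff).astype(np.float32) / n
    return float((diff ** 2).mean()), (2.0 / n) * diff.astype(np.float32)


def train_network(net: UNet, inputs: np.ndarray, targets: np.ndarray,
                  cfg: TrainConfig, rng: np.random.Generator | None = None
                  ) -> list[dict]:
    """Train one network on (N, 2, H, W) inputs and (N, out_ch, H, W) targets.

    Returns a history of per-epoch records with training loss and
    validation MAE (in the normalized intensity domain). The validation
    split is taken deterministically from the RNG.
    """
    if inputs.shape[0] != targets.shape[0]:
        raise ValueError("inputs and targets must align")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = inputs.shape[0]
    order = rng.permutation(n)
    n_val = int(round(cfg.validation_fraction * n))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise ValueError("no training examples left after validation split")
    opt = _nn.Adam(net.parameters(), lr=cfg.learning_rate)
    history = []
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine" and cfg.epochs > 1:
            lo = cfg.learning_rate / 10.0
            opt.lr = lo + 0.5 * (cfg.learning_rate - lo) * (
                1.0 + np.cos(np.pi * epoch / (cfg.epochs - 1)))
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, perm.size, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = inputs[idx], targets[idx]
            if cfg.augment_flips:
                if rng.random() < 0.5:
                    xb, yb = xb[..., ::-1].copy(), yb[..., ::-1].copy()
                if rng.random() < 0.5:
                    xb, yb = xb[..., ::-1, :].copy(), yb[..., ::-1, :].copy()
            opt.zero_grad()
            pred = net.forward(xb, training=True, rng=rng)
            loss, dy = _loss_grad(pred, yb, cfg.loss)
            net.backward(dy)
            opt.step()
            losses.append(loss)
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_idx.size:
            val_pred = net.predict(inputs[val_idx])
            record["val_mae"] = float(np.abs(val_pred - targets[val_idx]).mean())
        history.append(record)
    return history


def train_parallel(model: ParallelModel, inputs: np.ndarray, targets: np.ndarray,
                   cfg: TrainConfig) -> dict[int, list[dict]]:
    """Train every branch on its own target position.

    ``inputs`` is (N, 2, H, W); ``targets`` is (N, 2m-1, H, W) with
    position k in channel k. Each branch's RNG derives from (cfg.seed, k)
    alone, so training branch k inside the parallel run is identical to
    training it by itself.
    """
    if targets.shape[1] != model.targets_per_gap:
        raise ValueError(
            f"targets supply {targets.shape[1]} positions, model has "
            f"{model.targets_per_gap} branches")
    history: dict[int, list[dict]] = {}
    for k, net in enumerate(model.branches):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, k)))
        history[k] = train_network(net, inputs, targets[:, k:k + 1], cfg, rng=rng)
    return history


def predict_slices(model: ParallelModel, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Ordered (2m-1, H, W) prediction for one slice pair, clamped to [0, 1]."""
    left = np.asarray(left, dtype=np.float32)
    right = np.asarray(right, dtype=np.float32)
    if left.shape != right.shape or left.ndim != 2:
        raise ValueError(f"left/right must be equal-shape 2-D slices, got "
                         f"{left.shape} and {right.shape}")
    x = np.stack([left, right])[None]  # (1, 2, H, W)
    return np.stack([net.predict(x)[0, 0] for net in model.branches])


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: ParallelModel, path: str | os.PathLike) -> None:
    """Save all branch parameters plus spec/seed metadata as .npz."""
    arrays = {}
    for k, net in enumerate(model.branches):
        for i, a in enumerate(net.state_arrays()):
            arrays[f"b{k}_{i}"] = a
    meta = {"spec": asdict(model.spec), "seed": model.seed,
            "targets_per_gap": model.targets_per_gap}
    np.savez(os.fspath(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | os.PathLike) -> ParallelModel:
    with np.load(os.fspath(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_dict = meta["spec"]
        spec_dict["image_shape"] = tuple(spec_dict["image_shape"])
        spec = UnetSpec(**spec_dict)
        model = build_parallel(spec, meta["targets_per_gap"], seed=meta["seed"])
        for k, net in enumerate(model.branches):
            arrays = []
            i = 0
            while f"b{k}_{i}" in data:
                arrays.append(data[f"b{k}_{i}"])
                i += 1
            net.set_state(arrays)
    return model
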