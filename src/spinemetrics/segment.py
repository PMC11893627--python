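"""Inception U-Net segmentation of radiograph ROIs.

Each ROI class (vertebrae, C7/neck, the two sacral endplate disks, the
femoral heads) gets its own network mapping a normalized grayscale ROI
image to a per-pixel probability map.  The architecture is a U-Net
whose encoder/decoder blocks are inception modules: three parallel
convolution branches (1x1, 3x3, 5x5 kernels, ReLU) concatenated along
channels.  Training minimizes binary cross-entropy with Adam
(initial learning rate 5e-4 by default), weights start from He-normal
initialization, and the training corpus is split 85:15 into training
and validation folds by a seeded shuffle.  Probability maps are turned
into binary masks at a threshold of 0.7 (values exactly at the
threshold are kept).

The full-scale regime of the original clinical pipeline (500 epochs,
batch 20, hundreds of radiographs) is configuration, not code; the
defaults here are desk-scale so a network trains on phantom ROIs in
minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam, Conv2d, MaxPool2x2, ReLU, Upsample2x2, bce_with_logits, sigmoid

__all__ = [
    "NetworkConfig",
    "InceptionUNet",
    "build_model",
    "train_model",
    "predict",
    "binarize",
    "dice_score",
]

BINARIZE_THRESHOLD = 0.7


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters for one ROI network.

    ``input_hw`` must be divisible by ``2**depth``.  ``base_width`` is
    the per-branch channel count of the first inception block; widths
    double at each encoder level.  ``branch_kernels`` are the parallel
    convolution kernel sizes of every inception module.
    """

    input_hw: tuple[int, int] = (64, 32)
    depth: int = 3
    base_width: int = 8
    branch_kernels: tuple[int, ...] = (1, 3, 5)
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 5e-4
    validation_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        h, w = self.input_hw
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {self.input_hw} not divisible by 2^depth={f}"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must lie in (0, 1)")
        if self.depth < 1 or self.base_width < 1:
            raise ValueError("depth and base_width must be >= 1")


class _InceptionBlock:
    """Parallel 1x1 / 3x3 / 5x5 convolution branches, ReLU each,
    concatenated along channels (out channels = len(kernels) * width)."""

    def __init__(self, cin, width, kernels, rng):
        self.convs = [Conv2d(cin, width, k, rng) for k in kernels]
        self.relus = [ReLU() for _ in kernels]
        self.cout = width * len(kernels)
        self._splits = None

    def forward(self, x, train=True):
        outs = [r.forward(c.forward(x, train), train)
                for c, r in zip(self.convs, self.relus)]
        self._splits = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        dx = None
        ofs = 0
        for c, r, s in zip(self.convs, self.relus, self._splits):
            g = grad[:, ofs : ofs + s]
            ofs += s
            d = c.backward(r.backward(g))
            dx = d if dx is None else dx + d
        return dx

    def params(self):
        return [p for c in self.convs for p in c.params()]


class InceptionUNet:
    """Encoder-decoder with inception blocks and skip connections;
    final 1x1 convolution produces single-channel logits."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ks = config.branch_kernels
        w0 = config.base_width
        self.enc_blocks: list[_InceptionBlock] = []
        self.pools: list[MaxPool2x2] = []
        cin = 1
        for d in range(config.depth):
            blk = _InceptionBlock(cin, w0 * 2**d, ks, rng)
            self.enc_blocks.append(blk)
            self.pools.append(MaxPool2x2())
            cin = blk.cout
        self.bottleneck = _InceptionBlock(cin, w0 * 2**config.depth, ks, rng)
        cin = self.bottleneck.cout
        self.ups: list[Upsample2x2] = []
        self.dec_blocks: list[_InceptionBlock] = []
        for d in reversed(range(config.depth)):
            skip = self.enc_blocks[d].cout
            blk = _InceptionBlock(cin + skip, w0 * 2**d, ks, rng)
            self.ups.append(Upsample2x2())
            self.dec_blocks.append(blk)
            cin = blk.cout
        self.head = Conv2d(cin, 1, 1, rng)
        self._skip_channels = [b.cout for b in self.enc_blocks]

    # -- passes -------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([x, skip], axis=1)
            x = blk.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        skip_grads = []
        for i in reversed(range(len(self.dec_blocks))):
            g = self.dec_blocks[i].backward(g)
            skip_c = self._skip_channels[len(self.dec_blocks) - 1 - i]
            up_c = g.shape[1] - skip_c
            g, g_skip = g[:, :up_c], g[:, up_c:]
            skip_grads.append(g_skip)
            g = self.ups[i].backward(g)
        g = self.bottleneck.backward(g)
        # skip_grads was filled shallow-to-deep, i.e. already indexed
        # like enc_blocks
        for i in reversed(range(len(self.enc_blocks))):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(g)

    def params(self):
        out = []
        for blk in self.enc_blocks:
            out += blk.params()
        out += self.bottleneck.params()
        for blk in self.dec_blocks:
            out += blk.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    # -- persistence --------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()]

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.state_arrays())}
        np.savez(path, **arrays)
        with open(str(path) + ".json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, path) -> "InceptionUNet":
        with open(str(path) + ".json") as fh:
            d = json.load(fh)
        d["input_hw"] = tuple(d["input_hw"])
        d["branch_kernels"] = tuple(d["branch_kernels"])
        model = cls(NetworkConfig(**d))
        p_npz = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        data = np.load(p_npz)
        for i, (p, _) in enumerate(model.params()):
            p[...] = data[f"p{i}"]
        return model


def build_model(config: NetworkConfig) -> InceptionUNet:
    """Construct the inception U-Net; identical seeds give identical
    initial weights."""
    return InceptionUNet(config)


def dice_score(pred: np.ndarray, true: np.ndarray) -> float:
    """Dice/F1 on binary arrays; 1.0 when both are empty."""
    p = pred.astype(bool)
    t = true.astype(bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_bce: list[float] = field(default_factory=list)
    val_bce: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def as_rows(self):
        return [
            {"epoch": e, "train_bce": tb, "val_bce": vb, "val_dice": vd}
            for e, tb, vb, vd in zip(
                self.epochs, self.train_bce, self.val_bce, self.val_dice
            )
        ]


def _as_batch(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    return x


def train_model(
    model: InceptionUNet,
    images: np.ndarray,
    masks: np.ndarray,
    config: NetworkConfig | None = None,
) -> TrainingHistory:
    """Train on (N, H, W) images and binary masks.

    The corpus is shuffled once with the configured seed and split
    85:15 (by default) into training and validation folds; per-epoch
    training/validation BCE and validation Dice are recorded and the
    best-validation weights are restored at the end.  Deterministic
    given the seed.
    """
    config = config or model.config
    x = _as_batch(images)
    y = _as_batch(masks).astype(np.float32)
    if x.shape != y.shape:
        raise ValueError(f"images {x.shape} and masks {y.shape} misaligned")
    if x.shape[0] == 0:
        raise ValueError("empty training corpus")
    if x.shape[2:] != tuple(config.input_hw):
        raise ValueError(
            f"images {x.shape[2:]} do not match network input {config.input_hw}"
        )
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("masks must be binary")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(x.shape[0])
    n_val = max(1, int(round(config.validation_fraction * x.shape[0]))) \
        if x.shape[0] > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = order, order[:0]
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    opt = Adam(model.params(), lr=config.learning_rate)
    hist = TrainingHistory()
    best_val = np.inf
    best_state = [p.copy() for p, _ in model.params()]
    for epoch in range(config.epochs):
        perm = rng.permutation(xt.shape[0])
        losses = []
        for s in range(0, len(perm), config.batch_size):
            idx = perm[s : s + config.batch_size]
            logits = model.forward_logits(xt[idx], train=True)
            loss, grad = bce_with_logits(logits, yt[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        if xv.shape[0]:
            vlogits = model.forward_logits(xv, train=False)
            vloss, _ = bce_with_logits(vlogits, yv)
            vdice = dice_score(sigmoid(vlogits) >= BINARIZE_THRESHOLD, yv >= 0.5)
        else:
            vloss, vdice = float("nan"), float("nan")
        hist.epochs.append(epoch)
        hist.train_bce.append(float(np.mean(losses)))
        hist.val_bce.append(vloss)
        hist.val_dice.append(vdice)
        if xv.shape[0] and vloss < best_val:
            best_val = vloss
            hist.best_epoch = epoch
            best_state = [p.copy() for p, _ in model.params()]
    if xv.shape[0]:
        for (p, _), saved in zip(model.params(), best_state):
            p[...] = saved
    return hist


def predict(model: InceptionUNet, roi_image: np.ndarray) -> np.ndarray:
    """Probability map in [0, 1] for one ROI image (deterministic)."""
    x = np.asarray(roi_image, dtype=np.float32)
    if x.ndim != 2 or x.shape != tuple(model.config.input_hw):
        raise ValueError(
            f"image shape {x.shape} does not match network input "
            f"{model.config.input_hw}"
        )
    logits = model.forward_logits(x[None, None], train=False)
    return sigmoid(logits)[0, 0].astype(np.float64)


def binarize(prob_map: np.ndarray, threshold: float = BINARIZE_THRESHOLD) -> np.ndarray:
    """Threshold a probability map into a binary mask (>= keeps the
    boundary value); idempotent on {0,1} maps for thresholds <= 1."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("binarization threshold must lie in (0, 1)")
    m = np.asarray(prob_map, dtype=float)
    if m.min() < 0.0 or m.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return m >= threshold
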