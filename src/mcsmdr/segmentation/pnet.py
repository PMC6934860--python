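"""Dilated fully convolutional spheroid segmenter.

The network follows the P-Net design: 13 3x3 convolution layers grouped
into five blocks (2, 2, 3, 3, 3 layers) with per-block dilation rates
that grow the receptive field without any spatial downsampling, so the
score map keeps the input resolution.  The five block outputs are
concatenated channel-wise and passed through dropout and two 1x1
classification layers that produce per-pixel background/spheroid
scores.  Training minimises a class-weighted cross-entropy (background
: foreground = 1:10 by default, reflecting how few pixels a spheroid
occupies) with Adam, and augments each training pair with the eight
square-symmetry transforms (rotations by 0/90/180/270 degrees, each
with and without a horizontal flip).

Everything runs in float32 NumPy; see :mod:`mcsmdr.segmentation.nn`
for the layer implementations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from ..containers import SegMask
from .nn import Adam, Conv2d, Dropout, ReLU, Sequential

_LOG_EPS = 1e-7


@dataclass
class PNetConfig:
    """Architecture and training hyper-parameters.

    The layer grouping (13 convolutions in five blocks of 2/2/3/3/3),
    the 3x3 kernels, the Adam learning rate of 1e-4, the 1:10
    background:foreground class weighting and the 20-epoch budget are
    the published settings; dilation rates, channel width, dropout
    rate and batch size are free choices exposed here.
    """

    n_blocks: int = 5
    convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)
    kernel_size: int = 3
    dilation_per_block: tuple[int, ...] = (1, 2, 4, 8, 16)
    channels_per_block: int = 64
    dropout_rate: float = 0.5
    input_size: int = 512
    n_classes: int = 2
    class_weights: tuple[float, float] = (1.0, 10.0)
    learning_rate: float = 1e-4
    max_epochs: int = 20
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks != len(self.convs_per_block) or self.n_blocks != len(
            self.dilation_per_block
        ):
            raise ValueError("convs_per_block and dilation_per_block must have n_blocks entries")
        if sum(self.convs_per_block) != 13:
            raise ValueError("the network uses 13 convolution layers in total")
        if self.kernel_size != 3:
            raise ValueError("kernel size is fixed at 3x3")
        if not all(w > 0 for w in self.class_weights):
            raise ValueError("class weights must be strictly positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes != 2:
            raise ValueError("binary segmentation only")
        if self.input_size < 16:
            raise ValueError("input_size too small for the receptive field")
        if self.channels_per_block < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("channels, batch size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainReport:
    """Per-epoch weighted cross-entropy losses and validation Dice."""

    epoch_losses: list[float] = field(default_factory=list)
    n_training_pairs: int = 0
    n_augmented: int = 0
    val_dice: list[float] = field(default_factory=list)


class PNet:
    """Handle bundling layers, config and the forward/backward passes."""

    def __init__(self, config: PNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.channels_per_block
        self.blocks: list[Sequential] = []
        c_in = 1
        for b in range(config.n_blocks):
            layers: list = []
            for _ in range(config.convs_per_block[b]):
                layers.append(
                    Conv2d(c_in, c, config.kernel_size, config.dilation_per_block[b], rng)
                )
                layers.append(ReLU())
                c_in = c
            self.blocks.append(Sequential(*layers))
        cat = config.n_blocks * c
        self.classifier = Sequential(
            Dropout(config.dropout_rate, rng),
            Conv2d(cat, c, 1, 1, rng),
            ReLU(),
            Dropout(config.dropout_rate, rng),
            Conv2d(c, config.n_classes, 1, 1, rng),
        )

    # -- plumbing -----------------------------------------------------
    def params(self) -> list[np.ndarray]:
        out = [p for blk in self.blocks for p in blk.params()]
        return out + self.classifier.params()

    def grads(self) -> list[np.ndarray]:
        out = [g for blk in self.blocks for g in blk.grads()]
        return out + self.classifier.grads()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    # -- passes -------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, H, W, 1) -> per-pixel class scores (N, H, W, 2)."""
        outs = []
        h = x
        for blk in self.blocks:
            h = blk.forward(h, training)
            outs.append(h)
        cat = np.concatenate(outs, axis=-1)
        self._split = [o.shape[-1] for o in outs]
        return self.classifier.forward(cat, training)

    def backward(self, dscores: np.ndarray) -> None:
        dcat = self.classifier.backward(dscores)
        edges = np.cumsum(self._split)[:-1]
        chunks = np.split(dcat, edges, axis=-1)
        d_next = None
        for blk, chunk in zip(reversed(self.blocks), reversed(chunks)):
            d = chunk if d_next is None else chunk + d_next
            d_next = blk.backward(np.ascontiguousarray(d))


def build_pnet(config: PNetConfig | None = None) -> PNet:
    """Construct a seeded, untrained network from a config."""
    return PNet(config or PNetConfig())


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    scores: np.ndarray,
    truth: np.ndarray | SegMask,
    class_weights: tuple[float, float] = (1.0, 10.0),
) -> float:
    """Mean over pixels of -w(class) * log p(true class).

    ``scores`` are unnormalised per-pixel class scores (..., 2);
    probabilities below 1e-7 are clamped before the log.
    """
    y = truth.pixels if isinstance(truth, SegMask) else np.asarray(truth)
    if scores.shape[:-1] != y.shape:
        raise ValueError("score map and truth mask shapes differ")
    p = softmax(scores)
    p_true = np.where(y.astype(bool), p[..., 1], p[..., 0])
    w = np.where(y.astype(bool), class_weights[1], class_weights[0])
    return float(np.mean(-w * np.log(np.clip(p_true, _LOG_EPS, None))))


def _ce_grad(scores: np.ndarray, y: np.ndarray, class_weights) -> np.ndarray:
    p = softmax(scores)
    onehot = np.zeros_like(p)
    yb = y.astype(bool)
    onehot[..., 1] = yb
    onehot[..., 0] = ~yb
    w = np.where(yb, class_weights[1], class_weights[0])[..., None].astype(np.float32)
    return w * (p - onehot) / y.size


def normalize_frame(frame: np.ndarray) -> np.ndarray:
    """Per-frame z-score; makes the net insensitive to camera gain."""
    f = np.asarray(frame, dtype=np.float32)
    return (f - f.mean()) / (f.std() + 1e-8)


def _resize_image(frame: np.ndarray, size: int) -> np.ndarray:
    if frame.shape == (size, size):
        return np.asarray(frame, dtype=np.float32)
    return resize(frame, (size, size), order=1, anti_aliasing=True,
                  preserve_range=True).astype(np.float32)


def _resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mask.shape == shape:
        return mask.astype(np.uint8)
    return resize(mask.astype(np.uint8), shape, order=0, anti_aliasing=False,
                  preserve_range=True).astype(np.uint8)


def dihedral_transforms(img: np.ndarray) -> list[np.ndarray]:
    """The 8 square symmetries: rotations x optional horizontal flip."""
    out = []
    for k in range(4):
        r = np.rot90(img, k)
        out.append(r)
        out.append(np.fliplr(r))
    return out


def train_pnet(
    images: list[np.ndarray],
    masks: list[SegMask | np.ndarray],
    config: PNetConfig | None = None,
    val_images: list[np.ndarray] | None = None,
    val_masks: list[SegMask | np.ndarray] | None = None,
    augment: bool = True,
) -> tuple[PNet, TrainReport]:
    """Train a segmenter on (frame, mask) pairs.

    Frames are resized to ``config.input_size`` (bilinear; masks
    nearest-neighbour), z-scored, augmented 8x with flips/rotations,
    and optimised with Adam on the weighted cross-entropy for up to
    ``config.max_epochs`` epochs.  Deterministic given config.seed.
    """
    config = config or PNetConfig()
    if len(images) == 0:
        raise ValueError("training set must contain at least one (image, mask) pair")
    if len(images) != len(masks):
        raise ValueError("one mask per training image required")

    size = config.input_size
    xs, ys = [], []
    for img, msk in zip(images, masks):
        m = msk.pixels if isinstance(msk, SegMask) else np.asarray(msk)
        x = normalize_frame(_resize_image(np.asarray(img, np.float32), size))
        y = _resize_mask(m, (size, size))
        if augment:
            xs.extend(dihedral_transforms(x))
            ys.extend(dihedral_transforms(y))
        else:
            xs.append(x)
            ys.append(y)
    xs = [np.ascontiguousarray(x, dtype=np.float32) for x in xs]
    ys = [np.ascontiguousarray(y) for y in ys]

    model = PNet(config)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    report = TrainReport(n_training_pairs=len(images), n_augmented=len(xs))

    n = len(xs)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = np.stack([xs[i] for i in idx])[..., None]
            yb = np.stack([ys[i] for i in idx])
            scores = model.forward(xb, training=True)
            losses.append(weighted_cross_entropy(scores, yb, config.class_weights))
            model.backward(_ce_grad(scores, yb, config.class_weights))
            opt.step(model.grads())
        report.epoch_losses.append(float(np.mean(losses)))
        if val_images:
            from .metrics import dice

            scores_d = []
            for img, msk in zip(val_images, val_masks):
                pred = segment(model, img)
                truth = msk if isinstance(msk, SegMask) else SegMask(np.asarray(msk))
                scores_d.append(dice(pred, truth))
            report.val_dice.append(float(np.mean(scores_d)))
    return model, report


def segment(model: PNet, frame: np.ndarray,
            decision_threshold: float | None = None) -> SegMask:
    """Segment one frame: dense prediction + largest component + hole fill.

    The frame is resized to the model's input size and scored per
    pixel.  Training with foreground-weighted cross-entropy shifts the
    effective class prior by the weight ratio, so the default decision
    rule compensates: a pixel is foreground when p_fg exceeds
    w_fg / (w_fg + w_bg) (10/11 for the default 1:10 weights), which
    restores the unweighted Bayes decision.  The foreground is then
    smoothed, reduced to its largest connected component, hole-filled
    and mapped back to the original resolution with nearest-neighbour
    interpolation.  An all-background score map yields an empty mask
    with ``empty_warning`` set.
    """
    frame = np.asarray(frame, dtype=np.float32)
    orig_shape = frame.shape
    x = normalize_frame(_resize_image(frame, model.config.input_size))[None, ..., None]
    scores = model.forward(x, training=False)[0]
    if decision_threshold is None:
        w_bg, w_fg = model.config.class_weights
        decision_threshold = w_fg / (w_fg + w_bg)
    fg = softmax(scores)[..., 1] > decision_threshold
    if fg.any():
        # smooth ragged per-pixel decisions before keeping the spheroid
        fg = ndi.binary_closing(fg, structure=np.ones((3, 3)), iterations=2)
    if fg.any():
        lab, nlab = ndi.label(fg)
        if nlab > 1:
            sizes = ndi.sum(fg, lab, index=np.arange(1, nlab + 1))
            fg = lab == (1 + int(np.argmax(sizes)))
        fg = ndi.binary_fill_holes(fg)
    out = _resize_mask(fg.astype(np.uint8), orig_shape)
    return SegMask(pixels=out, source="pnet", empty_warning=not bool(out.any()))


def save_model(path: str | Path, model: PNet) -> None:
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez(Path(path), config=json.dumps(asdict(model.config)), **arrays)


def load_model(path: str | Path) -> PNet:
    data = np.load(Path(path), allow_pickle=False)
    cfg = json.loads(str(data["config"]))
    for key in ("convs_per_block", "dilation_per_block", "class_weights"):
        cfg[key] = tuple(cfg[key])
    model = PNet(PNetConfig(**cfg))
    for i, p in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    return model
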