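"""Cell-level mitosis classifier: MitosRes-CNN and cross-domain adaptation heads.

MitosRes-CNN is a compact residual network for 3x120x120 cell patches: a
stride-2 stem, three residual blocks (3x3 convolutions + batch normalization
+ leaky ReLU, average-pool downsampling inside each block, 1x1 channel
expansion at the block end, projection skips), a 4x4 adaptive average pool,
and a dropout-regularised dense head ending in a 2-way softmax.  The channel
schedule is 32 -> 96 -> 288 -> 512.

``MITOSRES_SHAPES`` records the expected (channels, height, width) at every
named stage; the builder propagates shapes through the constructed layers and
refuses to build if any stage disagrees, so the architecture table is an
executable fixture rather than documentation.

A ``reduced`` preset (same topology, narrower and on 3x40x40 inputs) trains
in minutes on one CPU and is used for desk-scale end-to-end runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn

__all__ = [
    "MITOSRES_SHAPES",
    "TrainingConfig",
    "BuildError",
    "leaky_relu",
    "residual_add",
    "build_mitosres_cnn",
    "build_reduced_mitosres_cnn",
    "init_weights",
    "build_adapted_classifier",
    "TinyBackbone",
    "augment_patch",
    "balanced_sampler",
    "PatchSet",
    "train_classifier",
    "predict_scores",
]


class BuildError(ValueError):
    """Shape propagation disagreed with the declared architecture table."""


def leaky_relu(a, slope: float = 0.01):
    """f(a) = a if a > 0 else slope * a (elementwise)."""
    a = np.asarray(a, dtype=float)
    out = np.where(a > 0, a, slope * a)
    return out.item() if out.ndim == 0 else out


def residual_add(transformed: np.ndarray, identity: np.ndarray) -> np.ndarray:
    """Elementwise residual sum; shapes must already agree (project the skip first)."""
    transformed = np.asarray(transformed)
    identity = np.asarray(identity)
    if transformed.shape != identity.shape:
        raise ValueError(
            f"residual add needs equal shapes, got {transformed.shape} and {identity.shape}"
        )
    return transformed + identity


#: Expected output shape (C, H, W) after each named stage for a 3x120x120 input.
MITOSRES_SHAPES = {
    "stem": (32, 60, 60),
    "block1.expand_in": (64, 60, 60),
    "block1.convs": (64, 60, 60),
    "block1.pool": (64, 30, 30),
    "block1.expand_out": (96, 30, 30),
    "block1.skip": (96, 30, 30),
    "block2.convs": (96, 30, 30),
    "block2.pool": (96, 15, 15),
    "block2.expand_out": (288, 15, 15),
    "block2.skip": (288, 15, 15),
    "block3.convs": (288, 15, 15),
    "block3.pool": (288, 7, 7),
    "block3.expand_out": (512, 7, 7),
    "block3.skip": (512, 7, 7),
    "head.pool": (512, 4, 4),
    "head.flatten": (8192,),
    "head.fc1": (150,),
    "head.fc2": (2,),
}


def _conv_bn(in_ch, out_ch, kernel, stride=1, pad=0):
    return [nn.Conv2d(in_ch, out_ch, kernel, stride, pad), nn.BatchNorm2d(out_ch)]


def _conv_units(ch, units, convs_per_unit, kernel=3, pad=1):
    """``units`` repetitions of (conv+BN) x convs_per_unit followed by one leaky ReLU."""
    layers = []
    for _ in range(units):
        for _ in range(convs_per_unit):
            layers += _conv_bn(ch, ch, kernel, 1, pad)
        layers.append(nn.LeakyReLU())
    return layers


def _check(stage: str, got: tuple, expected: dict) -> None:
    if stage in expected and tuple(got) != tuple(expected[stage]):
        raise BuildError(f"stage {stage}: propagated shape {got} != declared {expected[stage]}")


def build_mitosres_cnn(check_shapes: bool = True) -> nn.Sequential:
    """Full-size MitosRes-CNN for 3x120x120 inputs (shape-checked against the table)."""
    in_shape = (3, 120, 120)
    expected = MITOSRES_SHAPES if check_shapes else {}

    stem = nn.Sequential(_conv_bn(3, 32, 3, 2, 1) + [nn.LeakyReLU()], name="stem")
    _check("stem", stem.out_shape(in_shape), expected)
    s = stem.out_shape(in_shape)

    # Block 1: 1x1 expansion in, 3 units of 3 convs, pool /2, 1x1 expansion out
    b1_main_layers = _conv_bn(32, 64, 1, 1, 0)
    _check("block1.expand_in", nn.Sequential(b1_main_layers).out_shape(s), expected)
    b1_main_layers += _conv_units(64, units=3, convs_per_unit=3)
    _check("block1.convs", nn.Sequential(b1_main_layers).out_shape(s), expected)
    b1_main_layers += [nn.AvgPool2d(3, 2, 1)]
    _check("block1.pool", nn.Sequential(b1_main_layers).out_shape(s), expected)
    b1_main_layers += _conv_bn(64, 96, 1, 1, 0) + [nn.LeakyReLU()]
    _check("block1.expand_out", nn.Sequential(b1_main_layers).out_shape(s), expected)
    b1_skip = nn.Sequential(_conv_bn(32, 96, 1, 2, 0), name="block1.skip")
    _check("block1.skip", b1_skip.out_shape(s), expected)
    block1 = nn.Residual(nn.Sequential(b1_main_layers, name="block1.main"), b1_skip, name="block1")
    s1 = block1.out_shape(s)

    # Block 2
    b2_main_layers = _conv_units(96, units=3, convs_per_unit=3)
    _check("block2.convs", nn.Sequential(b2_main_layers).out_shape(s1), expected)
    b2_main_layers += [nn.AvgPool2d(3, 2, 1)]
    _check("block2.pool", nn.Sequential(b2_main_layers).out_shape(s1), expected)
    b2_main_layers += _conv_bn(96, 288, 1, 1, 0) + [nn.LeakyReLU()]
    _check("block2.expand_out", nn.Sequential(b2_main_layers).out_shape(s1), expected)
    b2_skip = nn.Sequential(_conv_bn(96, 288, 1, 2, 0), name="block2.skip")
    _check("block2.skip", b2_skip.out_shape(s1), expected)
    block2 = nn.Residual(nn.Sequential(b2_main_layers, name="block2.main"), b2_skip, name="block2")
    s2 = block2.out_shape(s1)

    # Block 3: 2 units of 3 convs + 1 unit of 2 convs, pool /2 (pad 0 -> 7x7),
    # 3x3 expansion to 512; stride-2 projection skip cropped from 8x8 to 7x7.
    b3_main_layers = _conv_units(288, units=2, convs_per_unit=3) + _conv_units(288, units=1, convs_per_unit=2)
    _check("block3.convs", nn.Sequential(b3_main_layers).out_shape(s2), expected)
    b3_main_layers += [nn.AvgPool2d(3, 2, 0)]
    _check("block3.pool", nn.Sequential(b3_main_layers).out_shape(s2), expected)
    b3_main_layers += _conv_bn(288, 512, 3, 1, 1) + [nn.LeakyReLU()]
    _check("block3.expand_out", nn.Sequential(b3_main_layers).out_shape(s2), expected)
    b3_skip = nn.Sequential(_conv_bn(288, 512, 1, 2, 0) + [nn.Crop2d(7, 7)], name="block3.skip")
    _check("block3.skip", b3_skip.out_shape(s2), expected)
    block3 = nn.Residual(nn.Sequential(b3_main_layers, name="block3.main"), b3_skip, name="block3")
    s3 = block3.out_shape(s2)

    head_layers = [nn.AdaptiveAvgPool2d(4)]
    _check("head.pool", nn.Sequential(head_layers).out_shape(s3), expected)
    head_layers += [nn.Flatten()]
    _check("head.flatten", nn.Sequential(head_layers).out_shape(s3), expected)
    head_layers += [nn.Dropout(0.5), nn.Linear(8192, 150)]
    _check("head.fc1", nn.Sequential(head_layers).out_shape(s3), expected)
    head_layers += [nn.Dropout(0.5), nn.BatchNorm1d(150), nn.Linear(150, 2)]
    _check("head.fc2", nn.Sequential(head_layers).out_shape(s3), expected)

    net = nn.Sequential([stem, block1, block2, block3] + head_layers, name="mitosres")
    net.input_shape = in_shape
    return net


def build_reduced_mitosres_cnn(input_size: int = 40, channels=(8, 12, 16, 24, 32), fc_hidden: int = 32) -> nn.Sequential:
    """Narrow MitosRes-CNN preset (same 3-block residual topology) for CPU training."""
    c0, c1, c2, c3, c4 = channels
    in_shape = (3, input_size, input_size)

    stem = nn.Sequential(_conv_bn(3, c0, 3, 2, 1) + [nn.LeakyReLU()], name="stem")

    def block(in_ch, mid_ch, out_ch, spatial_in, name, pool_pad=1):
        main = (
            _conv_bn(in_ch, mid_ch, 1, 1, 0)
            + _conv_units(mid_ch, units=1, convs_per_unit=2)
            + [nn.AvgPool2d(3, 2, pool_pad)]
            + _conv_bn(mid_ch, out_ch, 1, 1, 0)
            + [nn.LeakyReLU()]
        )
        main_seq = nn.Sequential(main, name=f"{name}.main")
        out_sp = main_seq.out_shape((in_ch, spatial_in, spatial_in))[1]
        skip_layers = _conv_bn(in_ch, out_ch, 1, 2, 0)
        skip_sp = nn.Sequential(skip_layers).out_shape((in_ch, spatial_in, spatial_in))[1]
        if skip_sp != out_sp:
            skip_layers.append(nn.Crop2d(out_sp, out_sp))
        return nn.Residual(main_seq, nn.Sequential(skip_layers, name=f"{name}.skip"), name=name), out_sp

    sp = stem.out_shape(in_shape)[1]
    block1, sp = block(c0, c1, c2, sp, "block1")
    block2, sp = block(c2, c2, c3, sp, "block2")
    block3, sp = block(c3, c3, c4, sp, "block3", pool_pad=0)

    pooled = 2
    flat = c4 * pooled * pooled
    head = [
        nn.AdaptiveAvgPool2d(pooled),
        nn.Flatten(),
        nn.Dropout(0.5),
        nn.Linear(flat, fc_hidden),
        nn.Dropout(0.5),
        nn.BatchNorm1d(fc_hidden),
        nn.Linear(fc_hidden, 2),
    ]
    net = nn.Sequential([stem, block1, block2, block3] + head, name="mitosres-reduced")
    net.out_shape(in_shape)  # raises on any internal inconsistency
    net.input_shape = in_shape
    return net


def init_weights(network: nn.Layer, seed: int = 0, mode: str = "reciprocal") -> nn.Layer:
    """Uniform Glorot-style init (see :func:`mitdet.nn.glorot_bound`), biases 0."""
    return nn.init_network(network, seed=seed, mode=mode)


def param_count(network: nn.Layer) -> int:
    return int(sum(p.value.size for p in network.params()))


class TinyBackbone(nn.Sequential):
    """Small stand-in feature extractor satisfying the pluggable-backbone contract.

    Any object with the ``Layer`` interface plus an ``out_channels`` attribute
    can be adapted; real pretrained backbones would plug in the same way.
    """

    def __init__(self, out_channels: int = 32, in_ch: int = 3):
        half = max(out_channels // 2, 4)
        super().__init__(
            _conv_bn(in_ch, half, 3, 2, 1)
            + [nn.LeakyReLU()]
            + _conv_bn(half, out_channels, 3, 2, 1)
            + [nn.LeakyReLU()],
            name="tiny-backbone",
        )
        self.out_channels = out_channels


def build_adapted_classifier(backbone, pool_size: int, fc_dims: Sequence[Sequence[int]]) -> nn.Sequential:
    """Cross-domain adaptation: backbone + adaptive pool + task-specific dense stack.

    ``fc_dims`` is a list of ``[n_in, n_out]`` pairs ending in ``[*, 2]``
    (e.g. ``[[4*4*512, 750], [750, 2]]``); the first ``n_in`` must equal
    ``pool_size**2 * backbone.out_channels``.  All parameters stay trainable.
    """
    pool_size = int(pool_size)
    fc_dims = [list(map(int, pair)) for pair in fc_dims]
    if not fc_dims or fc_dims[-1][1] != 2:
        raise ValueError("fc_dims must end in a 2-way layer")
    pooled = pool_size * pool_size * backbone.out_channels
    if fc_dims[0][0] != pooled:
        raise ValueError(
            f"fc_dims[0]={fc_dims[0][0]} inconsistent with pooled feature size {pooled}"
        )
    for a, b in zip(fc_dims[:-1], fc_dims[1:]):
        if a[1] != b[0]:
            raise ValueError(f"fc layer chain broken: {a} -> {b}")
    layers = [backbone, nn.AdaptiveAvgPool2d(pool_size), nn.Flatten()]
    for i, (n_in, n_out) in enumerate(fc_dims):
        layers.append(nn.Linear(n_in, n_out))
        if i < len(fc_dims) - 1:
            layers.append(nn.LeakyReLU())
    return nn.Sequential(layers, name="adapted")


# ---------------------------------------------------------------------------
# data handling


def augment_patch(patch: np.ndarray, seed: int, jitter: float = 0.10) -> np.ndarray:
    """Random flips, 90-degree rotations and colour jitter; label-preserving.

    ``patch`` is (H, W, 3); jitter scales brightness, contrast (around the
    mean) and saturation (around the luminance) by factors in [1-j, 1+j].
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(patch)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    out = np.rot90(out, k=int(rng.integers(4)))
    x = out.astype(float)
    b, c, s = 1.0 + jitter * rng.uniform(-1, 1, size=3)
    x = x * b
    x = x.reshape(-1, 3).mean(axis=0) + c * (x - x.reshape(-1, 3).mean(axis=0))
    gray = x @ np.array([0.299, 0.587, 0.114])
    x = gray[..., None] + s * (x - gray[..., None])
    x = np.clip(x, 0, 255)
    return np.rint(x).astype(patch.dtype) if np.issubdtype(patch.dtype, np.integer) else x


def balanced_sampler(
    labels: np.ndarray,
    batch_size: int,
    n_batches: int,
    seed: int,
    positive_fraction: float | None = 0.5,
):
    """Yield index batches with an expected per-batch positive fraction.

    With ``positive_fraction=None`` (or equal to the prevalence within 1e-9)
    the sampler degenerates to plain epoch shuffling without replacement.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one example of each class")
    rng = np.random.default_rng(seed)
    prevalence = len(pos) / len(labels)
    if positive_fraction is None or abs(positive_fraction - prevalence) < 1e-9:
        order = rng.permutation(len(labels))
        for b in range(n_batches):
            lo = (b * batch_size) % len(labels)
            if lo + batch_size > len(labels):
                order = rng.permutation(len(labels))
                lo = 0
            yield order[lo : lo + batch_size]
        return
    for _ in range(n_batches):
        take_pos = rng.random(batch_size) < positive_fraction
        idx = np.where(
            take_pos,
            rng.choice(pos, size=batch_size),
            rng.choice(neg, size=batch_size),
        )
        yield idx


@dataclass
class PatchSet:
    """Patches with labels and patient (or source-scene) provenance."""

    images: np.ndarray  # (N, H, W, 3) uint8
    labels: np.ndarray  # (N,)
    patients: np.ndarray  # (N,) hashable ids

    def __len__(self):
        return len(self.labels)


@dataclass
class TrainingConfig:
    """Cell-classifier training settings (defaults follow the published setup)."""

    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 250
    momentum: float = 0.9
    seed: int = 0
    positive_fraction: float | None = 0.5
    augment: bool = True
    init_mode: str = "reciprocal"
    jitter: float = 0.10

    def __post_init__(self):
        if min(self.batch_size, self.epochs) <= 0 or self.learning_rate <= 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")


def _to_net_input(images: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    x = (images.astype(np.float32) - mu) / sigma
    return np.transpose(x, (0, 3, 1, 2))


def _f_score_binary(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    if tp == 0:
        return 0.0
    p, r = tp / (tp + fp), tp / (tp + fn)
    return 2 * p * r / (p + r)


def train_classifier(
    network: nn.Layer,
    train_set: PatchSet,
    val_set: PatchSet,
    config: TrainingConfig,
    batches_per_epoch: int | None = None,
):
    """Train with cross-entropy, cosine-annealed SGD and best-validation checkpointing.

    Train/validation patient sets must be disjoint; augmentation and
    oversampling apply to training batches only.  Returns ``(network,
    history)`` where history holds the per-epoch learning rate, training loss
    and validation F-score, plus the dataset standardization stats used.
    """
    overlap = set(np.unique(train_set.patients)) & set(np.unique(val_set.patients))
    if overlap:
        raise ValueError(f"train/validation patients overlap: {sorted(overlap)!r}")

    rng = np.random.default_rng(config.seed)
    mu = train_set.images.reshape(-1, 3).mean(axis=0).astype(np.float32)
    sigma = np.maximum(train_set.images.reshape(-1, 3).std(axis=0), 1e-3).astype(np.float32)
    x_val = _to_net_input(val_set.images, mu, sigma)

    if batches_per_epoch is None:
        batches_per_epoch = max(len(train_set) // config.batch_size, 1)
    opt = nn.SGD(network.params(), config.learning_rate, config.momentum, config.weight_decay)
    total_steps = config.epochs * batches_per_epoch

    history = {"lr": [], "train_loss": [], "val_f": [], "mu": mu, "sigma": sigma}
    best = (0.0, nn.get_state(network))
    step = 0
    for epoch in range(config.epochs):
        sampler = balanced_sampler(
            train_set.labels,
            config.batch_size,
            batches_per_epoch,
            seed=int(rng.integers(2**31)),
            positive_fraction=config.positive_fraction,
        )
        losses = []
        for idx in sampler:
            batch = train_set.images[idx]
            if config.augment:
                batch = np.stack(
                    [augment_patch(p, seed=int(rng.integers(2**31)), jitter=config.jitter) for p in batch]
                )
            x = _to_net_input(batch, mu, sigma)
            y = train_set.labels[idx]
            lr = nn.cosine_lr(config.learning_rate, step, total_steps)
            logits = network.forward(x, train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            opt.zero_grad()
            network.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
            step += 1
        val_pred = predict_scores(network, x_val, already_standardized=True)[:, 1] > 0.5
        val_f = _f_score_binary(val_pred.astype(int), val_set.labels)
        history["lr"].append(lr)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_f"].append(val_f)
        if val_f >= best[0]:  # ties keep the most-trained state
            best = (val_f, nn.get_state(network))
    nn.set_state(network, best[1])
    history["best_val_f"] = best[0]
    return network, history


def predict_scores(
    network: nn.Layer,
    patches: np.ndarray,
    stats=None,
    batch_size: int = 64,
    already_standardized: bool = False,
) -> np.ndarray:
    """Per-patch class probabilities (columns: non-mitosis, mitosis); rows sum to 1."""
    if already_standardized:
        x = np.asarray(patches, dtype=np.float32)
    else:
        if stats is None:
            raise ValueError("provide the training-set stats (mu, sigma)")
        mu, sigma = stats
        x = _to_net_input(np.asarray(patches), np.asarray(mu, np.float32), np.asarray(sigma, np.float32))
    expected = getattr(network, "input_shape", None)
    if expected is not None and tuple(x.shape[1:]) != tuple(expected):
        raise ValueError(f"patch shape {x.shape[1:]} does not match network input {expected}")
    if len(x) == 0:
        return np.zeros((0, 2))
    out = []
    for lo in range(0, len(x), batch_size):
        logits = network.forward(x[lo : lo + batch_size], train=False)
        out.append(nn.softmax(logits))
    return np.concatenate(out, axis=0)
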