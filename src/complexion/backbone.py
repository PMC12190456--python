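"""Convolutional feature extractors.

The production contract is the EfficientNet-B0 family: mobile inverted
bottleneck (MBConv) blocks with squeeze-and-excitation attention, a final
1x1 convolution to 1280 channels, and global average pooling, so the
extractor maps a ``(B, C, S, S)`` batch to ``(B, 1280)`` embeddings.  A
50-layer residual network is provided for the architecture comparison, and a
three-block ``tiny`` backbone (feature_dim 64) supports desk-scale training
of the full pipelines.

No pretrained weights ship with the package; ``pretrained=True`` falls back
to a seeded random initialisation and nothing downstream depends on
pretrained values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

#: architecture name -> global-pooled feature width
FEATURE_DIMS = {"efficientnet_b0": 1280, "resnet50": 2048, "tiny": 64}


@dataclass
class BackboneSpec:
    """Recipe for a feature extractor.

    ``pretrained`` is accepted for interface compatibility; offline builds
    always use the seeded random initialisation.
    """

    architecture: str = "efficientnet_b0"
    in_channels: int = 3
    pretrained: bool = False
    seed: int = 0

    @property
    def feature_dim(self) -> int:
        if self.architecture not in FEATURE_DIMS:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; supported: {sorted(FEATURE_DIMS)}"
            )
        return FEATURE_DIMS[self.architecture]


class FeatureExtractor(nn.Module):
    """Backbone trunk + global pooling; the classification head is removed."""

    def __init__(self, trunk: nn.Sequential, feature_dim: int, in_channels: int, architecture: str):
        self.trunk = trunk
        self.pool = nn.GlobalAvgPool2d()
        self.feature_dim = feature_dim
        self.in_channels = in_channels
        self.architecture = architecture

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (B, {self.in_channels}, H, W) input, got shape {x.shape}"
            )
        return self.pool(self.trunk(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.trunk.backward(self.pool.backward(grad))


def _conv_bn_act(cin, cout, k, stride, groups, rng, act=True):
    mods = [
        nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2, groups=groups, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
    ]
    if act:
        mods.append(nn.SiLU())
    return nn.Sequential(*mods)


def _mbconv(cin, cout, k, stride, expand, rng):
    cmid = cin * expand
    mods = []
    if expand != 1:
        mods.append(_conv_bn_act(cin, cmid, 1, 1, 1, rng))
    mods.append(_conv_bn_act(cmid, cmid, k, stride, cmid, rng))
    mods.append(nn.SqueezeExcite(cmid, max(1, cin // 4), rng=rng))
    mods.append(_conv_bn_act(cmid, cout, 1, 1, 1, rng, act=False))
    body = nn.Sequential(*mods)
    if stride == 1 and cin == cout:
        return nn.Residual(body)
    return body

# (expand, channels, repeats, stride, kernel) per stage of the B0 scaling
_B0_STAGES = [
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
]


def _build_efficientnet_b0_trunk(in_channels: int, rng) -> nn.Sequential:
    mods = [_conv_bn_act(in_channels, 32, 3, 2, 1, rng)]
    cin = 32
    for expand, cout, repeats, stride, k in _B0_STAGES:
        for r in range(repeats):
            mods.append(_mbconv(cin, cout, k, stride if r == 0 else 1, expand, rng))
            cin = cout
    mods.append(_conv_bn_act(cin, 1280, 1, 1, 1, rng))
    return nn.Sequential(*mods)


def _bottleneck(cin, width, stride, rng):
    cout = width * 4
    body = nn.Sequential(
        nn.Conv2d(cin, width, 1, bias=False, rng=rng), nn.BatchNorm2d(width), nn.ReLU(),
        nn.Conv2d(width, width, 3, stride=stride, padding=1, bias=False, rng=rng),
        nn.BatchNorm2d(width), nn.ReLU(),
        nn.Conv2d(width, cout, 1, bias=False, rng=rng), nn.BatchNorm2d(cout),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = nn.Sequential(
            nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng), nn.BatchNorm2d(cout)
        )
    return nn.Residual(body, shortcut=shortcut, post_act=nn.ReLU())


def _build_resnet50_trunk(in_channels: int, rng) -> nn.Sequential:
    mods = [
        nn.Conv2d(in_channels, 64, 7, stride=2, padding=3, bias=False, rng=rng),
        nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d(3, 2, padding=1),
    ]
    cin = 64
    for width, repeats, stride in [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]:
        for r in range(repeats):
            mods.append(_bottleneck(cin, width, stride if r == 0 else 1, rng))
            cin = width * 4
    return nn.Sequential(*mods)


def _build_tiny_trunk(in_channels: int, rng) -> nn.Sequential:
    mods = []
    cin = in_channels
    for cout in (16, 32, 64):
        mods.append(nn.Conv2d(cin, cout, 3, stride=2, padding=1, bias=False, rng=rng))
        mods.append(nn.BatchNorm2d(cout))
        mods.append(nn.ReLU())
        cin = cout
    return nn.Sequential(*mods)


_BUILDERS = {
    "efficientnet_b0": _build_efficientnet_b0_trunk,
    "resnet50": _build_resnet50_trunk,
    "tiny": _build_tiny_trunk,
}


def build_feature_extractor(spec: BackboneSpec) -> FeatureExtractor:
    """Construct the backbone named by ``spec`` as a global-pooled extractor."""
    if spec.architecture not in _BUILDERS:
        raise ValueError(
            f"unknown architecture {spec.architecture!r}; supported: {sorted(_BUILDERS)}"
        )
    rng = np.random.default_rng(spec.seed)
    trunk = _BUILDERS[spec.architecture](spec.in_channels, rng)
    return FeatureExtractor(trunk, spec.feature_dim, spec.in_channels, spec.architecture)


def build_classifier(spec: BackboneSpec, n_classes: int = 1000) -> nn.Sequential:
    """Backbone with its fully-connected classification head attached."""
    extractor = build_feature_extractor(spec)
    head_rng = np.random.default_rng(spec.seed + 1)
    return nn.Sequential(extractor, nn.Linear(spec.feature_dim, n_classes, rng=head_rng))


def _first_conv(extractor: FeatureExtractor) -> nn.Conv2d:
    mod = extractor.trunk.modules[0]
    while isinstance(mod, nn.Sequential):
        mod = mod.modules[0]
    assert isinstance(mod, nn.Conv2d)
    return mod


def adapt_input_channels(extractor: FeatureExtractor, target_channels: int,
                         init: str = "mean") -> FeatureExtractor:
    """Widen (or shrink) the first convolution to ``target_channels`` inputs.

    ``init='mean'`` seeds each added channel's kernels with the mean of the
    existing RGB kernels so learned low-level filters keep responding;
    ``init='zero'`` leaves added channels inert so the RGB response is
    initially unchanged.
    """
    if target_channels < 1:
        raise ValueError("target_channels must be >= 1")
    conv = _first_conv(extractor)
    old = conv.weight.data
    cur = conv.in_channels
    if target_channels == cur:
        return extractor
    if init not in ("mean", "zero"):
        raise ValueError("init must be 'mean' or 'zero'")
    if target_channels < cur:
        new_w = old[:, :target_channels].copy()
    else:
        extra = old.mean(axis=1, keepdims=True) if init == "mean" else np.zeros_like(old[:, :1])
        new_w = np.concatenate([old] + [extra] * (target_channels - cur), axis=1)
    conv.weight = nn.Parameter(new_w)
    conv.in_channels = target_channels
    extractor.in_channels = target_channels
    return extractor


def count_parameters(model: nn.Module) -> int:
    """Exact count of trainable scalars (running BN statistics excluded)."""
    return model.num_parameters()


def normalize_batch(images: np.ndarray) -> np.ndarray:
    """uint8 (B, H, W, C) -> float32 (B, C, H, W), scaled to [0,1] then
    standardised with natural-image channel statistics.

    A fourth (grayscale) channel, when present, uses the mean of the RGB
    statistics.
    """
    if images.ndim != 4:
        raise ValueError("expected (B, H, W, C) batch")
    c = images.shape[3]
    x = images.astype(np.float32) / 255.0
    mean = IMAGENET_MEAN
    std = IMAGENET_STD
    if c == 4:
        mean = np.concatenate([mean, [float(IMAGENET_MEAN.mean())]])
        std = np.concatenate([std, [float(IMAGENET_STD.mean())]])
    elif c != 3:
        raise ValueError(f"expected 3 or 4 channels, got {c}")
    x = (x - mean) / std
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


@dataclass
class TrainConfig:
    """SGD fine-tuning hyperparameters (defaults follow the study protocol)."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epochs: int = 50
    batch_size: int = 16
    input_side: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("hyperparameters must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.input_side < 8:
            raise ValueError("input_side must be >= 8")


def extract_features(extractor: FeatureExtractor, batch: np.ndarray) -> np.ndarray:
    """Embed a preprocessed ``(B, C, S, S)`` batch to ``(B, feature_dim)``.

    Runs in eval mode (running BN statistics), so batching is irrelevant:
    a crop embeds identically alone or inside a larger batch.
    """
    if batch.ndim != 4:
        raise ValueError("expected a 4-D (B, C, S, S) batch")
    if batch.shape[1] != extractor.in_channels:
        raise ValueError(
            f"extractor expects {extractor.in_channels} channels, got {batch.shape[1]}"
        )
    was_training = extractor.training
    extractor.eval()
    try:
        feats = extractor(batch.astype(np.float32))
    finally:
        extractor.train(was_training)
    return feats
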