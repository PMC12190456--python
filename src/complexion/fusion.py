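"""Multi-feature fusion classification pipeline.

Each face is segmented into N ROI crops; every crop is resized to
``input_side`` squares, optionally extended from RGB to four channels with a
BT.601 grayscale plane, and embedded by a convolutional backbone into a
``feature_dim``-vector.  The per-ROI embeddings are fused channel-wise into
a ``(B, feature_dim, N)`` block, flattened to ``(B, feature_dim x N)`` and
classified by a single fully-connected layer — no hidden layer.  Training
uses SGD with momentum, L2 weight decay and a cross-entropy objective.

With N = 1 and a whole-face "crop" the same machinery degenerates to the
plain whole-image classifier baseline; with ``channels=3`` the grayscale
ablation is recovered.  All ablation variants differ only in configuration,
never in code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .backbone import BackboneSpec, TrainConfig, build_feature_extractor, normalize_batch
from .data_model import DatasetManifest, FaceSample
from .imageops import bt601_luma, resize_image
from .labels import LABELS, N_CLASSES
from .roi import ROI_ORDER, ROIName, segment_rois


def to_rgbg(image: np.ndarray) -> np.ndarray:
    """Append a BT.601 luma plane to an H x W x 3 uint8 image -> H x W x 4."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    return np.concatenate([image, bt601_luma(image)[..., None]], axis=2)


@dataclass
class FusionConfig:
    """ROI set, channel mode and training hyperparameters for the pipeline."""

    roi_set: tuple[ROIName, ...] = ROI_ORDER
    channels: int = 4
    shared_backbone: bool = True
    architecture: str = "tiny"
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        self.roi_set = tuple(
            ROIName.from_name(r) if isinstance(r, str) else r for r in self.roi_set
        )
        if len(self.roi_set) < 1:
            raise ValueError("roi_set must name at least one ROI")
        if self.channels not in (3, 4):
            raise ValueError("channels must be 3 (RGB) or 4 (RGB + grayscale)")

    @property
    def n_rois(self) -> int:
        return len(self.roi_set)


class FusionClassifier(nn.Module):
    """Per-ROI extractor(s) -> fused feature block -> flatten -> FC logits."""

    def __init__(self, config: FusionConfig, n_classes: int = N_CLASSES):
        self.config = config
        spec = BackboneSpec(
            architecture=config.architecture,
            in_channels=config.channels,
            seed=config.train.seed,
        )
        n = config.n_rois
        if config.shared_backbone:
            shared = build_feature_extractor(spec)
            self.extractors = [shared] * n
        else:
            self.extractors = [
                build_feature_extractor(replace(spec, seed=spec.seed + j)) for j in range(n)
            ]
        self.feature_dim = spec.feature_dim
        self.head = nn.Linear(
            self.feature_dim * n, n_classes, rng=np.random.default_rng(config.train.seed + 101)
        )

    @property
    def flattened_width(self) -> int:
        return self.head.in_features

    def fuse_features(self, branches: list[np.ndarray]) -> np.ndarray:
        """(B, C, S, S) per ROI -> (B, feature_dim, N) fused block.

        Column j depends only on ROI j's crops (locality of extraction).
        """
        if len(branches) != self.config.n_rois:
            raise ValueError(f"expected {self.config.n_rois} ROI branches, got {len(branches)}")
        feats = [ext(xb.astype(np.float32)) for ext, xb in zip(self.extractors, branches)]
        return np.stack(feats, axis=2)

    def logits(self, branches: list[np.ndarray]) -> np.ndarray:
        block = self.fuse_features(branches)
        return self.head(block.reshape(block.shape[0], -1))


def preprocess_sample(sample: FaceSample, config: FusionConfig) -> list[np.ndarray]:
    """Segment, resize and normalise one sample into per-ROI (C, S, S) planes."""
    crops = segment_rois(sample, config.roi_set)
    side = config.train.input_side
    out = []
    for crop in crops:
        img = resize_image(crop.image, (side, side))
        if config.channels == 4:
            img = to_rgbg(img)
        out.append(normalize_batch(img[None])[0])
    return out


def _branch_tensors(samples: list[FaceSample], config: FusionConfig) -> list[np.ndarray]:
    per_sample = [preprocess_sample(s, config) for s in samples]
    return [
        np.stack([ps[j] for ps in per_sample]) for j in range(config.n_rois)
    ]


def _label_indices(samples: list[FaceSample]) -> np.ndarray:
    return np.array([s.label.code - 1 for s in samples], dtype=int)


def train_fusion(
    manifest: DatasetManifest | list[FaceSample],
    config: FusionConfig,
) -> tuple[FusionClassifier, list[float]]:
    """Fit the fusion classifier; returns the model and per-epoch mean loss.

    The backbone and head are optimised jointly.  Deterministic for a fixed
    ``config.train.seed`` under single-threaded execution.
    """
    samples = list(manifest)
    present = {s.label for s in samples}
    missing = [lab.value for lab in LABELS if lab not in present]
    if missing:
        raise ValueError(f"training split lacks class(es) {missing}; the head is untrainable")
    model = FusionClassifier(config)
    cfg = config.train
    branches = _branch_tensors(samples, config)
    targets = _label_indices(samples)
    history = _sgd_epochs(model, model.extractors, model.head, branches, targets, cfg)
    return model, history


def _sgd_epochs(model, extractors, head, branches, targets, cfg: TrainConfig) -> list[float]:
    """Mini-batch SGD over a multi-branch model; returns per-epoch mean loss."""
    n = targets.size
    n_branches = len(branches)
    shared = n_branches > 1 and all(e is extractors[0] for e in extractors)
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    model.train(True)
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = [b[idx] for b in branches]
            yb = targets[idx]
            opt.zero_grad()
            feats = [ext(x) for ext, x in zip(extractors, xb)]
            block = np.stack(feats, axis=2)
            logits = head(block.reshape(len(idx), -1))
            loss, dlogits = nn.cross_entropy(logits, yb)
            dblock = head.backward(dlogits).reshape(block.shape)
            for j in range(n_branches - 1, -1, -1):
                # a shared backbone holds only the last branch's caches, so
                # earlier branches are re-forwarded before their backward
                if shared and j != n_branches - 1:
                    extractors[j](xb[j])
                extractors[j].backward(np.ascontiguousarray(dblock[:, :, j]))
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    model.eval()
    return history


def predict_fusion(
    model: FusionClassifier,
    samples: DatasetManifest | list[FaceSample],
) -> tuple[list[str], np.ndarray]:
    """Predict labels and class probabilities for complete face images.

    Each input is a whole face with landmarks; ROI segmentation happens
    inside prediction, then the trained extractor scores the regions.
    Returns (label names, (B, 5) probability rows summing to 1).
    """
    samples = list(samples)
    model.eval()
    branches = _branch_tensors(samples, model.config)
    probs = nn.softmax(model.logits(branches))
    labels = [LABELS[int(k)].value for k in probs.argmax(axis=1)]
    return labels, probs


def evaluate_accuracy(model: FusionClassifier, samples) -> float:
    samples = list(samples)
    pred, _ = predict_fusion(model, samples)
    true = [s.label.value for s in samples]
    return float(np.mean([p == t for p, t in zip(pred, true)]))
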