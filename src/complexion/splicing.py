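"""Multi-feature splicing classification pipeline.

ROI crops vary in size across faces, so each ROI is first standardised to
the dataset-median size for that region.  Each resized crop is then spread
in the channel dimension — flattened row-major to an ``(h_i x w_i, 3)``
pixel sequence — the six sequences are concatenated in ROI order into a
``(P, 3)`` sequence, and the sequence is reshaped row-major into one
near-square composite image of shape ``(h_out, w_out, 3)`` with
``w_out = floor(sqrt(P))``, ``h_out = ceil(P / w_out)`` and trailing cells
zero-padded.  The composite images form a new dataset on which a standard
single-image classifier is trained.

The transform is exactly invertible given its :class:`SpliceRecord`
bookkeeping; :func:`unsplice` is the test oracle for that inverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .backbone import TrainConfig, normalize_batch
from .data_model import DatasetManifest, FaceSample, save_manifest
from .fusion import FusionClassifier, FusionConfig, _label_indices, _sgd_epochs, to_rgbg
from .imageops import resize_image
from .labels import LABELS
from .roi import ROI_ORDER, ROIBox, ROICrop, ROIName, segment_rois


@dataclass
class SizeManifest:
    """Per-ROI median target sizes and the derived composite geometry."""

    rois: tuple[ROIName, ...]
    sizes: dict[ROIName, tuple[int, int]]  # roi -> (h, w)

    @property
    def total_pixels(self) -> int:
        return sum(h * w for h, w in self.sizes.values())

    @property
    def output_size(self) -> tuple[int, int]:
        p = self.total_pixels
        w_out = int(np.floor(np.sqrt(p)))
        h_out = int(np.ceil(p / w_out))
        return h_out, w_out

    @property
    def pad_length(self) -> int:
        h_out, w_out = self.output_size
        return h_out * w_out - self.total_pixels


@dataclass
class SpliceRecord:
    """Everything needed to invert one spliced image back to its crops."""

    rois: tuple[ROIName, ...]
    sizes: dict[ROIName, tuple[int, int]]
    pad_length: int

    def to_json(self) -> str:
        return json.dumps({
            "rois": [r.value for r in self.rois],
            "sizes": {r.value: list(self.sizes[r]) for r in self.rois},
            "pad_length": self.pad_length,
        })

    @classmethod
    def from_json(cls, text: str) -> "SpliceRecord":
        data = json.loads(text)
        rois = tuple(ROIName.from_name(r) for r in data["rois"])
        sizes = {r: tuple(data["sizes"][r.value]) for r in rois}
        return cls(rois, sizes, int(data["pad_length"]))


def _median_half_up(values: np.ndarray) -> int:
    """Median; for even counts the mean of the middle two, rounded half up."""
    return int(np.floor(np.median(values) + 0.5))


def median_roi_sizes(
    manifest: DatasetManifest | list[FaceSample],
    rois: tuple[ROIName, ...] = ROI_ORDER,
) -> SizeManifest:
    """Per-ROI median crop height and width across the dataset."""
    samples = list(manifest)
    if not samples:
        raise ValueError("cannot take median ROI sizes of an empty manifest")
    rois = tuple(ROIName.from_name(r) if isinstance(r, str) else r for r in rois)
    if not rois:
        raise ValueError("ROI list must not be empty")
    heights = {r: [] for r in rois}
    widths = {r: [] for r in rois}
    for s in samples:
        for crop in segment_rois(s, rois):
            heights[crop.roi].append(crop.box.height)
            widths[crop.roi].append(crop.box.width)
    sizes = {
        r: (_median_half_up(np.array(heights[r])), _median_half_up(np.array(widths[r])))
        for r in rois
    }
    return SizeManifest(rois, sizes)


def splice_sample(
    crops: list[ROICrop],
    sizes: SizeManifest,
) -> tuple[np.ndarray, SpliceRecord]:
    """Resize, flatten, concatenate and reshape one sample's crops."""
    if tuple(c.roi for c in crops) != sizes.rois:
        raise ValueError(
            f"crop order {[c.roi.value for c in crops]} does not match "
            f"size manifest order {[r.value for r in sizes.rois]}"
        )
    sequences = []
    for crop in crops:
        h, w = sizes.sizes[crop.roi]
        resized = resize_image(crop.image, (h, w))
        sequences.append(resized.reshape(h * w, 3))
    seq = np.concatenate(sequences, axis=0)
    h_out, w_out = sizes.output_size
    pad = sizes.pad_length
    if pad:
        seq = np.concatenate([seq, np.zeros((pad, 3), dtype=seq.dtype)], axis=0)
    spliced = seq.reshape(h_out, w_out, 3)
    return spliced, SpliceRecord(sizes.rois, dict(sizes.sizes), pad)


def unsplice(spliced: np.ndarray, record: SpliceRecord) -> list[ROICrop]:
    """Exact inverse of :func:`splice_sample` down to the resized crops."""
    h_out, w_out = spliced.shape[:2]
    total = sum(h * w for h, w in record.sizes.values())
    if h_out * w_out != total + record.pad_length:
        raise ValueError(
            f"record expects {total + record.pad_length} cells, image has {h_out * w_out}"
        )
    seq = spliced.reshape(h_out * w_out, 3)
    crops = []
    offset = 0
    for roi in record.rois:
        h, w = record.sizes[roi]
        block = seq[offset : offset + h * w].reshape(h, w, 3)
        crops.append(ROICrop(roi, ROIBox(0, 0, w, h), np.ascontiguousarray(block)))
        offset += h * w
    return crops


def build_spliced_dataset(
    manifest: DatasetManifest,
    rois: tuple[ROIName, ...],
    sizes: SizeManifest,
    out_dir: str | Path,
) -> DatasetManifest:
    """Write one spliced PNG (plus a JSON splice record) per sample."""
    rois = tuple(ROIName.from_name(r) if isinstance(r, str) else r for r in rois)
    if not rois:
        raise ValueError("ROI list must not be empty")
    if rois != sizes.rois:
        raise ValueError("size manifest was computed for a different ROI list")
    out_dir = Path(out_dir)
    img_dir = out_dir / "spliced"
    img_dir.mkdir(parents=True, exist_ok=True)
    samples = []
    for s in manifest:
        crops = segment_rois(s, rois)
        spliced, record = splice_sample(crops, sizes)
        img_path = img_dir / f"{s.sample_id}.png"
        Image.fromarray(spliced).save(img_path)
        (img_dir / f"{s.sample_id}.json").write_text(record.to_json())
        samples.append(FaceSample(s.sample_id, s.label, img_path, None, s.split))
    spliced_manifest = DatasetManifest(samples)
    save_manifest(spliced_manifest, out_dir / "spliced.csv")
    return spliced_manifest


@dataclass
class WholeImageConfig:
    """Single-image classifier settings for the spliced dataset."""

    channels: int = 3
    architecture: str = "tiny"
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class SplicedClassifier:
    """Backbone + 5-class head operating on whole (composite) images."""

    model: FusionClassifier

    def _tensor(self, samples: list[FaceSample]) -> np.ndarray:
        side = self.model.config.train.input_side
        planes = []
        for s in samples:
            im = resize_image(s.image, (side, side))
            if self.model.config.channels == 4:
                im = to_rgbg(im)
            planes.append(normalize_batch(im[None])[0])
        return np.stack(planes)

    def predict(self, manifest) -> tuple[list[str], np.ndarray]:
        samples = list(manifest)
        self.model.eval()
        probs = nn.softmax(self.model.logits([self._tensor(samples)]))
        labels = [LABELS[int(k)].value for k in probs.argmax(axis=1)]
        return labels, probs

    def accuracy(self, manifest) -> float:
        samples = list(manifest)
        pred, _ = self.predict(samples)
        return float(np.mean([p == s.label.value for p, s in zip(pred, samples)]))


def train_on_spliced(
    manifest: DatasetManifest | list[FaceSample],
    config: WholeImageConfig | None = None,
) -> tuple[SplicedClassifier, list[float]]:
    """Train a standard single-image classifier on spliced composites.

    Same optimiser contracts as the fusion trainer (SGD, cross-entropy,
    per-epoch loss history, seeded determinism); no segmentation happens
    here — the composites are consumed as-is.
    """
    config = config or WholeImageConfig()
    samples = list(manifest)
    side = config.train.input_side
    planes = []
    for s in samples:
        im = resize_image(s.image, (side, side))
        if config.channels == 4:
            im = to_rgbg(im)
        planes.append(normalize_batch(im[None])[0])
    x = np.stack(planes)
    targets = _label_indices(samples)
    fc = FusionConfig(roi_set=(ROI_ORDER[0],), channels=config.channels,
                      architecture=config.architecture, train=config.train)
    model = FusionClassifier(fc)
    history = _sgd_epochs(model, model.extractors, model.head, [x], targets, config.train)
    return SplicedClassifier(model), history
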