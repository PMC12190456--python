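"""Synthetic face-like fixtures with programmatic 68-point landmarks.

The clinical dataset behind the complexion pipelines is private, so this
module renders schematic frontal faces whose five classes differ only by
ROI-local colour distributions: a skin-tone ellipse on a flat background,
with each of the six landmark-derived ROI boxes filled from a per-class,
per-ROI palette plus i.i.d. Gaussian pixel noise.  Class-discriminative
colour sits mainly in the cheeks, forehead and nose and only weakly in the
chin and philtrum, mirroring the observation that those two regions share
similar colour characteristics.  Ground truth (the palette and the colours
actually rendered) is recorded per sample, which makes recovery experiments
quantitative.

Everything is a pure function of (config, seed): same seed, byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .data_model import DatasetManifest, FaceSample, save_manifest
from .labels import LABELS, ComplexionLabel
from .landmarks import LandmarkSet, save_landmarks
from .roi import ROI_ORDER, ROIName, roi_box

#: per-class counts emulating the study's 131:134:168:160:128 ratio (721 total)
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "dark": 131, "red": 134, "pallid": 168, "sallow": 160, "normal": 128,
}

BASE_SKIN = np.array([205.0, 175.0, 150.0])
BACKGROUND = np.array([70.0, 80.0, 90.0])

# full-strength per-class colour shifts away from the base skin tone
_CLASS_SHIFTS: dict[str, np.ndarray] = {
    "dark": np.array([-70.0, -60.0, -50.0]),
    "red": np.array([35.0, -30.0, -30.0]),
    "pallid": np.array([30.0, 28.0, 35.0]),
    "sallow": np.array([15.0, 20.0, -55.0]),
    "normal": np.array([0.0, 0.0, 0.0]),
}

# chin and philtrum carry only a quarter of the shift (weakly informative)
_WEAK_ROIS = {ROIName.CHIN, ROIName.PHILTRUM}
_WEAK_FACTOR = 0.25


def default_palette(separation: float = 1.0) -> dict[str, dict[str, list[float]]]:
    """Class x ROI mean RGB palette.

    ``separation`` scales every class shift toward the common base tone:
    0 makes all classes identical (any classifier is at chance), 1 is the
    default separable palette.
    """
    palette: dict[str, dict[str, list[float]]] = {}
    for label in LABELS:
        shifts = _CLASS_SHIFTS[label.value] * separation
        palette[label.value] = {}
        for roi in ROI_ORDER:
            factor = _WEAK_FACTOR if roi in _WEAK_ROIS else 1.0
            # integer-valued means render exactly under zero noise
            color = np.rint(np.clip(BASE_SKIN + factor * shifts, 0, 255))
            palette[label.value][roi.value] = [float(v) for v in color]
    return palette


def load_palette(path: str | Path) -> dict[str, dict[str, list[float]]]:
    """Read a YAML palette file (class -> roi -> [R, G, B])."""
    palette = yaml.safe_load(Path(path).read_text())
    _check_palette(palette)
    return palette


def _check_palette(palette) -> None:
    for label in LABELS:
        if label.value not in palette:
            raise ValueError(f"palette missing class {label.value!r}")
        for roi in ROI_ORDER:
            if roi.value not in palette[label.value]:
                raise ValueError(f"palette missing {label.value}/{roi.value}")


@dataclass
class SyntheticConfig:
    image_side: int = 256
    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    palette: dict[str, dict[str, list[float]]] = field(default_factory=default_palette)
    noise_sd: float = 8.0
    landmark_jitter_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.landmark_jitter_sd < 0:
            raise ValueError("noise_sd and landmark_jitter_sd must be >= 0")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class_counts must be nonnegative")
        _check_palette(self.palette)


@dataclass
class SyntheticSampleRecord:
    """A rendered sample plus the colours actually painted into each ROI."""

    sample: FaceSample
    palette_means: dict[str, list[float]]
    rendered_means: dict[str, list[float]]


def _template_points() -> np.ndarray:
    """Canonical frontal-face layout in unit coordinates (x right, y down)."""
    pts = np.zeros((68, 2))
    t = np.linspace(0.0, np.pi, 17)
    pts[0:17, 0] = 0.5 - 0.38 * np.cos(t)                      # jaw, left temple -> chin -> right temple
    pts[0:17, 1] = 0.35 + 0.58 * np.sin(t)
    for k in range(5):                                          # brows
        frac = k / 4.0
        arch = 0.02 * np.sin(np.pi * frac)
        pts[17 + k] = (0.20 + 0.22 * frac, 0.30 - arch)
        pts[22 + k] = (0.58 + 0.22 * frac, 0.30 - 0.02 * np.sin(np.pi * (1 - frac)))
    pts[27:31] = [(0.5, 0.34), (0.5, 0.40), (0.5, 0.46), (0.5, 0.52)]   # nose bridge
    pts[31:36] = [(0.42, 0.56), (0.46, 0.57), (0.5, 0.58), (0.54, 0.57), (0.58, 0.56)]
    pts[36:42] = [(0.24, 0.38), (0.28, 0.36), (0.33, 0.36),             # right eye (image left)
                  (0.37, 0.38), (0.33, 0.40), (0.28, 0.40)]
    pts[42:48] = [(0.63, 0.38), (0.67, 0.36), (0.72, 0.36),             # left eye
                  (0.76, 0.38), (0.72, 0.40), (0.67, 0.40)]
    pts[48:55] = [(0.36, 0.74), (0.40, 0.72), (0.45, 0.71), (0.50, 0.705),
                  (0.55, 0.71), (0.60, 0.72), (0.64, 0.74)]             # outer lip, upper
    pts[55:60] = [(0.59, 0.77), (0.55, 0.785), (0.50, 0.79), (0.45, 0.785), (0.41, 0.77)]
    pts[60:65] = [(0.40, 0.74), (0.45, 0.735), (0.50, 0.735), (0.55, 0.735), (0.60, 0.74)]
    pts[65:68] = [(0.55, 0.755), (0.50, 0.76), (0.45, 0.755)]           # inner lip, lower
    return pts


def canonical_landmarks(
    image_side: int,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LandmarkSet:
    """Scale the frontal-face template to the image and add Gaussian jitter.

    Points are clipped in-bounds after jittering; deterministic for a fixed
    generator state.
    """
    if image_side < 64:
        raise ValueError(f"image_side must be >= 64 (template degenerate below), got {image_side}")
    pts = _template_points() * image_side
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
    pts = np.clip(pts, 0, image_side - 1)
    return LandmarkSet(pts)


def render_face(
    label: ComplexionLabel,
    landmarks: LandmarkSet,
    config: SyntheticConfig,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
) -> SyntheticSampleRecord:
    """Paint one face: background, skin ellipse, then the six ROI fills."""
    side = config.image_side
    img = np.empty((side, side, 3))
    img[:] = BACKGROUND
    yy, xx = np.mgrid[0:side, 0:side]
    cx, cy = 0.5 * side, 0.52 * side
    ax, ay = 0.40 * side, 0.45 * side
    face = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    img[face] = BASE_SKIN
    if config.noise_sd > 0:
        img[face] += rng.normal(0.0, config.noise_sd, (int(face.sum()), 3))
    palette_means: dict[str, list[float]] = {}
    boxes = {}
    for roi in ROI_ORDER:
        box = roi_box(landmarks, roi, image_size=(side, side))
        boxes[roi] = box
        mean = np.asarray(config.palette[label.value][roi.value], dtype=float)
        palette_means[roi.value] = [float(v) for v in mean]
        patch = np.broadcast_to(mean, (box.height, box.width, 3)).copy()
        if config.noise_sd > 0:
            patch += rng.normal(0.0, config.noise_sd, patch.shape)
        img[box.y0 : box.y1, box.x0 : box.x1] = patch
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    rendered_means = {
        roi.value: [float(v) for v in
                    out[b.y0 : b.y1, b.x0 : b.x1].reshape(-1, 3).mean(axis=0)]
        for roi, b in boxes.items()
    }
    sample = FaceSample(sample_id, label, _image=out, _landmarks=landmarks)
    return SyntheticSampleRecord(sample, palette_means, rendered_means)


def generate_samples(config: SyntheticConfig) -> list[SyntheticSampleRecord]:
    """Render every sample in memory, deterministically from config.seed."""
    records: list[SyntheticSampleRecord] = []
    for ci, label in enumerate(LABELS):
        count = int(config.class_counts.get(label.value, 0))
        for i in range(count):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, ci, i)))
            lm = canonical_landmarks(config.image_side, config.landmark_jitter_sd, rng)
            sid = f"{label.value}_{i:04d}"
            records.append(render_face(label, lm, config, rng, sample_id=sid))
    return records


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> DatasetManifest:
    """Write images, landmark sidecars and a manifest CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    lmk_dir = out_dir / "landmarks"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
        lmk_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    samples: list[FaceSample] = []
    truth: dict[str, dict] = {}
    for rec in generate_samples(config):
        sid = rec.sample.sample_id
        img_path = img_dir / f"{sid}.png"
        lmk_path = lmk_dir / f"{sid}.json"
        Image.fromarray(rec.sample.image).save(img_path)
        save_landmarks(rec.sample._landmarks, lmk_path)
        truth[sid] = {"palette": rec.palette_means, "rendered": rec.rendered_means}
        samples.append(FaceSample(sid, rec.sample.label, img_path, lmk_path))
    manifest = DatasetManifest(samples)
    save_manifest(manifest, out_dir / "manifest.csv")
    (out_dir / "ground_truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    return manifest
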