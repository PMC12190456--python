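"""Dataset manifest I/O, train/test splitting and flip augmentation.

A manifest is a UTF-8 CSV with header columns ``sample_id``, ``image_path``,
``landmark_path`` (optional), ``label`` and ``split`` (optional).  Paths are
resolved relative to the manifest's directory.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .labels import ComplexionLabel
from .landmarks import LandmarkSet, load_landmarks

_SPLITS = ("train", "test", "none")


@dataclass
class FaceSample:
    """One face photograph with its label and (optional) landmark set."""

    sample_id: str
    label: ComplexionLabel
    image_path: Path | None = None
    landmark_path: Path | None = None
    split: str = "none"
    _image: np.ndarray | None = field(default=None, repr=False)
    _landmarks: LandmarkSet | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.split not in _SPLITS:
            raise ValueError(f"split must be one of {_SPLITS}, got {self.split!r}")

    @property
    def image(self) -> np.ndarray:
        """H x W x 3 uint8 RGB raster (lazily loaded, then cached)."""
        if self._image is None:
            if self.image_path is None:
                raise ValueError(f"sample {self.sample_id}: no image attached or on disk")
            with Image.open(self.image_path) as im:
                self._image = np.asarray(im.convert("RGB"))
        return self._image

    @property
    def landmarks(self) -> LandmarkSet | None:
        if self._landmarks is None and self.landmark_path is not None:
            self._landmarks = load_landmarks(self.landmark_path)
        return self._landmarks

    def require_landmarks(self) -> LandmarkSet:
        lm = self.landmarks
        if lm is None:
            raise ValueError(
                f"sample {self.sample_id} has no landmarks; supply a 68-point sidecar "
                "(JSON or pts) or run an external landmark detector first"
            )
        return lm


@dataclass
class DatasetManifest:
    samples: list[FaceSample]

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(s.label.value for s in self.samples))

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def subset(self, indices, split: str | None = None) -> "DatasetManifest":
        chosen = [self.samples[i] for i in indices]
        if split is not None:
            chosen = [replace(s, split=split) for s in chosen]
        return DatasetManifest(chosen)


def load_manifest(path: str | Path, check_files: bool = True) -> DatasetManifest:
    """Read a manifest CSV; labels are validated row by row.

    ``check_files`` verifies that every referenced image (and landmark
    sidecar) exists at load time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    base = path.parent
    samples: list[FaceSample] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "image_path", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: manifest header must include {sorted(required)}")
        for row_no, row in enumerate(reader, start=2):  # header is line 1
            try:
                label = ComplexionLabel.from_name(row["label"])
            except ValueError as exc:
                raise ValueError(f"{path} row {row_no}: {exc}") from None
            img = base / row["image_path"]
            lmk = row.get("landmark_path") or None
            lmk_path = base / lmk if lmk else None
            if check_files:
                if not img.exists():
                    raise FileNotFoundError(f"{path} row {row_no}: image not found: {img}")
                if lmk_path is not None and not lmk_path.exists():
                    raise FileNotFoundError(f"{path} row {row_no}: landmarks not found: {lmk_path}")
            split = (row.get("split") or "none").strip().lower() or "none"
            if split not in _SPLITS:
                raise ValueError(f"{path} row {row_no}: invalid split {split!r}")
            samples.append(FaceSample(row["sample_id"], label, img, lmk_path, split))
    return DatasetManifest(samples)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    base = path.parent
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "image_path", "landmark_path", "label", "split"])
        for s in manifest.samples:
            img = _relativize(s.image_path, base)
            lmk = _relativize(s.landmark_path, base) if s.landmark_path else ""
            writer.writerow([s.sample_id, img, lmk, s.label.value, s.split])


def _relativize(p: Path | None, base: Path) -> str:
    if p is None:
        return ""
    try:
        return Path(p).relative_to(base).as_posix()
    except ValueError:
        return Path(p).as_posix()


def split_dataset(
    manifest: DatasetManifest,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[DatasetManifest, DatasetManifest]:
    """Disjoint, exhaustive train/test partition (default 8:2).

    With ``stratified`` (the default) each class contributes
    round-half-up(ratio x count) samples to train and the remainder to test,
    so the class ratio survives the split.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(manifest)
    if stratified:
        by_class: dict[str, list[int]] = {}
        for i, s in enumerate(manifest.samples):
            by_class.setdefault(s.label.value, []).append(i)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for name in sorted(by_class):
            idx = np.array(by_class[name])
            if idx.size < 2:
                raise ValueError(
                    f"class {name!r} has {idx.size} sample(s); stratified splitting needs >= 2"
                )
            perm = rng.permutation(idx.size)
            n_train = int(np.floor(ratio * idx.size + 0.5))  # round half up
            train_idx.extend(idx[perm[:n_train]])
            test_idx.extend(idx[perm[n_train:]])
        train_idx.sort()
        test_idx.sort()
    else:
        perm = rng.permutation(n)
        n_train = int(np.floor(ratio * n + 0.5))
        train_idx = sorted(perm[:n_train].tolist())
        test_idx = sorted(perm[n_train:].tolist())
    return manifest.subset(train_idx, split="train"), manifest.subset(test_idx, split="test")


def hflip_augment(sample: FaceSample) -> FaceSample:
    """Horizontally mirrored copy: image columns reversed, landmark x
    coordinates mapped to W-1-x with indices re-permuted so anatomical
    identities (left eye stays the left eye) are preserved.  Label and split
    carry over unchanged; the flipped copy keeps the original's split so a
    flip pair can never straddle train and test.
    """
    img = sample.image
    flipped = np.ascontiguousarray(img[:, ::-1])
    lm = sample.landmarks
    flipped_lm = lm.hflip(img.shape[1]) if lm is not None else None
    return FaceSample(
        sample_id=f"{sample.sample_id}_hflip",
        label=sample.label,
        image_path=None,
        landmark_path=None,
        split=sample.split,
        _image=flipped,
        _landmarks=flipped_lm,
    )
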