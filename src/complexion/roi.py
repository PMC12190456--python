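"""Six facial regions of interest from 68-point landmark geometry.

Only the chin construction is anchored to a published recipe (the bounding
box of points 9, 56, 58 and 60, 1-based); the other five boxes are this
package's documented conventions, chosen to be deterministic, anatomically
plausible and mirror-symmetric:

* nose      — bounding box of points 28-36, inset 10% per side;
* philtrum  — x across points 33-35, y from point 34 down to point 52;
* chin      — bounding box of points 9, 56, 58, 60;
* right_cheek — x between points 4 and 49, y between points 29 and 5;
* left_cheek  — the mirrored construction (points 14, 55, 29, 13);
* forehead  — x across points 18-27, extending upward from the brow line by
  0.6 x (brow-to-jaw height) / 3, clipped to the frame (the 68-point scheme
  has no forehead landmarks, so upward extrapolation is unavoidable).

Boxes are 0-based, half-open ``[x0, x1) x [y0, y1)`` and clipped to the
image frame; a box that clips to zero area is an error naming the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .landmarks import LandmarkSet, validate_landmarks  # noqa: F401  (re-export)


class ROIName(Enum):
    NOSE = "nose"
    FOREHEAD = "forehead"
    PHILTRUM = "philtrum"
    CHIN = "chin"
    RIGHT_CHEEK = "right_cheek"
    LEFT_CHEEK = "left_cheek"

    @classmethod
    def from_name(cls, name: str) -> "ROIName":
        try:
            return cls(name.strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown ROI {name!r}; valid ROIs: {valid}") from None


#: canonical order consumed by the fusion and splicing pipelines
ROI_ORDER: tuple[ROIName, ...] = tuple(ROIName)

#: the five-region set found to classify best (chin dropped, philtrum kept)
BEST_ROI_SET: tuple[ROIName, ...] = (
    ROIName.NOSE,
    ROIName.FOREHEAD,
    ROIName.PHILTRUM,
    ROIName.RIGHT_CHEEK,
    ROIName.LEFT_CHEEK,
)


@dataclass(frozen=True)
class ROIBox:
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate box [{self.x0},{self.x1})x[{self.y0},{self.y1})")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def mirrored(self, image_width: int) -> "ROIBox":
        return ROIBox(image_width - self.x1, self.y0, image_width - self.x0, self.y1)


@dataclass
class ROICrop:
    roi: ROIName
    box: ROIBox
    image: np.ndarray  # h x w x 3 uint8, h/w equal the box dimensions


def _points(lm: LandmarkSet, numbers) -> np.ndarray:
    return np.array([lm.point(n) for n in numbers])


def _bbox(pts: np.ndarray) -> tuple[float, float, float, float]:
    return pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max()


def _raw_box(lm: LandmarkSet, roi: ROIName) -> tuple[float, float, float, float]:
    if roi is ROIName.CHIN:
        return _bbox(_points(lm, (9, 56, 58, 60)))
    if roi is ROIName.NOSE:
        x0, y0, x1, y1 = _bbox(_points(lm, range(28, 37)))
        dx, dy = 0.1 * (x1 - x0), 0.1 * (y1 - y0)
        return x0 + dx, y0 + dy, x1 - dx, y1 - dy
    if roi is ROIName.PHILTRUM:
        xs = _points(lm, (33, 34, 35))[:, 0]
        return xs.min(), lm.point(34)[1], xs.max(), lm.point(52)[1]
    if roi is ROIName.RIGHT_CHEEK:
        xa, xb = lm.point(4)[0], lm.point(49)[0]
        ya, yb = lm.point(29)[1], lm.point(5)[1]
        return min(xa, xb), min(ya, yb), max(xa, xb), max(ya, yb)
    if roi is ROIName.LEFT_CHEEK:
        xa, xb = lm.point(55)[0], lm.point(14)[0]
        ya, yb = lm.point(29)[1], lm.point(13)[1]
        return min(xa, xb), min(ya, yb), max(xa, xb), max(ya, yb)
    if roi is ROIName.FOREHEAD:
        brows = _points(lm, range(18, 28))
        x0, x1 = brows[:, 0].min(), brows[:, 0].max()
        brow_top = brows[:, 1].min()
        jaw_bottom = _points(lm, range(1, 18))[:, 1].max()
        extent = 0.6 * (jaw_bottom - brow_top) / 3.0
        return x0, brow_top - extent, x1, brow_top
    raise ValueError(f"unknown ROI {roi!r}")  # pragma: no cover


def roi_box(landmarks: LandmarkSet, roi: ROIName, image_size: tuple[int, int] | None = None) -> ROIBox:
    """Deterministic pixel box for one ROI; clipped to (W, H) when given."""
    fx0, fy0, fx1, fy1 = _raw_box(landmarks, roi)
    # half-open closure: the max coordinate pixel is included
    x0, y0 = int(np.floor(fx0)), int(np.floor(fy0))
    x1, y1 = int(np.floor(fx1)) + 1, int(np.floor(fy1)) + 1
    if image_size is not None:
        w, h = image_size
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"ROI {roi.value!r} collapses to zero area after clipping")
    return ROIBox(x0, y0, x1, y1)


def segment_rois(sample, rois: tuple[ROIName, ...] | list[ROIName] = ROI_ORDER) -> list[ROICrop]:
    """Crop the requested ROIs from a sample, in request order.

    The sample must carry landmarks (a sidecar or an in-memory set); crops
    are views restricted to each ROI's box.
    """
    lm = sample.require_landmarks() if hasattr(sample, "require_landmarks") else sample.landmarks
    img = sample.image
    h, w = img.shape[:2]
    crops = []
    for roi in rois:
        roi = ROIName.from_name(roi) if isinstance(roi, str) else roi
        box = roi_box(lm, roi, image_size=(w, h))
        crops.append(ROICrop(roi, box, img[box.y0 : box.y1, box.x0 : box.x1]))
    return crops
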