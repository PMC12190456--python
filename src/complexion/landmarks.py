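"""68-point facial landmark sets in the iBUG annotation scheme.

External files use the scheme's conventional 1-based point numbering
(jaw 1-17, brows 18-27, nose 28-36, eyes 37-48, mouth 49-68); in memory the
points array is 0-based.  Sidecars are read from JSON
(``{"points": [[x, y] * 68]}``) or from the pts text dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

N_LANDMARKS = 68


def _mirror_permutation() -> np.ndarray:
    """0-based index remap preserving anatomical identity under a horizontal flip."""
    perm = np.empty(N_LANDMARKS, dtype=int)
    perm[0:17] = np.arange(16, -1, -1)          # jaw
    perm[17:27] = np.arange(26, 16, -1)         # brows swap left/right
    perm[27:31] = np.arange(27, 31)             # nose bridge (midline)
    perm[31:36] = np.arange(35, 30, -1)         # nostril base
    perm[36:42] = [45, 44, 43, 42, 47, 46]      # right eye <-> left eye
    perm[42:48] = [39, 38, 37, 36, 41, 40]
    perm[48:55] = [54, 53, 52, 51, 50, 49, 48]  # outer lip, upper
    perm[55:60] = [59, 58, 57, 56, 55]          # outer lip, lower
    perm[60:65] = [64, 63, 62, 61, 60]          # inner lip, upper
    perm[65:68] = [67, 66, 65]                  # inner lip, lower
    return perm


MIRROR_PERMUTATION = _mirror_permutation()


@dataclass
class LandmarkSet:
    """68 (x, y) pixel coordinates, iBUG order, 0-based indexing in memory."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected ({N_LANDMARKS}, 2) points, got shape {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("landmark coordinates must be finite")
        self.points = pts

    def point(self, number: int) -> np.ndarray:
        """Access by the scheme's 1-based point number (as printed in annotations)."""
        if not 1 <= number <= N_LANDMARKS:
            raise ValueError(f"point number must be 1-{N_LANDMARKS}, got {number}")
        return self.points[number - 1]

    def hflip(self, width: int) -> "LandmarkSet":
        """Mirror across the vertical midline of a ``width``-pixel image."""
        flipped = self.points.copy()
        flipped[:, 0] = width - 1 - flipped[:, 0]
        return LandmarkSet(flipped[MIRROR_PERMUTATION])

    def scaled(self, factor: float) -> "LandmarkSet":
        return LandmarkSet(self.points * factor)


@dataclass
class ValidationReport:
    ok: bool
    failures: list[str] = field(default_factory=list)


def validate_landmarks(landmarks, image_size: tuple[int, int]) -> ValidationReport:
    """Check a candidate landmark set against a (W, H) frame.

    Report-returning: collects all failures instead of raising, so callers
    can surface every problem with a sidecar at once.
    """
    failures: list[str] = []
    pts = np.asarray(landmarks.points if isinstance(landmarks, LandmarkSet) else landmarks, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        return ValidationReport(False, [f"expected an (N, 2) point array, got shape {pts.shape}"])
    if pts.shape[0] != N_LANDMARKS:
        failures.append(f"expected {N_LANDMARKS} points, got {pts.shape[0]}")
    if not np.isfinite(pts).all():
        failures.append("non-finite coordinates present")
    else:
        w, h = image_size
        oob = np.where((pts[:, 0] < 0) | (pts[:, 0] >= w) | (pts[:, 1] < 0) | (pts[:, 1] >= h))[0]
        if oob.size:
            nums = ", ".join(str(i + 1) for i in oob[:5])
            failures.append(f"{oob.size} point(s) outside the [0,{w})x[0,{h}) frame (points {nums}...)")
        if pts.shape[0] == N_LANDMARKS:
            jaw = pts[0:17]
            if np.ptp(jaw[:, 0]) <= 0:
                failures.append("degenerate geometry: jaw width is zero")
    return ValidationReport(not failures, failures)


def load_landmarks(path: str | Path) -> LandmarkSet:
    """Read a JSON or pts-dialect sidecar."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".pts" or text.lstrip().startswith("version"):
        return _parse_pts(text, path)
    data = json.loads(text)
    if "points" not in data:
        raise ValueError(f"{path}: landmark JSON must contain a 'points' array")
    return LandmarkSet(np.asarray(data["points"], dtype=float))


def save_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    payload = {"points": [[float(x), float(y)] for x, y in landmarks.points]}
    Path(path).write_text(json.dumps(payload))


def _parse_pts(text: str, path: Path) -> LandmarkSet:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    try:
        start = lines.index("{") + 1
        end = lines.index("}")
    except ValueError:
        raise ValueError(f"{path}: malformed pts file (missing braces)") from None
    pts = [tuple(float(v) for v in ln.split()[:2]) for ln in lines[start:end]]
    return LandmarkSet(np.asarray(pts, dtype=float))
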