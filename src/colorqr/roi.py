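"""Assay-hardware ROI detection and color measurement in the canonical frame.

Two detectors share a common box+score contract:

* the BTB strip's ink pad is found by multi-scale normalized cross-correlation
  against a structural template of the pad (a pluggable stand-in for an
  appearance-trained cascade detector);
* the DPD cuvette's dark-bordered face is found by contour detection plus
  aspect-ratio and area gating, after which a centered inner ROI 25x smaller
  (5x per axis) is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template
from skimage.measure import approximate_polygon, find_contours
from skimage.transform import rescale

__all__ = [
    "ROIBox",
    "ROIMeasurement",
    "DetectionBelowThresholdError",
    "NoCuvetteCandidateError",
    "detect_strip_pad",
    "detect_cuvette",
    "shrink_to_inner_roi",
    "measure_roi",
    "DEFAULT_SCALES",
    "DEFAULT_NCC_THRESHOLD",
]

DEFAULT_NCC_THRESHOLD = 0.5
DEFAULT_SCALES = (0.75, 1.0, 1.25, 1.5)
DEFAULT_CUVETTE_ASPECT = 3.0  # visible face 3.3 cm x 1.1 cm
DEFAULT_ASPECT_TOL = 0.25
DEFAULT_INNER_SHRINK = 5.0    # 5x per axis => area ratio 25


class DetectionBelowThresholdError(ValueError):
    def __init__(self, best_score: float, threshold: float):
        self.best_score = best_score
        self.threshold = threshold
        super().__init__(f"best template score {best_score:.3f} below threshold {threshold}")


class NoCuvetteCandidateError(ValueError):
    def __init__(self, rejected: list[str]):
        self.rejected = rejected
        msg = "no contour satisfies the cuvette constraints"
        if rejected:
            msg += "; rejected: " + "; ".join(rejected)
        super().__init__(msg)


@dataclass
class ROIBox:
    x: int
    y: int
    w: int
    h: int
    score: float = 1.0
    kind: str = "strip_pad"

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> int:
        return self.w * self.h

    def iou(self, other: "ROIBox") -> float:
        x0 = max(self.x, other.x)
        y0 = max(self.y, other.y)
        x1 = min(self.x + self.w, other.x + other.w)
        y1 = min(self.y + self.h, other.y + other.h)
        inter = max(0, x1 - x0) * max(0, y1 - y0)
        return inter / (self.area + other.area - inter)


@dataclass
class ROIMeasurement:
    mean_rgb: np.ndarray
    std_rgb: np.ndarray
    pixel_count: int
    box: ROIBox


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        return img @ np.array([0.299, 0.587, 0.114])
    return img


def detect_strip_pad(canonical: np.ndarray, template: np.ndarray,
                     search_window: tuple[int, int, int, int] | None = None,
                     threshold: float = DEFAULT_NCC_THRESHOLD,
                     scales: tuple[float, ...] = DEFAULT_SCALES) -> ROIBox:
    """Best multi-scale normalized-cross-correlation match of the pad template.

    ``search_window`` is (x, y, w, h) in canonical coordinates (the region to
    the right of the QR code); the whole frame is searched when omitted.
    The returned score is the correlation coefficient clipped to [0, 1]; a
    below-threshold best match raises, carrying the best score found.
    """
    gray = _to_gray(canonical)
    if search_window is None:
        wx, wy = 0, 0
        window = gray
    else:
        wx, wy, ww, wh = search_window
        if wx < 0 or wy < 0 or wx + ww > gray.shape[1] or wy + wh > gray.shape[0]:
            raise ValueError(f"search window {search_window} outside image {gray.shape}")
        window = gray[wy:wy + wh, wx:wx + ww]
    tgray = _to_gray(template)
    best = None
    for s in scales:
        templ = rescale(tgray, s, order=1, anti_aliasing=s < 1.0, preserve_range=True)
        th, tw = templ.shape
        if th > window.shape[0] or tw > window.shape[1] or th < 2 or tw < 2:
            continue
        if templ.std() == 0 or window.std() == 0:
            continue
        corr = match_template(window, templ)
        idx = np.unravel_index(np.argmax(corr), corr.shape)
        score = float(corr[idx])
        if best is None or score > best[0]:
            best = (score, idx, tw, th)
    if best is None:
        raise DetectionBelowThresholdError(0.0, threshold)
    score, (iy, ix), tw, th = best
    if score < threshold:
        raise DetectionBelowThresholdError(score, threshold)
    return ROIBox(x=wx + int(ix), y=wy + int(iy), w=tw, h=th,
                  score=float(np.clip(score, 0.0, 1.0)), kind="strip_pad")


def _corner_count(vertices: np.ndarray, straight_cos: float = 0.95) -> int:
    """Count true polygon corners, merging near-collinear vertices.

    Douglas-Peucker keeps the (arbitrary) contour start point even when it
    lies mid-edge, so raw vertex counts over-report; a vertex whose incident
    edges are nearly parallel is not a corner.
    """
    n = len(vertices)
    if n < 3:
        return n
    corners = 0
    for i in range(n):
        a = vertices[i] - vertices[(i - 1) % n]
        b = vertices[(i + 1) % n] - vertices[i]
        cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12)
        if cosang < straight_cos:
            corners += 1
    return corners


def detect_cuvette(canonical: np.ndarray,
                   expected_aspect: float = DEFAULT_CUVETTE_ASPECT,
                   aspect_tol: float = DEFAULT_ASPECT_TOL,
                   area_range: tuple[float, float] = (2000.0, 200000.0),
                   search_window: tuple[int, int, int, int] | None = None,
                   dark_threshold: float = 80.0) -> ROIBox:
    """Locate the cuvette's dark-bordered face by contour detection.

    The black-painted border makes the face the largest 4-vertex contour of
    the dark mask whose bounding-box aspect ratio is within ``aspect_tol``
    (relative) of ``expected_aspect`` and whose area is in ``area_range``.
    The fixed dark threshold keeps detection invariant to moderate global
    illumination gain (border stays near black, background stays bright).
    """
    gray = _to_gray(canonical)
    ox = oy = 0
    if search_window is not None:
        ox, oy, ww, wh = search_window
        gray = gray[oy:oy + wh, ox:ox + ww]
    mask = (gray < dark_threshold).astype(float)
    rejected: list[str] = []
    best: ROIBox | None = None
    for contour in find_contours(mask, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        perim = np.linalg.norm(np.diff(contour, axis=0), axis=1).sum()
        approx = approximate_polygon(contour, tolerance=0.02 * max(perim, 1.0))
        nvert = _corner_count(approx[:-1] if closed else approx)
        if nvert != 4:
            rejected.append(f"contour with {nvert} vertices")
            continue
        y0, x0 = contour.min(axis=0)
        y1, x1 = contour.max(axis=0)
        w, h = x1 - x0, y1 - y0
        if w < 4 or h < 4:
            rejected.append("contour too small")
            continue
        aspect = w / h
        if abs(aspect - expected_aspect) > aspect_tol * expected_aspect:
            rejected.append(f"aspect {aspect:.2f} outside "
                            f"{expected_aspect}+/-{aspect_tol * 100:.0f}%")
            continue
        area = w * h
        if not area_range[0] <= area <= area_range[1]:
            rejected.append(f"area {area:.0f} outside {area_range}")
            continue
        box = ROIBox(x=ox + int(round(x0)), y=oy + int(round(y0)),
                     w=int(round(w)), h=int(round(h)), score=1.0, kind="cuvette_outer")
        if best is None or box.area > best.area:
            best = box
    if best is None:
        raise NoCuvetteCandidateError(rejected)
    return best


def shrink_to_inner_roi(outer: ROIBox, shrink: float = DEFAULT_INNER_SHRINK) -> ROIBox:
    """Centered inner box with each side divided by ``shrink`` (area / shrink^2)."""
    if shrink <= 1:
        raise ValueError("shrink must be > 1")
    w = max(1, int(round(outer.w / shrink)))
    h = max(1, int(round(outer.h / shrink)))
    x = outer.x + int(round((outer.w - w) / 2))
    y = outer.y + int(round((outer.h - h) / 2))
    return ROIBox(x=x, y=y, w=w, h=h, score=outer.score, kind="cuvette_inner")


def measure_roi(canonical: np.ndarray, box: ROIBox) -> ROIMeasurement:
    """Per-channel mean and standard deviation over the box pixels."""
    img = np.asarray(canonical)
    if box.x < 0 or box.y < 0 or box.x + box.w > img.shape[1] or box.y + box.h > img.shape[0]:
        raise ValueError(f"box {box} outside image of shape {img.shape}")
    patch = img[box.y:box.y + box.h, box.x:box.x + box.w].astype(float)
    if patch.ndim == 2:
        patch = patch[..., None].repeat(3, axis=-1)
    return ROIMeasurement(
        mean_rgb=patch.mean(axis=(0, 1)),
        std_rgb=patch.std(axis=(0, 1)),
        pixel_count=box.w * box.h,
        box=box,
    )
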