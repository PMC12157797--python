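"""Scene analysis: locate and decode the Color QR code, rectify, sample patches.

Detection is engine-agnostic in its data model: anything able to produce the
symbol quad and payload can stand behind :class:`QRDetection`.  The built-in
engine binarizes the scene (Otsu), scans for the three finder patterns by
their 1:1:3:1:1 run signature, refines the bottom-right alignment pattern,
estimates the projective map between image and module coordinates, samples
the module grid and decodes it with the package's QR codec.

The canonical frame is defined by a layout: the symbol occupies a fixed
square and the assay hardware search window sits at a fixed region to its
right, so downstream ROI detectors work in stable coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from skimage.feature import match_template
from skimage.filters import threshold_otsu
from skimage.transform import AffineTransform, ProjectiveTransform, warp

from . import qrcodec
from .codegen import ColorQRSpec

__all__ = [
    "Layout",
    "QRDetection",
    "PatchMeasurement",
    "QRNotFoundError",
    "DegenerateHomographyError",
    "default_layout",
    "load_layout",
    "locate_and_decode",
    "rectify_to_canonical",
    "sample_palette_patches",
]


class QRNotFoundError(ValueError):
    """No decodable QR symbol in the scene."""


class DegenerateHomographyError(ValueError):
    """The detected quad yields a (near-)singular projective map."""


@dataclass(frozen=True)
class Layout:
    """Canonical-frame geometry: canvas size, QR square, hardware window."""

    canvas_w: int
    canvas_h: int
    qr_x: int
    qr_y: int
    module_px: int
    modules: int
    window: tuple[int, int, int, int]   # x, y, w, h

    @property
    def qr_size_px(self) -> int:
        return self.modules * self.module_px

    @classmethod
    def from_dict(cls, d: dict) -> "Layout":
        return cls(canvas_w=d["canvas_w"], canvas_h=d["canvas_h"],
                   qr_x=d["qr"]["x"], qr_y=d["qr"]["y"],
                   module_px=d["qr"]["module_px"], modules=d["qr"]["modules"],
                   window=(d["window"]["x"], d["window"]["y"],
                           d["window"]["w"], d["window"]["h"]))


def load_layout(path) -> Layout:
    return Layout.from_dict(json.loads(Path(path).read_text()))


def default_layout() -> Layout:
    with resources.files("colorqr.data").joinpath("layout_default.json").open() as fh:
        return Layout.from_dict(json.load(fh))


@dataclass
class QRDetection:
    """Symbol localization result.

    ``corners`` are the four outer symbol corners (TL, TR, BR, BL) in image
    pixels; ``homography`` maps image pixels to module coordinates (x = col,
    y = row, in module units), so the symbol corners land on (0,0)...(side,
    side).
    """

    corners: np.ndarray
    payload: str
    qr_id: str
    homography: np.ndarray
    side: int
    meta: dict = field(default_factory=dict)


@dataclass
class PatchMeasurement:
    """Captured vs reference color of one embedded palette patch."""

    entry_id: str
    captured_rgb: np.ndarray
    reference_rgb: tuple[int, int, int]
    pixel_count: int


def _estimate_transform(cls, src: np.ndarray, dst: np.ndarray):
    """Estimate a skimage transform; returns None on degenerate input."""
    if hasattr(cls, "from_estimate"):
        tform = cls.from_estimate(src, dst)
        return tform if tform else None
    tform = cls()
    return tform if tform.estimate(src, dst) else None


def _gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        return img @ np.array([0.299, 0.587, 0.114])
    return img


def _rle(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a 1-D boolean array: (start indices, lengths)."""
    n = len(values)
    edges = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], edges])
    lengths = np.diff(np.concatenate([starts, [n]]))
    return starts, lengths


def _ratio_ok(widths, tol: float = 0.55) -> float | None:
    """Return the module size if five runs match 1:1:3:1:1, else None."""
    total = sum(widths)
    if total < 7:
        return None
    m = total / 7.0
    expect = (1, 1, 3, 1, 1)
    for wdt, e in zip(widths, expect):
        if abs(wdt - e * m) > tol * m * (1.5 if e == 3 else 1.0):
            return None
    return m


def _finder_candidates(dark: np.ndarray) -> list[tuple[float, float, float]]:
    h, w = dark.shape
    out = []
    for r in range(h):
        starts, lengths = _rle(dark[r])
        vals = dark[r][starts]
        for i in range(len(starts) - 4):
            if not vals[i]:
                continue
            m = _ratio_ok(lengths[i:i + 5])
            if m is None:
                continue
            cx = starts[i + 2] + lengths[i + 2] / 2.0
            # vertical cross-check through the horizontal center
            col = dark[:, min(int(cx), w - 1)]
            cs, cl = _rle(col)
            j = np.searchsorted(cs, r, side="right") - 1
            if not col[cs[j]] or j < 2 or j > len(cs) - 3:
                continue
            mv = _ratio_ok(cl[j - 2:j + 3])
            if mv is None or not 0.4 < mv / m < 2.5:
                continue
            cy = cs[j] + cl[j] / 2.0
            out.append((cx, cy, (m + mv) / 2.0))
    return out


def _cluster(cands: list[tuple[float, float, float]]) -> list[tuple[float, float, float, int]]:
    clusters: list[list] = []   # [sx, sy, sm, count]
    for cx, cy, m in cands:
        for cl in clusters:
            if abs(cx - cl[0] / cl[3]) < 3.5 * m and abs(cy - cl[1] / cl[3]) < 3.5 * m:
                cl[0] += cx
                cl[1] += cy
                cl[2] += m
                cl[3] += 1
                break
        else:
            clusters.append([cx, cy, m, 1])
    return [(c[0] / c[3], c[1] / c[3], c[2] / c[3], c[3]) for c in clusters]


def _order_finders(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Identify (TL, TR, BL) among three finder centers.

    TL is the vertex whose angle is closest to 90 degrees; TR/BL are fixed so
    the x-cross of (TL->TR, TL->BL) is positive in image coordinates.
    """
    best, tl_i = None, 0
    for i in range(3):
        v1 = centers[(i + 1) % 3] - centers[i]
        v2 = centers[(i + 2) % 3] - centers[i]
        cosang = abs(np.dot(v1, v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        if best is None or cosang < best:
            best, tl_i = cosang, i
    tl = centers[tl_i]
    a, b = centers[(tl_i + 1) % 3], centers[(tl_i + 2) % 3]
    u, v = a - tl, b - tl
    if u[0] * v[1] - u[1] * v[0] < 0:
        a, b = b, a
    return tl, a, b  # TL, TR, BL


def _refine_alignment(dark: np.ndarray, predicted: np.ndarray, m: float) -> np.ndarray | None:
    """Refine the bottom-right alignment pattern center near its prediction."""
    half = int(round(3.5 * m))
    x0 = int(round(predicted[0])) - half
    y0 = int(round(predicted[1])) - half
    x1, y1 = x0 + 2 * half, y0 + 2 * half
    if x0 < 0 or y0 < 0 or x1 > dark.shape[1] or y1 > dark.shape[0]:
        return None
    window = dark[y0:y1, x0:x1].astype(float)
    tpx = max(2, int(round(m)))
    cell = np.ones((5, 5))
    cell[1:4, 1:4] = 0.0
    cell[2, 2] = 1.0
    templ = np.repeat(np.repeat(cell, tpx, axis=0), tpx, axis=1)
    if templ.shape[0] > window.shape[0] or templ.shape[1] > window.shape[1]:
        return None
    corr = match_template(window, templ)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    if corr[iy, ix] < 0.4:
        return None
    return np.array([x0 + ix + templ.shape[1] / 2.0, y0 + iy + templ.shape[0] / 2.0])


def locate_and_decode(scene: np.ndarray) -> QRDetection:
    """Find and decode the QR symbol in a photograph.

    Raises :class:`QRNotFoundError` when no decodable symbol is present.
    """
    gray = _gray(scene)
    if gray.shape[0] < 64 or gray.shape[1] < 64:
        raise QRNotFoundError(f"image too small: {gray.shape}")
    if gray.max() == gray.min():
        raise QRNotFoundError("blank image")
    dark = gray < threshold_otsu(gray)

    clusters = _cluster(_finder_candidates(dark))
    clusters = [c for c in clusters if c[3] >= 2]
    if len(clusters) < 3:
        raise QRNotFoundError(f"found only {len(clusters)} finder pattern(s)")
    clusters.sort(key=lambda c: -c[3])
    centers = np.array([[c[0], c[1]] for c in clusters[:3]])
    msize = float(np.mean([c[2] for c in clusters[:3]]))

    tl, tr, bl = _order_finders(centers)
    dist = (np.linalg.norm(tr - tl) + np.linalg.norm(bl - tl)) / 2.0
    version = int(np.clip(round((dist / msize + 7 - 17) / 4.0), 1, 10))

    last_err: Exception | None = None
    for v in dict.fromkeys([version, version - 1, version + 1]):
        if not 1 <= v <= 10:
            continue
        side = qrcodec.matrix_side(v)
        src_mod = np.array([[3.5, 3.5], [side - 3.5, 3.5], [3.5, side - 3.5]])
        dst_img = np.array([tl, tr, bl])
        aff = _estimate_transform(AffineTransform, src_mod, dst_img)
        if aff is None:
            last_err = DegenerateHomographyError("collinear finder centers")
            continue
        tform = aff
        if v >= 2:
            pred = aff(np.array([[side - 6.5, side - 6.5]]))[0]
            align = _refine_alignment(dark, pred, msize)
            if align is not None:
                proj = _estimate_transform(
                    ProjectiveTransform,
                    np.vstack([src_mod, [[side - 6.5, side - 6.5]]]),
                    np.vstack([dst_img, align]))
                if proj is not None:
                    tform = proj
        if abs(np.linalg.det(tform.params)) < 1e-12:
            last_err = DegenerateHomographyError("singular symbol transform")
            continue
        inv = np.linalg.inv(tform.params)

        cols, rows = np.meshgrid(np.arange(side) + 0.5, np.arange(side) + 0.5)
        pts = np.column_stack([cols.ravel(), rows.ravel(), np.ones(side * side)])
        img_pts = pts @ tform.params.T
        img_pts = img_pts[:, :2] / img_pts[:, 2:3]
        xi = np.clip(np.round(img_pts[:, 0]).astype(int), 0, dark.shape[1] - 1)
        yi = np.clip(np.round(img_pts[:, 1]).astype(int), 0, dark.shape[0] - 1)
        matrix = dark[yi, xi].reshape(side, side)
        try:
            payload = qrcodec.decode_matrix(matrix)
        except qrcodec.QRDecodeError as exc:
            last_err = exc
            continue
        corner_mod = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float)
        corners = tform(corner_mod)
        return QRDetection(
            corners=corners,
            payload=payload,
            qr_id=payload.split("#", 1)[1] if "#" in payload else "",
            homography=inv,                    # image -> module coordinates
            side=side,
            meta={"module_size_px": msize},
        )
    raise QRNotFoundError(f"finder patterns found but symbol not decodable: {last_err}")


def rectify_to_canonical(scene: np.ndarray, det: QRDetection, layout: Layout) -> np.ndarray:
    """Warp the scene so the QR symbol occupies the layout's fixed square.

    Resampling is bilinear; regions outside the source image are white.
    """
    # module units -> canonical canvas pixels
    s = np.array([[layout.module_px, 0, layout.qr_x],
                  [0, layout.module_px, layout.qr_y],
                  [0, 0, 1.0]], dtype=float)
    h_img2mod = det.homography
    if abs(np.linalg.det(h_img2mod)) < 1e-12:
        raise DegenerateHomographyError("near-singular detection homography")
    # canvas -> image map for inverse warping
    m = np.linalg.inv(h_img2mod) @ np.linalg.inv(s)
    tform = ProjectiveTransform(matrix=m)
    img = np.asarray(scene, dtype=float) / 255.0
    out = warp(img, tform, output_shape=(layout.canvas_h, layout.canvas_w),
               order=1, cval=1.0, preserve_range=True)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def sample_palette_patches(canonical: np.ndarray, spec: ColorQRSpec,
                           layout: Layout,
                           central_fraction: float = 0.5) -> list[PatchMeasurement]:
    """Mean captured color of each palette patch in the canonical frame.

    Each patch is averaged over the central ``central_fraction`` of its
    module square, avoiding warp/demosaicing bleed at module borders.
    """
    mpx = layout.module_px
    size = max(1, int(mpx * central_fraction))
    off = (mpx - size) // 2
    img = np.asarray(canonical, dtype=float)
    out = []
    placements = spec.resolved_placements()
    for entry, (r, c) in zip(spec.palette, placements):
        x0 = layout.qr_x + c * mpx + off
        y0 = layout.qr_y + r * mpx + off
        patch = img[y0:y0 + size, x0:x0 + size]
        if patch.size == 0:
            raise ValueError(f"patch {entry.id!r} at ({r},{c}) outside the canonical frame")
        out.append(PatchMeasurement(
            entry_id=entry.id,
            captured_rgb=patch.reshape(-1, patch.shape[-1]).mean(axis=0),
            reference_rgb=entry.reference_rgb,
            pixel_count=size * size,
        ))
    return out
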