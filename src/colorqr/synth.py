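"""Synthetic scene and feature generation with complete ground truth.

No image dataset accompanies the assays, so every pipeline stage is
exercised on rendered scenes that emulate the acquisition protocol: a Color
QR chart next to the reacted hardware, lit by a Planckian-locus illuminant
between 2500 and 6500 K, photographed with hand-held perspective jitter and
sensor noise.

Dye response models
-------------------
BTB strip (blue ramp): the red channel decays exponentially with
concentration, R = exp((b - C)/|m|), which is the exact inverse of the
calibration line C = m ln(R) + b with m = -0.64 ppm per ln-unit and
b = 3.3 ppm; green and blue decrease linearly.  DPD cuvette (pink ramp):
ln G and ln B decrease linearly in C while R stays high, so the zero-analyte
color is near neutral and the reacted color sits in the pink sector.  The
channel coefficients besides (m, b) are package constants chosen to
reproduce the qualitative response trends; they are synthetic conveniences,
not measured chemistry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import ProjectiveTransform, warp

from .codegen import ColorQRSpec, default_palette, embed_palette, encode_payload, render_symbol
from .colorimetry import DEFAULT_BOUNDS, FeatureVector
from .roi import ROIBox
from .vision import Layout, default_layout

__all__ = [
    "BTBParams",
    "DPDParams",
    "SyntheticScene",
    "CCT_GRID",
    "btb_response",
    "dpd_response",
    "illuminant_gains",
    "render_scene",
    "generate_dataset",
    "generate_feature_table",
    "strip_pad_template",
    "default_spec",
]

#: illumination grid of the fixed acquisition setup, in kelvin
CCT_GRID = tuple(range(2500, 7000, 500))

REFERENCE_CCT = 6500.0
DEFAULT_PAYLOAD = "http://diesmar.com/#n87RXv6i3"


@dataclass(frozen=True)
class BTBParams:
    """BTB strip response: exponential red decay, linear green/blue decay.

    ``m`` (ppm per ln-intensity) and ``b`` (ppm) define R = exp((b - C)/|m|),
    the inverse of the ln(R) calibration line; sigma is 8-bit channel noise.
    """

    m: float = -0.64
    b: float = 3.3
    G0: float = 200.0
    gG: float = 25.0
    B0: float = 150.0
    gB: float = 10.0
    noise_sigma: float = 2.0
    valid_range: tuple[float, float] = (0.0, 8.4)


@dataclass(frozen=True)
class DPDParams:
    """DPD cuvette response: log-linear green/blue decay, red held high."""

    G0: float = 230.0
    gG: float = 0.25
    B0: float = 235.0
    gB: float = 0.35
    R_level: float = 230.0
    noise_sigma: float = 2.0
    valid_range: tuple[float, float] = (0.0, 8.4)


def _noisy_clip(rgb: np.ndarray, sigma: float, rng) -> np.ndarray:
    if sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires a seeded rng")
        rgb = rgb + rng.normal(0.0, sigma, size=3)
    return np.clip(rgb, 0.0, 255.0)


def btb_response(concentration: float, params: BTBParams | None = None,
                 rng=None, noise_sigma: float | None = None) -> np.ndarray:
    """Noisy RGB of the BTB pad at a free-chlorine concentration (ppm)."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    p = params or BTBParams()
    sigma = p.noise_sigma if noise_sigma is None else noise_sigma
    rgb = np.array([
        np.exp((p.b - concentration) / abs(p.m)),
        p.G0 - p.gG * concentration,
        p.B0 - p.gB * concentration,
    ])
    return _noisy_clip(rgb, sigma, rng)


def dpd_response(concentration: float, params: DPDParams | None = None,
                 rng=None, noise_sigma: float | None = None) -> np.ndarray:
    """Noisy RGB of the DPD cuvette liquid at a concentration (ppm)."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    p = params or DPDParams()
    sigma = p.noise_sigma if noise_sigma is None else noise_sigma
    rgb = np.array([
        p.R_level,
        p.G0 * np.exp(-p.gG * concentration),
        p.B0 * np.exp(-p.gB * concentration),
    ])
    return _noisy_clip(rgb, sigma, rng)


def _planck_rgb(cct: float) -> np.ndarray:
    """Blackbody RGB via the Tanner Helland piecewise log/power fit."""
    t = cct / 100.0
    if t <= 66:
        r = 255.0
        g = 99.4708025861 * np.log(t) - 161.1195681661
    else:
        r = 329.698727446 * (t - 60) ** -0.1332047592
        g = 288.1221695283 * (t - 60) ** -0.0755148492
    if t >= 66:
        b = 255.0
    elif t <= 19:
        b = 0.0
    else:
        b = 138.5177312231 * np.log(t - 10) - 305.0447927307
    return np.clip([r, g, b], 1e-6, 255.0)


def illuminant_gains(cct: float) -> np.ndarray:
    """Von Kries RGB gains of a Planckian illuminant relative to 6500 K.

    Gains are normalized per channel by the 6500 K reference illuminant (the
    chart's reference condition), so ``illuminant_gains(6500) == (1, 1, 1)``
    exactly; warm illuminants give red gain > 1 > blue gain.
    """
    if not 1000 <= cct <= 12000:
        raise ValueError(f"CCT must be in [1000, 12000] K, got {cct}")
    return _planck_rgb(cct) / _planck_rgb(REFERENCE_CCT)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

# strip geometry in canonical pixels
STRIP_W, STRIP_H = 80, 260
STRIP_BG = 230
PAD_OUTER = 62
PAD_BORDER = 3
FRAME_DARK = 20
CUVETTE_W, CUVETTE_H = 240, 80
CUVETTE_BORDER = 6
CUVETTE_DARK = 15


def strip_pad_template() -> np.ndarray:
    """Structural grayscale template of the strip's ink-pad frame.

    Dark frame around a mid-gray interior; the interior value is a neutral
    stand-in since the actual pad color varies with concentration and
    normalized cross-correlation is invariant to affine intensity shifts.
    """
    t = np.full((PAD_OUTER, PAD_OUTER), float(FRAME_DARK))
    t[PAD_BORDER:-PAD_BORDER, PAD_BORDER:-PAD_BORDER] = 140.0
    return t


def default_spec(chemistry: str = "BTB", payload: str = DEFAULT_PAYLOAD,
                 layout: Layout | None = None) -> ColorQRSpec:
    """Ready-to-render Color QR spec with the default palette and placements."""
    layout = layout or default_layout()
    spec = ColorQRSpec(payload=payload, version=3, ec_level="Q",
                       palette=default_palette(chemistry),
                       module_px=layout.module_px)
    spec.placements = spec.resolved_placements()
    return spec


@dataclass
class SyntheticScene:
    """Rendered scene plus complete ground truth."""

    image: np.ndarray           # warped, noisy capture (H, W, 3) uint8
    canvas: np.ndarray          # pre-warp, noise-free canonical canvas, uint8
    truth: dict = field(default_factory=dict)


def _draw_strip(canvas: np.ndarray, x0: int, y0: int, pad_rgb: np.ndarray) -> ROIBox:
    canvas[y0:y0 + STRIP_H, x0:x0 + STRIP_W] = STRIP_BG
    px = x0 + (STRIP_W - PAD_OUTER) // 2
    py = y0 + (STRIP_H - PAD_OUTER) // 2
    canvas[py:py + PAD_OUTER, px:px + PAD_OUTER] = FRAME_DARK
    b = PAD_BORDER
    canvas[py + b:py + PAD_OUTER - b, px + b:px + PAD_OUTER - b] = pad_rgb
    return ROIBox(x=px, y=py, w=PAD_OUTER, h=PAD_OUTER, kind="strip_pad")


def _draw_cuvette(canvas: np.ndarray, x0: int, y0: int, liquid_rgb: np.ndarray) -> ROIBox:
    canvas[y0:y0 + CUVETTE_H, x0:x0 + CUVETTE_W] = CUVETTE_DARK
    b = CUVETTE_BORDER
    canvas[y0 + b:y0 + CUVETTE_H - b, x0 + b:x0 + CUVETTE_W - b] = liquid_rgb
    return ROIBox(x=x0, y=y0, w=CUVETTE_W, h=CUVETTE_H, kind="cuvette_outer")


def render_scene(spec: ColorQRSpec | None = None, chemistry: str = "BTB",
                 concentration: float = 0.5, layout: Layout | None = None,
                 cct: float = 6500.0, warp_jitter: float = 0.0,
                 noise_sigma: float = 0.0, seed: int = 0,
                 gamma: bool = False,
                 params: BTBParams | DPDParams | None = None) -> SyntheticScene:
    """Render one labelled scene: Color QR plus reacted assay hardware.

    The pipeline is: draw the canonical canvas (white background, symbol at
    the layout square, hardware in the search window with positional
    jitter), apply per-pixel illuminant gains, optionally a gamma-2.2
    non-linearity, a projective warp with corner jitter bounded by
    ``warp_jitter`` times the canvas size, and additive Gaussian noise.
    Identical seeds produce byte-identical images.
    """
    chemistry = chemistry.upper()
    layout = layout or default_layout()
    if spec is None:
        spec = default_spec(chemistry, layout=layout)
    rng = np.random.default_rng(seed)

    # assay color at the reference illuminant (noise enters at the pixel level)
    if chemistry == "BTB":
        assay_rgb = btb_response(concentration, params, noise_sigma=0.0)
    elif chemistry == "DPD":
        assay_rgb = dpd_response(concentration, params, noise_sigma=0.0)
    else:
        raise ValueError(f"unknown chemistry {chemistry!r}")

    canvas = np.full((layout.canvas_h, layout.canvas_w, 3), 255.0)

    matrix = encode_payload(spec.payload, spec.version, spec.ec_level)
    placements = spec.resolved_placements(matrix)
    colored = embed_palette(matrix, spec.palette, placements)
    symbol = render_symbol(colored, module_px=layout.module_px, quiet_zone=spec.quiet_zone)
    qpx = layout.qr_x - spec.quiet_zone * layout.module_px
    qpy = layout.qr_y - spec.quiet_zone * layout.module_px
    if qpx < 0 or qpy < 0 or qpy + symbol.shape[0] > layout.canvas_h \
            or qpx + symbol.shape[1] > layout.canvas_w:
        raise ValueError("layout: QR symbol (with quiet zone) exceeds the canvas")
    canvas[qpy:qpy + symbol.shape[0], qpx:qpx + symbol.shape[1]] = symbol

    wx, wy, ww, wh = layout.window
    if not (wx >= qpx + symbol.shape[1] or wx + ww <= qpx):
        raise ValueError("layout overlap: hardware window collides with the QR symbol")
    if chemistry == "BTB":
        free_x, free_y = ww - STRIP_W, wh - STRIP_H
        x0 = wx + free_x // 2 + int(rng.integers(-min(20, free_x // 2), min(20, free_x // 2) + 1))
        y0 = wy + free_y // 2 + int(rng.integers(-min(20, free_y // 2), min(20, free_y // 2) + 1))
        hw_box = _draw_strip(canvas, x0, y0, assay_rgb)
    else:
        free_x, free_y = ww - CUVETTE_W, wh - CUVETTE_H
        x0 = wx + free_x // 2 + int(rng.integers(-min(20, free_x // 2), min(20, free_x // 2) + 1))
        y0 = wy + free_y // 2 + int(rng.integers(-min(20, free_y // 2), min(20, free_y // 2) + 1))
        hw_box = _draw_cuvette(canvas, x0, y0, assay_rgb)

    gains = illuminant_gains(cct)
    canvas = canvas * gains
    if gamma:
        canvas = 255.0 * (np.clip(canvas, 0, 255) / 255.0) ** (1.0 / 2.2)
    canvas = np.clip(canvas, 0.0, 255.0)
    canvas_u8 = np.round(canvas).astype(np.uint8)

    h, w = layout.canvas_h, layout.canvas_w
    src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
    jitter = rng.uniform(-warp_jitter, warp_jitter, size=(4, 2)) * np.array([w, h])
    dst = src + jitter
    from .vision import _estimate_transform
    tform = _estimate_transform(ProjectiveTransform, src, dst)
    if tform is None:
        raise ValueError("degenerate warp corners")
    if warp_jitter == 0:
        image = canvas.copy()
    else:
        image = warp(canvas / 255.0, ProjectiveTransform(matrix=np.linalg.inv(tform.params)),
                     output_shape=(h, w), order=1, cval=1.0, preserve_range=True) * 255.0
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    image_u8 = np.clip(np.round(image), 0, 255).astype(np.uint8)

    bounds = DEFAULT_BOUNDS[chemistry]
    corners_canvas = np.array([
        [layout.qr_x, layout.qr_y],
        [layout.qr_x + layout.qr_size_px, layout.qr_y],
        [layout.qr_x + layout.qr_size_px, layout.qr_y + layout.qr_size_px],
        [layout.qr_x, layout.qr_y + layout.qr_size_px],
    ], dtype=float)
    truth = {
        "chemistry": chemistry,
        "concentration": float(concentration),
        "class_label": bounds.classify(concentration),
        "assay_rgb": assay_rgb,
        "homography": tform.params,            # canvas -> image
        "corners_image": tform(corners_canvas),
        ("pad_box" if chemistry == "BTB" else "cuvette_box"): hw_box,
        "illuminant_cct": float(cct),
        "gains": gains,
        "gamma": bool(gamma),
        "warp_jitter": float(warp_jitter),
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
        "payload": spec.payload,
    }
    return SyntheticScene(image=image_u8, canvas=canvas_u8, truth=truth)


def _sample_concentrations(n: int, chemistry: str, sampler: str, rng,
                           conc_range: tuple[float, float]) -> np.ndarray:
    bounds = DEFAULT_BOUNDS[chemistry.upper()]
    if sampler == "uniform":
        return rng.uniform(conc_range[0], conc_range[1], size=n)
    if sampler == "stratified":
        intervals = [(max(0.02, conc_range[0]), bounds.low_max),
                     (bounds.low_max, bounds.high_min),
                     (bounds.high_min, min(3.0, conc_range[1]))]
        lo, hi = np.array(intervals).T[:, np.arange(n) % 3]
        return rng.uniform(lo, hi)
    if sampler == "medium":
        return rng.uniform(bounds.low_max, bounds.high_min, size=n)
    raise ValueError(f"unknown sampler {sampler!r}")


def generate_dataset(n: int, chemistry: str = "BTB", out_dir=None,
                     sampler: str = "stratified",
                     conc_range: tuple[float, float] = (0.0, 8.4),
                     cct_grid: tuple[float, ...] = CCT_GRID,
                     warp_jitter: float = 0.03, noise_sigma: float = 2.0,
                     seed: int = 0, gamma: bool = False,
                     spec: ColorQRSpec | None = None,
                     layout: Layout | None = None,
                     write_images: bool = True):
    """Render ``n`` labelled scenes sweeping the illuminant grid.

    Returns ``(scenes, truth_table)``; when ``out_dir`` is given the scenes
    are written as PNG with a truth CSV (training-table schema) and a
    sidecar JSON holding the generation parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    chemistry = chemistry.upper()
    layout = layout or default_layout()
    if spec is None:
        spec = default_spec(chemistry, layout=layout)
    rng = np.random.default_rng(seed)
    concs = _sample_concentrations(n, chemistry, sampler, rng, conc_range)

    scenes, rows = [], []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i in range(n):
        cct = cct_grid[i % len(cct_grid)]
        scene = render_scene(spec=spec, chemistry=chemistry, concentration=float(concs[i]),
                             layout=layout, cct=cct, warp_jitter=warp_jitter,
                             noise_sigma=noise_sigma, seed=seed + i + 1, gamma=gamma)
        name = f"scene_{i:04d}.png"
        if out_path is not None and write_images:
            try:
                Image.fromarray(scene.image).save(out_path / name)
            except OSError as exc:
                raise OSError(f"failed writing {out_path / name}: {exc}") from exc
        scenes.append(scene)
        rows.append({
            "image_path": name,
            "chemistry": chemistry,
            "concentration_ppm": float(concs[i]),
            "class_label": scene.truth["class_label"],
            "illuminant_K": float(cct),
            "flash": "no",
            "device": "synthetic",
            "seed": seed + i + 1,
        })
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path / "truth.csv", index=False)
        meta = {
            "n": n, "chemistry": chemistry, "sampler": sampler,
            "conc_range": list(conc_range), "cct_grid": list(cct_grid),
            "warp_jitter": warp_jitter, "noise_sigma": noise_sigma,
            "seed": seed, "gamma": gamma, "payload": spec.payload,
        }
        (out_path / "dataset.json").write_text(json.dumps(meta, indent=1))
    return scenes, table


def generate_feature_table(n: int, chemistry: str = "BTB",
                           concentrations=None, sampler: str = "stratified",
                           conc_range: tuple[float, float] = (0.0, 8.4),
                           noise_sigma: float = 2.0, seed: int = 0,
                           params: BTBParams | DPDParams | None = None) -> pd.DataFrame:
    """Feature rows straight from the response model, bypassing rendering.

    Emulates a perfectly corrected capture: the dye response plus channel
    noise, converted to the six model features.  Used for calibration and
    classifier studies where the optics are not under test.
    """
    chemistry = chemistry.upper()
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = _sample_concentrations(n, chemistry, sampler, rng, conc_range)
    concentrations = np.asarray(concentrations, dtype=float)
    response = btb_response if chemistry == "BTB" else dpd_response
    bounds = DEFAULT_BOUNDS[chemistry]
    rows = []
    for c in concentrations:
        rgb = response(float(c), params, rng=rng, noise_sigma=noise_sigma)
        fv = FeatureVector.from_rgb(rgb)
        rows.append({**fv.as_dict(), "concentration_ppm": float(c),
                     "class_label": bounds.classify(float(c)), "chemistry": chemistry})
    return pd.DataFrame(rows)


def scene_digest(scene: SyntheticScene) -> str:
    """SHA-256 of the rendered image bytes (determinism checks)."""
    return hashlib.sha256(np.ascontiguousarray(scene.image).tobytes()).hexdigest()
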