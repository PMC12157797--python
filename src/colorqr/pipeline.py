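"""End-to-end scene analysis: detect, rectify, color-correct, measure.

Thin orchestration over the stage modules; each step can also be run
separately for debugging or re-calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codegen import ColorQRSpec
from .colorcorr import ColorCorrectionMap, correction_residual, fit_tps_map
from .colorimetry import (CalibrationModel, FeatureVector, Measurement,
                          extract_features, predict_concentration)
from .roi import (ROIBox, ROIMeasurement, detect_cuvette, detect_strip_pad,
                  measure_roi, shrink_to_inner_roi)
from .vision import (Layout, QRDetection, default_layout, locate_and_decode,
                     rectify_to_canonical, sample_palette_patches)

__all__ = ["SceneAnalysis", "analyze_scene"]

# pad interior margin: keeps the measured region inside the ink window even
# with a few pixels of detection offset
PAD_INNER_SHRINK = 1.6


@dataclass
class SceneAnalysis:
    detection: QRDetection
    canonical: np.ndarray
    patches: list
    correction: ColorCorrectionMap
    residual: float
    roi_box: ROIBox
    roi_inner: ROIBox
    roi_measurement: ROIMeasurement
    features: FeatureVector
    measurement: Measurement | None = None


def analyze_scene(image: np.ndarray, spec: ColorQRSpec, chemistry: str = "BTB",
                  layout: Layout | None = None, template: np.ndarray | None = None,
                  model: CalibrationModel | None = None,
                  lam: float = 0.0) -> SceneAnalysis:
    """Run the full readout pipeline on one photograph.

    Steps: locate and decode the Color QR, rectify to the canonical frame,
    sample the embedded palette, fit the thin-plate-spline correction from
    captured/reference pairs, detect the assay ROI (strip pad or cuvette),
    measure its mean color, correct it and derive features; when a
    calibration model is supplied, also classify and estimate ppm.
    """
    chemistry = chemistry.upper()
    layout = layout or default_layout()
    det = locate_and_decode(image)
    canonical = rectify_to_canonical(image, det, layout)
    patches = sample_palette_patches(canonical, spec, layout)
    cmap = fit_tps_map(patches, lam=lam)
    residual = correction_residual(cmap, patches)

    if chemistry == "BTB":
        if template is None:
            from .synth import strip_pad_template
            template = strip_pad_template()
        box = detect_strip_pad(canonical, template, search_window=layout.window)
        inner = shrink_to_inner_roi(box, PAD_INNER_SHRINK)
        inner.kind = "strip_pad"
    else:
        box = detect_cuvette(canonical, search_window=layout.window)
        inner = shrink_to_inner_roi(box)
    rmeas = measure_roi(canonical, inner)
    features = extract_features(rmeas, cmap)
    measurement = None
    if model is not None:
        measurement = predict_concentration(
            features, model,
            provenance={"qr_id": det.qr_id, "payload": det.payload,
                        "correction_residual": residual})
    return SceneAnalysis(
        detection=det, canonical=canonical, patches=patches, correction=cmap,
        residual=residual, roi_box=box, roi_inner=inner, roi_measurement=rmeas,
        features=features, measurement=measurement,
    )
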