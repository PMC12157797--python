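"""Scene analysis: QR localization, rectification, palette sampling."""

import numpy as np
import pytest

from colorqr.codegen import embed_palette, encode_payload, render_symbol
from colorqr.synth import default_spec, render_scene
from colorqr.vision import (PatchMeasurement, QRNotFoundError, locate_and_decode,
                            rectify_to_canonical, sample_palette_patches)

PAYLOAD = "http://diesmar.com/#n87RXv6i3"


def test_blank_image_raises_not_found():
    with pytest.raises(QRNotFoundError):
        locate_and_decode(np.full((200, 200, 3), 255, dtype=np.uint8))

    with pytest.raises(QRNotFoundError):
        locate_and_decode(np.full((40, 40, 3), 255, dtype=np.uint8))


def test_unwarped_symbol_at_known_offset_decodes_exactly(btb_spec):
    matrix = encode_payload(PAYLOAD, 3, "Q")
    colored = embed_palette(matrix, btb_spec.palette, btb_spec.placements)
    symbol = render_symbol(colored, module_px=8, quiet_zone=4)
    canvas = np.full((500, 600, 3), 255, dtype=np.uint8)
    canvas[70:70 + symbol.shape[0], 90:90 + symbol.shape[1]] = symbol
    det = locate_and_decode(canvas)
    assert det.payload == PAYLOAD
    assert det.qr_id == "n87RXv6i3"
    # symbol corners: offset + quiet zone
    expected_tl = np.array([90 + 32, 70 + 32])
    assert np.abs(det.corners[0] - expected_tl).max() <= 2


def test_detected_corners_match_generator_ground_truth(warped_scene):
    det = locate_and_decode(warped_scene.image)
    assert det.payload == PAYLOAD
    assert np.abs(det.corners - warped_scene.truth["corners_image"]).max() <= 2


def test_detection_homography_maps_corners_to_canonical(warped_scene):
    det = locate_and_decode(warped_scene.image)
    h = det.homography
    pts = np.column_stack([det.corners, np.ones(4)]) @ h.T
    pts = pts[:, :2] / pts[:, 2:3]
    canonical = np.array([[0, 0], [det.side, 0], [det.side, det.side], [0, det.side]])
    assert np.abs(pts - canonical).max() <= 0.5 / 10  # 0.5 px at 10 px/module


def test_decoding_invariant_to_embedded_colors(layout):
    """The colored and black/white renders of the same spec both decode."""
    matrix = encode_payload(PAYLOAD, 3, "Q")
    spec = default_spec("BTB", layout=layout)
    for palette, placements in (([], []), (spec.palette, spec.placements)):
        colored = embed_palette(matrix, palette, placements)
        symbol = render_symbol(colored, module_px=10, quiet_zone=4)
        canvas = np.full((450, 450, 3), 255, dtype=np.uint8)
        canvas[40:40 + symbol.shape[0], 40:40 + symbol.shape[1]] = symbol
        assert locate_and_decode(canvas).payload == PAYLOAD


def test_identity_rectification_reproduces_canvas(identity_scene, layout):
    det = locate_and_decode(identity_scene.image)
    canonical = rectify_to_canonical(identity_scene.image, det, layout)
    # away from module edges the canonical frame equals the unwarped canvas
    diff = np.abs(canonical.astype(float) - identity_scene.canvas.astype(float))
    assert np.mean(diff) <= 1.0


def test_warp_roundtrip_recovers_canvas_away_from_edges(warped_scene, layout):
    from scipy.ndimage import maximum_filter, minimum_filter

    det = locate_and_decode(warped_scene.image)
    canonical = rectify_to_canonical(warped_scene.image, det, layout)
    ref = warped_scene.canvas.astype(float)
    gray = ref @ np.array([0.299, 0.587, 0.114])
    flat = (maximum_filter(gray, size=5) - minimum_filter(gray, size=5)) < 5
    diff = np.abs(canonical.astype(float) - ref)
    assert diff[flat].mean() <= 3.0


def test_rectified_patch_centers_land_on_canonical_coordinates(warped_scene, layout, btb_spec):
    det = locate_and_decode(warped_scene.image)
    canonical = rectify_to_canonical(warped_scene.image, det, layout)
    patches = sample_palette_patches(canonical, btb_spec, layout)
    # compare to the same patches sampled from the noise-free canvas
    truth = sample_palette_patches(warped_scene.canvas, btb_spec, layout)
    for got, want in zip(patches, truth):
        assert np.abs(got.captured_rgb - want.captured_rgb).max() <= 6


def test_noiseless_canonical_sampling_is_exact(identity_scene, layout, btb_spec):
    patches = sample_palette_patches(identity_scene.canvas, btb_spec, layout)
    for p in patches:
        assert isinstance(p, PatchMeasurement)
        assert np.array_equal(p.captured_rgb, np.asarray(p.reference_rgb, dtype=float))
        assert p.pixel_count == (layout.module_px // 2) ** 2


def test_warm_illuminant_raises_red_blue_ratio_of_neutral_patch(btb_spec, layout):
    ratios = {}
    for cct in (2500, 6500):
        scene = render_scene(spec=btb_spec, chemistry="BTB", concentration=0.5,
                             layout=layout, cct=cct, warp_jitter=0.0,
                             noise_sigma=0.0, seed=2)
        patches = sample_palette_patches(scene.canvas, btb_spec, layout)
        white = next(p for p in patches if p.entry_id == "gray60")
        ratios[cct] = white.captured_rgb[0] / max(white.captured_rgb[2], 1e-9)
    assert ratios[2500] > ratios[6500]


def test_rectification_error_does_not_grow_with_module_resolution(btb_spec):
    """Round-trip error at higher module resolution stays at least as low."""
    from dataclasses import replace

    from colorqr.vision import default_layout

    base = default_layout()
    errors = []
    for mpx in (5, 10):
        layout = replace(base, module_px=mpx)
        spec = default_spec("BTB", layout=layout)
        scene = render_scene(spec=spec, chemistry="BTB", concentration=0.5,
                             layout=layout, cct=6500, warp_jitter=0.02,
                             noise_sigma=0.0, seed=11)
        det = locate_and_decode(scene.image)
        canonical = rectify_to_canonical(scene.image, det, layout)
        patches = sample_palette_patches(canonical, spec, layout)
        err = np.mean([np.abs(p.captured_rgb - np.asarray(p.reference_rgb, float)).mean()
                       for p in patches])
        errors.append(err)
    assert errors[1] <= errors[0] + 0.5
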