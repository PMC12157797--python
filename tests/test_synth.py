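"""Synthetic generator: dye responses, illuminants, scenes, datasets."""

import numpy as np
import pytest

from colorqr.colorimetry import BTB_BOUNDS, DPD_BOUNDS, rgb_to_hls
from colorqr.synth import (BTBParams, CCT_GRID, btb_response, dpd_response,
                           generate_dataset, generate_feature_table,
                           illuminant_gains, render_scene, scene_digest)


# -- BTB response ------------------------------------------------------------

def test_btb_red_channel_inverts_calibration_line():
    """R = exp((b - C)/|m|): choosing C for ln R = ln 128 gives R = 128."""
    p = BTBParams()
    c = p.b - abs(p.m) * np.log(128.0)
    rgb = btb_response(c, p, noise_sigma=0.0)
    assert rgb[0] == pytest.approx(128.0, abs=1e-9)


def test_btb_response_monotone_decreasing():
    values = [btb_response(c, noise_sigma=0.0) for c in (0.2, 0.5, 0.9)]
    r, g, b = np.array(values).T
    assert r[0] > r[1] > r[2]
    assert g[0] > g[1] > g[2]
    assert b[0] > b[1] > b[2]


def test_btb_default_red_at_half_ppm():
    rgb = btb_response(0.5, noise_sigma=0.0)
    assert rgb[0] == pytest.approx(np.exp((3.3 - 0.5) / 0.64), abs=1e-9)
    assert rgb[0] == pytest.approx(79.44, abs=0.01)


def test_negative_concentration_rejected():
    with pytest.raises(ValueError):
        btb_response(-0.1)
    with pytest.raises(ValueError):
        dpd_response(-0.1)


# -- DPD response ------------------------------------------------------------

def test_dpd_channels_strictly_decreasing():
    concs = np.linspace(0, 3, 13)
    rgb = np.array([dpd_response(c, noise_sigma=0.0) for c in concs])
    assert np.all(np.diff(rgb[:, 1]) < 0)
    assert np.all(np.diff(rgb[:, 2]) < 0)
    assert np.ptp(rgb[:, 0]) == 0  # red held constant


def test_dpd_zero_analyte_is_near_neutral():
    rgb = dpd_response(0.0, noise_sigma=0.0)
    assert rgb.min() > 200
    _, _, s = rgb_to_hls(rgb)
    assert s < 0.2


def test_dpd_reacted_color_is_in_pink_sector():
    h, _, s = rgb_to_hls(dpd_response(2.0, noise_sigma=0.0))
    assert s > 0.2
    assert (280 <= h < 360) or (0 <= h < 20)


# -- illuminants -------------------------------------------------------------

def test_reference_illuminant_has_unit_gains():
    assert np.allclose(illuminant_gains(6500), 1.0, atol=0.05)


def test_warm_illuminant_direction():
    gains = illuminant_gains(2500)
    assert gains[0] > gains[2]
    assert gains[0] / gains[1] > 1.0 > gains[2] / gains[1]


def test_gains_are_continuous_in_cct():
    for cct in (2500, 3000, 4000, 5000, 6000):
        step = np.abs(illuminant_gains(cct + 1) - illuminant_gains(cct))
        assert step.max() < 1e-2


def test_out_of_range_cct_rejected():
    for cct in (500, 15000):
        with pytest.raises(ValueError):
            illuminant_gains(cct)


def test_cct_grid_matches_acquisition_protocol():
    assert CCT_GRID == tuple(range(2500, 7000, 500))


# -- scenes ------------------------------------------------------------------

def test_identical_seeds_render_identical_scenes(btb_spec, layout):
    kwargs = dict(spec=btb_spec, chemistry="BTB", concentration=0.7, layout=layout,
                  cct=3500, warp_jitter=0.05, noise_sigma=3.0, seed=99)
    assert scene_digest(render_scene(**kwargs)) == scene_digest(render_scene(**kwargs))
    other = render_scene(**{**kwargs, "seed": 100})
    assert scene_digest(other) != scene_digest(render_scene(**kwargs))


def test_truth_class_label_consistent_with_bounds(btb_spec, layout):
    for conc, expected in ((0.1, "low"), (0.5, "acceptable"), (1.5, "excess")):
        scene = render_scene(spec=btb_spec, chemistry="BTB", concentration=conc,
                             layout=layout, seed=1)
        assert scene.truth["class_label"] == expected


def test_truth_homography_maps_canvas_to_image(warped_scene, layout):
    h = warped_scene.truth["homography"]
    corners_canvas = np.array([
        [layout.qr_x, layout.qr_y, 1.0],
        [layout.qr_x + layout.qr_size_px, layout.qr_y, 1.0],
    ])
    mapped = corners_canvas @ h.T
    mapped = mapped[:, :2] / mapped[:, 2:3]
    assert np.allclose(mapped, warped_scene.truth["corners_image"][:2], atol=1e-9)


def test_identity_scene_palette_equals_references(identity_scene, btb_spec, layout):
    from colorqr.vision import sample_palette_patches

    patches = sample_palette_patches(identity_scene.image, btb_spec, layout)
    for p in patches:
        assert np.array_equal(p.captured_rgb, np.asarray(p.reference_rgb, dtype=float))


# -- datasets ----------------------------------------------------------------

def test_dataset_files_and_truth_rows(tmp_path, btb_spec, layout):
    scenes, table = generate_dataset(9, chemistry="BTB", out_dir=tmp_path,
                                     sampler="uniform", warp_jitter=0.0,
                                     noise_sigma=0.0, seed=5, spec=btb_spec,
                                     layout=layout)
    assert len(scenes) == len(table) == 9
    assert sorted(p.name for p in tmp_path.glob("scene_*.png")) == \
        sorted(table["image_path"])
    assert (tmp_path / "truth.csv").exists()
    assert (tmp_path / "dataset.json").exists()
    assert sorted(table["illuminant_K"].unique()) == sorted(CCT_GRID)


def test_stratified_sampler_covers_all_classes(btb_spec, layout):
    _, table = generate_dataset(30, chemistry="BTB", sampler="stratified",
                                warp_jitter=0.0, noise_sigma=0.0, seed=2,
                                spec=btb_spec, layout=layout, write_images=False)
    counts = table["class_label"].value_counts()
    assert all(counts[lbl] >= 9 for lbl in ("low", "acceptable", "excess"))


def test_truth_labels_equal_bounds_relabeling(btb_spec, layout):
    _, table = generate_dataset(12, chemistry="BTB", sampler="uniform",
                                warp_jitter=0.0, noise_sigma=0.0, seed=3,
                                spec=btb_spec, layout=layout, write_images=False)
    relabeled = [BTB_BOUNDS.classify(c) for c in table["concentration_ppm"]]
    assert list(table["class_label"]) == relabeled


def test_feature_table_matches_response_at_zero_noise():
    table = generate_feature_table(10, "DPD", sampler="medium",
                                   noise_sigma=0.0, seed=4)
    for _, row in table.iterrows():
        rgb = dpd_response(row["concentration_ppm"], noise_sigma=0.0)
        assert row["R"] == pytest.approx(rgb[0], abs=1e-9)
        assert row["G"] == pytest.approx(rgb[1], abs=1e-9)
        assert DPD_BOUNDS.classify(row["concentration_ppm"]) == row["class_label"]
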