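"""Colorimetric models: features, classifier, calibration regressions."""

import numpy as np
import pandas as pd
import pytest

from colorqr.colorimetry import (BTB_BOUNDS, CalibrationModel, ClassBounds,
                                 DegenerateFeatureError, FeatureVector,
                                 MissingClassError, classify, extract_features,
                                 fit_regression_btb, fit_regression_dpd,
                                 predict_concentration, rgb_to_hls, train_classifier)
from colorqr.colorcorr import fit_tps_map
from colorqr.roi import ROIBox, ROIMeasurement
from colorqr.synth import (BTBParams, btb_response, dpd_response,
                           generate_feature_table)


def identity_map(rng):
    ref = rng.uniform(0, 255, size=(24, 3))
    return fit_tps_map((ref, ref), lam=0.0)


# -- features ----------------------------------------------------------------

@pytest.mark.parametrize("rgb, expected", [
    ((255, 0, 0), (0.0, 0.5, 1.0)),
    ((128, 128, 128), (0.0, 128 / 255, 0.0)),
    ((0, 0, 255), (240.0, 0.5, 1.0)),
    ((255, 255, 255), (0.0, 1.0, 0.0)),
])
def test_rgb_to_hls_closed_forms(rgb, expected):
    h, l, s = rgb_to_hls(rgb)
    assert h == pytest.approx(expected[0], abs=1e-9)
    assert l == pytest.approx(expected[1], abs=1e-9)
    assert s == pytest.approx(expected[2], abs=1e-9)


def test_rgb_to_hls_rejects_out_of_range():
    with pytest.raises(ValueError):
        rgb_to_hls((256, 0, 0))


def test_extract_features_identity_map(rng):
    cmap = identity_map(rng)
    meas = ROIMeasurement(mean_rgb=np.array([200.0, 50.0, 50.0]),
                          std_rgb=np.zeros(3), pixel_count=100,
                          box=ROIBox(0, 0, 10, 10))
    fv = extract_features(meas, cmap)
    assert fv.R == pytest.approx(200, abs=1e-5)
    assert fv.Rc == fv.R
    h, l, s = rgb_to_hls((fv.R, fv.G, fv.B))
    assert (fv.H, fv.L, fv.S) == (h, l, s)


def test_gray_roi_has_zero_saturation(rng):
    cmap = identity_map(rng)
    meas = ROIMeasurement(mean_rgb=np.array([130.0, 130.0, 130.0]),
                          std_rgb=np.zeros(3), pixel_count=4,
                          box=ROIBox(0, 0, 2, 2))
    fv = extract_features(meas, cmap)
    assert fv.S == pytest.approx(0.0, abs=1e-9)
    assert fv.H == 0.0


# -- class bounds ------------------------------------------------------------

def test_bounds_are_half_open_and_manufacturer_valued():
    assert (BTB_BOUNDS.low_max, BTB_BOUNDS.high_min) == (0.2, 0.9)
    assert BTB_BOUNDS.classify(0.19) == "low"
    assert BTB_BOUNDS.classify(0.2) == "acceptable"
    assert BTB_BOUNDS.classify(0.9) == "excess"
    with pytest.raises(ValueError):
        ClassBounds(0.9, 0.2)


# -- classifier --------------------------------------------------------------

def separable_table():
    rows = []
    for conc in (0.1, 0.5, 2.0):
        rgb = btb_response(conc, noise_sigma=0.0)
        fv = FeatureVector.from_rgb(rgb)
        rows.extend([{**fv.as_dict(), "concentration_ppm": conc}] * 10)
    return pd.DataFrame(rows)


def test_noiseless_separable_classes_reach_perfect_heldout_accuracy():
    model = train_classifier(separable_table(), chemistry="BTB", split_seed=42)
    assert model.test_accuracy == 1.0


def test_permuted_labels_give_chance_level_accuracy(rng):
    table = generate_feature_table(120, "BTB", noise_sigma=0.5, seed=0)
    table["concentration_ppm"] = rng.permutation(table["concentration_ppm"].values)
    model = train_classifier(table, chemistry="BTB", split_seed=42)
    # 24 held-out rows; binomial 95% band around 1/3
    half_width = 1.96 * np.sqrt((1 / 3) * (2 / 3) / 24)
    assert abs(model.test_accuracy - 1 / 3) <= half_width + 1e-9


def test_single_class_training_raises():
    table = generate_feature_table(30, "BTB", concentrations=np.full(30, 0.5),
                                   noise_sigma=0.5, seed=1)
    with pytest.raises(MissingClassError):
        train_classifier(table, chemistry="BTB")


def test_zero_variance_feature_raises():
    table = separable_table()
    table["B"] = 100.0
    with pytest.raises(DegenerateFeatureError, match="B"):
        train_classifier(table, chemistry="BTB")


def test_scaled_training_features_are_standardized():
    from sklearn.model_selection import train_test_split

    table = generate_feature_table(150, "BTB", noise_sigma=1.0, seed=3)
    model = train_classifier(table, chemistry="BTB", split_seed=42)
    x = table.loc[:, list(model.feature_names)].to_numpy(float)
    labels = np.asarray([model.bounds.classify(c) for c in table["concentration_ppm"]])
    x_tr, _, _, _ = train_test_split(x, labels, test_size=0.2, random_state=42,
                                     stratify=labels)
    z = (x_tr - model.scaler_mean) / model.scaler_scale
    assert np.abs(z.mean(axis=0)).max() <= 1e-9
    assert np.abs(z.var(axis=0) - 1).max() <= 1e-9


@pytest.mark.parametrize("chemistry, conc, expected", [
    ("BTB", 0.05, "low"),
    ("BTB", 0.5, "acceptable"),
    ("BTB", 2.0, "excess"),
    ("DPD", 2.0, "excess"),
])
def test_classify_generator_labels(chemistry, conc, expected):
    table = generate_feature_table(150, chemistry, noise_sigma=0.5, seed=0)
    model = train_classifier(table, chemistry=chemistry, split_seed=42)
    response = btb_response if chemistry == "BTB" else dpd_response
    fv = FeatureVector.from_rgb(response(conc, noise_sigma=0.0))
    assert classify(fv, model) == expected


def test_classify_with_missing_feature_raises():
    table = generate_feature_table(150, "BTB", noise_sigma=0.5, seed=0)
    model = train_classifier(table, chemistry="BTB")
    object.__setattr__(model, "feature_names", ("R", "G", "B", "H", "L", "X"))
    fv = FeatureVector.from_rgb((100, 100, 100))
    with pytest.raises(KeyError):
        classify(fv, model)


def test_model_json_roundtrip_preserves_predictions(tmp_path):
    """The serialized decision function reproduces the in-memory SVC exactly."""
    table = generate_feature_table(150, "BTB", noise_sigma=1.0, seed=5)
    model = train_classifier(table, chemistry="BTB", split_seed=42)
    path = tmp_path / "model.json"
    model.to_json(path)
    restored = CalibrationModel.from_json(path)
    x = table.loc[:, list(model.feature_names)].to_numpy(float)
    assert np.array_equal(model.predict(x), restored.predict(x))


# -- BTB regression ----------------------------------------------------------

def medium_pairs(n=30, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    conc = np.linspace(0.25, 0.85, n)
    rc = np.array([btb_response(c, rng=rng, noise_sigma=sigma)[0] for c in conc])
    return np.column_stack([rc, conc])


def test_noiseless_regression_recovers_generator_coefficients():
    reg = fit_regression_btb(medium_pairs())
    p = BTBParams()
    assert reg.m == pytest.approx(p.m, abs=1e-6)
    assert reg.b == pytest.approx(p.b, abs=1e-6)
    assert reg.r2 == pytest.approx(1.0, abs=1e-9)


def test_noisy_regression_slope_within_printed_uncertainty():
    rng = np.random.default_rng(1)
    conc = rng.uniform(0.2, 0.9, 100)
    rc = np.array([btb_response(c, rng=rng, noise_sigma=2.0)[0] for c in conc])
    reg = fit_regression_btb(np.column_stack([rc, conc]))
    assert abs(reg.m - (-0.64)) <= 0.05
    assert abs(reg.b - 3.3) <= 0.2


def test_degenerate_design_raises():
    rows = np.tile([[80.0, 0.5]], (6, 1))
    with pytest.raises(np.linalg.LinAlgError):
        fit_regression_btb(rows)


def test_nonpositive_rc_raises():
    rows = medium_pairs()
    rows[0, 0] = 0.0
    with pytest.raises(ValueError, match="positive"):
        fit_regression_btb(rows)


def test_prediction_intervals_bracket_the_mean():
    reg = fit_regression_btb(medium_pairs(sigma=1.0, seed=2))
    frame = reg.predict(np.log([60.0, 90.0]))
    assert (frame["obs_ci_lower"] <= frame["mean"]).all()
    assert (frame["mean"] <= frame["obs_ci_upper"]).all()
    assert (frame["obs_ci_lower"] <= frame["mean_ci_lower"]).all()


def test_predicted_ppm_strictly_decreasing_in_rc():
    reg = fit_regression_btb(medium_pairs())
    assert reg.m < 0
    rc = np.linspace(45, 125, 20)
    ppm = reg.m * np.log(rc) + reg.b
    assert np.all(np.diff(ppm) < 0)


# -- DPD regression ----------------------------------------------------------

def test_collinear_log_channels_give_perfect_pc1_fit():
    conc = np.linspace(0.25, 1.05, 20)
    g = np.exp(5.4 - 0.25 * conc)
    b = np.exp(5.45 - 0.35 * conc)
    reg = fit_regression_dpd(np.column_stack([g, b, conc]))
    assert reg.explained_variance_ratio == pytest.approx(1.0, abs=1e-12)
    assert reg.ols.r2 == pytest.approx(1.0, abs=1e-9)
    pred = reg.predict_ppm(g, b)
    assert np.abs(pred - conc).max() <= 1e-9


def test_noisy_dpd_regression_r2():
    table = generate_feature_table(100, "DPD", sampler="medium",
                                   noise_sigma=2.0, seed=1)
    reg = fit_regression_dpd(table[["G", "B", "concentration_ppm"]].to_numpy())
    assert reg.ols.r2 >= 0.9


def test_pc1_loadings_match_closed_form_eigendecomposition(rng):
    conc = rng.uniform(0.2, 1.1, 60)
    g = np.exp(5.4 - 0.25 * conc + rng.normal(0, 0.01, 60))
    b = np.exp(5.45 - 0.35 * conc + rng.normal(0, 0.01, 60))
    reg = fit_regression_dpd(np.column_stack([g, b, conc]))
    logs = np.column_stack([np.log(g), np.log(b)])
    cov = np.cov(logs, rowvar=False)
    # closed-form leading eigenvector of a symmetric 2x2 matrix
    theta = 0.5 * np.arctan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1])
    v = np.array([np.cos(theta), np.sin(theta)])
    cross = abs(v[0] * reg.loadings[1] - v[1] * reg.loadings[0])
    assert cross <= 1e-8   # parallel up to sign


def test_nonpositive_channels_raise():
    rows = np.array([[100.0, 0.0, 0.5]] * 6)
    with pytest.raises(ValueError, match="positive"):
        fit_regression_dpd(rows)


# -- end measurement ---------------------------------------------------------

def btb_model_with_regression():
    table = generate_feature_table(150, "BTB", noise_sigma=0.5, seed=0)
    model = train_classifier(table, chemistry="BTB", split_seed=42)
    model.regression = fit_regression_btb(medium_pairs())
    return model


def test_inverse_evaluation_recovers_half_ppm():
    model = btb_model_with_regression()
    fv = FeatureVector.from_rgb(btb_response(0.5, noise_sigma=0.0))
    m = predict_concentration(fv, model)
    assert m.class_label == "acceptable"
    assert m.ppm == pytest.approx(0.5, abs=1e-6)
    assert not m.clipped
    assert m.ppm_interval[0] < 0.5 < m.ppm_interval[1]


@pytest.mark.parametrize("conc, label", [(0.05, "low"), (2.0, "excess")])
def test_out_of_range_classes_have_no_ppm(conc, label):
    model = btb_model_with_regression()
    fv = FeatureVector.from_rgb(btb_response(conc, noise_sigma=0.0))
    m = predict_concentration(fv, model)
    assert m.class_label == label
    assert m.ppm is None
    assert m.ppm_interval is None
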