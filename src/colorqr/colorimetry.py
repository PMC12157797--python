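"""Colorimetric models: features, 3-class chlorine classifier, calibrations.

Corrected ROI colors are turned into six features (R, G, B, hue, lightness,
saturation).  A support-vector classifier assigns one of three free-chlorine
classes -- low, acceptable, excess -- whose ppm boundaries follow the test
manufacturers (BTB strip: 0.2 / 0.9 ppm; DPD cuvette: 0.2 / 1.1 ppm).  For
samples in the acceptable range a per-chemistry regression produces the ppm
estimate: for BTB an ordinary least-squares fit of concentration on ln(Rc)
(the corrected red channel), for DPD an OLS fit on the first principal
component of (ln G, ln B).
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .colorcorr import ColorCorrectionMap, apply_map

__all__ = [
    "FeatureVector",
    "ClassBounds",
    "BTB_BOUNDS",
    "DPD_BOUNDS",
    "CalibrationModel",
    "Measurement",
    "MissingClassError",
    "DegenerateFeatureError",
    "rgb_to_hls",
    "extract_features",
    "train_classifier",
    "classify",
    "fit_regression_btb",
    "fit_regression_dpd",
    "predict_concentration",
]

CLASS_LABELS = ("low", "acceptable", "excess")
FEATURES_BTB = ("R", "G", "B", "H", "L", "S")
FEATURES_DPD = ("G", "B")


class MissingClassError(ValueError):
    """Fewer than the required rows (or none) for one of the three classes."""


class DegenerateFeatureError(ValueError):
    """A training feature has zero variance."""


def rgb_to_hls(rgb) -> tuple[float, float, float]:
    """Hexcone HSL of an 8-bit RGB triple: H in degrees [0, 360), L, S in [0, 1].

    H is defined as 0 for achromatic colors (S = 0).
    """
    r, g, b = rgb
    if not all(0 <= v <= 255 for v in (r, g, b)):
        raise ValueError(f"RGB components must be in [0,255], got {rgb}")
    h, l, s = colorsys.rgb_to_hls(r / 255.0, g / 255.0, b / 255.0)
    # hue is undefined (and numerically garbage) for achromatic colors
    return ((h * 360.0) % 360.0 if s > 1e-9 else 0.0, l, s)


@dataclass(frozen=True)
class FeatureVector:
    """Mean corrected ROI color expressed in the six model features."""

    R: float
    G: float
    B: float
    H: float
    L: float
    S: float

    @property
    def Rc(self) -> float:
        """Corrected red channel, the BTB regression predictor."""
        return self.R

    @classmethod
    def from_rgb(cls, rgb) -> "FeatureVector":
        h, l, s = rgb_to_hls(rgb)
        return cls(R=float(rgb[0]), G=float(rgb[1]), B=float(rgb[2]), H=h, L=l, S=s)

    def as_dict(self) -> dict[str, float]:
        return {"R": self.R, "G": self.G, "B": self.B, "H": self.H, "L": self.L, "S": self.S}


@dataclass(frozen=True)
class ClassBounds:
    """Chlorine class edges in ppm; intervals are half-open at the edges:
    low = C < low_max, acceptable = low_max <= C < high_min, excess = C >= high_min."""

    low_max: float
    high_min: float
    labels: tuple[str, str, str] = CLASS_LABELS

    def __post_init__(self):
        if not 0 < self.low_max < self.high_min:
            raise ValueError(f"need 0 < low_max < high_min, got {self}")

    def classify(self, concentration: float) -> str:
        if concentration < self.low_max:
            return self.labels[0]
        if concentration < self.high_min:
            return self.labels[1]
        return self.labels[2]


BTB_BOUNDS = ClassBounds(low_max=0.2, high_min=0.9)
DPD_BOUNDS = ClassBounds(low_max=0.2, high_min=1.1)

DEFAULT_BOUNDS = {"BTB": BTB_BOUNDS, "DPD": DPD_BOUNDS}


def extract_features(measurement, cmap: ColorCorrectionMap) -> FeatureVector:
    """Correct an ROI's mean color, then derive the HLS features.

    Correction is mean-then-correct: the scalar ROI mean is passed through
    the fitted color map once; HLS is computed from the corrected triple.
    """
    mean_rgb = np.asarray(getattr(measurement, "mean_rgb", measurement), dtype=float)
    corrected = np.clip(apply_map(cmap, mean_rgb), 0.0, 255.0)
    return FeatureVector.from_rgb(corrected)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """OLS calibration C = m * x + b with 95% parameter/prediction intervals."""

    m: float
    b: float
    r2: float
    m_ci: tuple[float, float]
    b_ci: tuple[float, float]
    n: int
    _model: object = field(default=None, repr=False)

    def predict(self, x) -> pd.DataFrame:
        """Mean prediction with 95% confidence and prediction intervals."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        exog = sm.add_constant(x, has_constant="add")
        frame = self._model.get_prediction(exog).summary_frame(alpha=0.05)
        frame.index = pd.RangeIndex(len(x))
        return frame

    def to_dict(self) -> dict:
        return {"slope": self.m, "intercept": self.b, "r2": self.r2,
                "slope_ci95": list(self.m_ci), "intercept_ci95": list(self.b_ci),
                "n": self.n}


def fit_regression_btb(rows) -> RegressionResult:
    """OLS of concentration on ln(Rc) over medium-range (Rc, C) pairs."""
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("rows must be (Rc, C) pairs")
    if arr.shape[0] < 5:
        raise ValueError(f"need >= 5 pairs, got {arr.shape[0]}")
    rc, conc = arr[:, 0], arr[:, 1]
    if np.any(rc <= 0):
        raise ValueError("all Rc values must be positive for ln(Rc)")
    x = np.log(rc)
    exog = sm.add_constant(x)
    if np.linalg.matrix_rank(exog) < 2:
        raise np.linalg.LinAlgError("degenerate design: ln(Rc) values are constant")
    fit = sm.OLS(conc, exog).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        m=float(fit.params[1]), b=float(fit.params[0]), r2=float(fit.rsquared),
        m_ci=(float(ci[1][0]), float(ci[1][1])), b_ci=(float(ci[0][0]), float(ci[0][1])),
        n=len(conc), _model=fit,
    )


@dataclass
class DPDRegression:
    """PC1-of-(ln G, ln B) calibration for the DPD chemistry."""

    loadings: np.ndarray          # (2,) PC1 loadings on (ln G, ln B)
    center: np.ndarray            # (2,) mean of (ln G, ln B)
    explained_variance_ratio: float
    ols: RegressionResult

    def project(self, g, b) -> np.ndarray:
        g = np.atleast_1d(np.asarray(g, dtype=float))
        b = np.atleast_1d(np.asarray(b, dtype=float))
        if np.any(g <= 0) or np.any(b <= 0):
            raise ValueError("G and B must be positive for the log transform")
        pts = np.column_stack([np.log(g), np.log(b)]) - self.center
        return pts @ self.loadings

    def predict_ppm(self, g, b) -> np.ndarray:
        return self.ols.m * self.project(g, b) + self.ols.b


def fit_regression_dpd(rows) -> DPDRegression:
    """PCA over (ln G, ln B) then OLS of concentration on PC1.

    The PC1 loadings are sign-fixed so the score increases with
    concentration, making the downstream slope orientation deterministic.
    """
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("rows must be (G, B, C) triples")
    if arr.shape[0] < 5:
        raise ValueError(f"need >= 5 rows, got {arr.shape[0]}")
    g, b, conc = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(g <= 0) or np.any(b <= 0):
        raise ValueError("all G and B values must be positive for the log transform")
    logs = np.column_stack([np.log(g), np.log(b)])
    center = logs.mean(axis=0)
    cov = np.cov(logs - center, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, -1]
    scores = (logs - center) @ pc1
    if np.corrcoef(scores, conc)[0, 1] < 0:
        pc1 = -pc1
        scores = -scores
    exog = sm.add_constant(scores)
    fit = sm.OLS(conc, exog).fit()
    ci = fit.conf_int(alpha=0.05)
    ols = RegressionResult(
        m=float(fit.params[1]), b=float(fit.params[0]), r2=float(fit.rsquared),
        m_ci=(float(ci[1][0]), float(ci[1][1])), b_ci=(float(ci[0][0]), float(ci[0][1])),
        n=len(conc), _model=fit,
    )
    evr = float(evals[-1] / evals.sum()) if evals.sum() > 0 else 1.0
    return DPDRegression(loadings=pc1, center=center, explained_variance_ratio=evr, ols=ols)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Standardizer + 3-class SVC + per-chemistry regression block."""

    chemistry: str
    feature_names: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    svc: SVC | None
    bounds: ClassBounds
    split_seed: int
    train_accuracy: float = float("nan")
    test_accuracy: float = float("nan")
    regression: object = None            # RegressionResult (BTB) or DPDRegression (DPD)
    svc_params: dict | None = None       # JSON-portable decision-function parameters

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (x - self.scaler_mean) / self.scaler_scale

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = self._scale(np.atleast_2d(np.asarray(features, dtype=float)))
        if self.svc is not None:
            return self.svc.predict(x)
        return _ovo_predict(self.svc_params, x)

    # -- persistence --------------------------------------------------------

    def to_json(self, path=None) -> str:
        svc = self.svc
        params = self.svc_params or {
            "gamma": float(svc._gamma),
            "classes": [str(c) for c in svc.classes_],
            "n_support": svc.n_support_.tolist(),
            "support_vectors": svc.support_vectors_.tolist(),
            "dual_coef": svc.dual_coef_.tolist(),
            "intercept": svc.intercept_.tolist(),
        }
        reg = None
        if isinstance(self.regression, RegressionResult):
            reg = {"kind": "btb", **self.regression.to_dict()}
        elif isinstance(self.regression, DPDRegression):
            reg = {"kind": "dpd", "loadings": self.regression.loadings.tolist(),
                   "center": self.regression.center.tolist(),
                   "explained_variance_ratio": self.regression.explained_variance_ratio,
                   **self.regression.ols.to_dict()}
        payload = json.dumps({
            "chemistry": self.chemistry,
            "feature_names": list(self.feature_names),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "svc": params,
            "bounds": {"low_max": self.bounds.low_max, "high_min": self.bounds.high_min},
            "split_seed": self.split_seed,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "regression": reg,
        }, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            raw = json.loads(Path(source).read_text())
        else:
            raw = json.loads(source)
        reg = None
        rr = raw.get("regression")
        if rr is not None:
            ols = RegressionResult(m=rr["slope"], b=rr["intercept"], r2=rr["r2"],
                                   m_ci=tuple(rr["slope_ci95"]), b_ci=tuple(rr["intercept_ci95"]),
                                   n=rr["n"])
            if rr["kind"] == "btb":
                reg = ols
            else:
                reg = DPDRegression(loadings=np.asarray(rr["loadings"]),
                                    center=np.asarray(rr["center"]),
                                    explained_variance_ratio=rr["explained_variance_ratio"],
                                    ols=ols)
        svc_params = dict(raw["svc"])
        svc_params["support_vectors"] = np.asarray(svc_params["support_vectors"], dtype=float)
        svc_params["dual_coef"] = np.asarray(svc_params["dual_coef"], dtype=float)
        svc_params["intercept"] = np.asarray(svc_params["intercept"], dtype=float)
        svc_params["n_support"] = np.asarray(svc_params["n_support"], dtype=int)
        return cls(
            chemistry=raw["chemistry"],
            feature_names=tuple(raw["feature_names"]),
            scaler_mean=np.asarray(raw["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(raw["scaler_scale"], dtype=float),
            svc=None,
            bounds=ClassBounds(raw["bounds"]["low_max"], raw["bounds"]["high_min"]),
            split_seed=int(raw["split_seed"]),
            train_accuracy=float(raw["train_accuracy"]),
            test_accuracy=float(raw["test_accuracy"]),
            regression=reg,
            svc_params=svc_params,
        )


def _ovo_predict(params: dict, x: np.ndarray) -> np.ndarray:
    """One-vs-one RBF-SVC prediction from serialized parameters.

    Reconstructs the libsvm decision functions: for classes i < j the
    decision uses the dual coefficients of class-i support vectors (row j-1)
    and class-j support vectors (row i), with vote + confidence tie-break.
    """
    sv = params["support_vectors"]
    dual = params["dual_coef"]
    intercept = params["intercept"]
    n_support = params["n_support"]
    classes = np.asarray(params["classes"])
    gamma = params["gamma"]
    starts = np.concatenate([[0], np.cumsum(n_support)])
    d2 = ((x[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
    kern = np.exp(-gamma * d2)                         # (m, n_sv)
    nc = len(classes)
    votes = np.zeros((x.shape[0], nc))
    conf = np.zeros((x.shape[0], nc))
    p = 0
    for i in range(nc):
        for j in range(i + 1, nc):
            si, ei = starts[i], starts[i + 1]
            sj, ej = starts[j], starts[j + 1]
            dec = (kern[:, si:ei] @ dual[j - 1, si:ei]
                   + kern[:, sj:ej] @ dual[i, sj:ej] + intercept[p])
            win = np.where(dec > 0, i, j)
            votes[np.arange(x.shape[0]), win] += 1
            conf[:, i] += dec
            conf[:, j] -= dec
            p += 1
    best = votes + 1e-9 * np.tanh(conf)   # confidence only breaks exact vote ties
    return classes[np.argmax(best, axis=1)]


def train_classifier(table: pd.DataFrame, bounds: ClassBounds | None = None,
                     split_seed: int = 42, chemistry: str = "BTB",
                     svc_c: float = 1.0) -> CalibrationModel:
    """Train the 3-class chlorine classifier on a labelled feature table.

    ``table`` needs a ``concentration_ppm`` column plus the chemistry's
    feature columns (BTB: R,G,B,H,L,S; DPD: G,B).  Rows are relabeled by the
    class bounds, split 80/20 stratified by ``split_seed``, standardized to
    zero mean / unit variance, and fed to an RBF SVC (C=1, gamma='scale').
    """
    chemistry = chemistry.upper()
    if bounds is None:
        bounds = DEFAULT_BOUNDS[chemistry]
    names = FEATURES_BTB if chemistry == "BTB" else FEATURES_DPD
    x = table.loc[:, list(names)].to_numpy(dtype=float)
    labels = np.asarray([bounds.classify(c) for c in table["concentration_ppm"]])

    counts = {lbl: int((labels == lbl).sum()) for lbl in bounds.labels}
    bad = [f"{lbl} ({n} rows)" for lbl, n in counts.items() if n < 3]
    if bad:
        raise MissingClassError(f"need >= 3 rows per class; deficient: {', '.join(bad)}")
    var = x.var(axis=0)
    if np.any(var == 0):
        dead = [names[i] for i in np.where(var == 0)[0]]
        raise DegenerateFeatureError(f"zero-variance feature(s): {dead}")

    x_tr, x_te, y_tr, y_te = train_test_split(
        x, labels, test_size=0.2, random_state=split_seed, stratify=labels)
    scaler = StandardScaler().fit(x_tr)
    svc = SVC(kernel="rbf", C=svc_c, gamma="scale")
    svc.fit(scaler.transform(x_tr), y_tr)
    model = CalibrationModel(
        chemistry=chemistry,
        feature_names=names,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        svc=svc,
        bounds=bounds,
        split_seed=split_seed,
        train_accuracy=float((svc.predict(scaler.transform(x_tr)) == y_tr).mean()),
        test_accuracy=float((svc.predict(scaler.transform(x_te)) == y_te).mean()),
    )
    return model


def classify(fv: FeatureVector, model: CalibrationModel) -> str:
    """Class label of a feature vector under a fitted model."""
    row = fv.as_dict()
    missing = [n for n in model.feature_names if n not in row]
    if missing:
        raise KeyError(f"feature(s) {missing} missing from the feature vector")
    x = np.array([[row[n] for n in model.feature_names]])
    return str(model.predict(x)[0])


@dataclass
class Measurement:
    """Final readout: class, optional ppm (acceptable range only), provenance."""

    class_label: str
    ppm: float | None
    ppm_interval: tuple[float, float] | None
    features: FeatureVector
    clipped: bool = False
    provenance: dict = field(default_factory=dict)


def predict_concentration(fv: FeatureVector, model: CalibrationModel,
                          provenance: dict | None = None) -> Measurement:
    """Classify, then estimate ppm only for the acceptable class.

    Regression output falling outside the acceptable interval is clipped to
    the bounds and flagged: it signals a sample that the classifier put in
    the medium range but whose color is at (or past) the range edge.
    """
    label = classify(fv, model)
    ppm = interval = None
    clipped = False
    if label == model.bounds.labels[1] and model.regression is not None:
        reg = model.regression
        if isinstance(reg, DPDRegression):
            raw = float(reg.predict_ppm(fv.G, fv.B)[0])
            interval = None
        else:
            if fv.Rc <= 0:
                raise ValueError("corrected red channel must be positive for ln(Rc)")
            raw = reg.m * float(np.log(fv.Rc)) + reg.b
            if reg._model is not None:
                frame = reg.predict(np.log(fv.Rc))
                interval = (float(frame["obs_ci_lower"][0]), float(frame["obs_ci_upper"][0]))
        ppm = float(np.clip(raw, model.bounds.low_max, model.bounds.high_min))
        clipped = ppm != raw
    return Measurement(class_label=label, ppm=ppm, ppm_interval=interval,
                       features=fv, clipped=clipped, provenance=provenance or {})
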